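# task_id: BrokenWindow
# provenance: synthetic stand-in checklist (24 items) modeled on the published picture-sequence norms; not the authoritative normed list
label	accepted_lemmas	extended_forms
and	and
ball	ball
be	be
boy	boy
break	break
go	go
he	he
his	his
in	in
it	it
kick	kick
lamp	lamp
look	look
of	of
out	out
over	over
play	play
sit	sit
soccer	soccer
the	the
through	through
to	to
up	up
window	window
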