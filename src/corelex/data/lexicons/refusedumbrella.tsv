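# task_id: RefusedUmbrella
# provenance: synthetic stand-in checklist (35 items) modeled on the published picture-sequence norms; not the authoritative normed list
label	accepted_lemmas	extended_forms
a	a
and	and
back	back
be	be
boy	boy
do	do
down	down
get	get
go	go
have	have
he	he
his	his
home	home
in	in
it	it
little	little
mother	mother;mom;mama;mommy
need	need
not	not
out	out
rain	rain
say	say
school	school
she	she
so	so
take	take
tell	tell
that	that
the	the
to	to
umbrella	umbrella
walk	walk
wet	wet
will	will
you	you
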