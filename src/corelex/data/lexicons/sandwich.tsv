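# task_id: Sandwich
# provenance: synthetic stand-in checklist (25 items) modeled on the published procedural-discourse norms; not the authoritative normed list
label	accepted_lemmas	extended_forms
a	a
and	and
bread	bread
butter	butter
get	get
it	it
jelly	jelly
knife	knife
of	of
on	on
one	one
other	other
out	out
peanut	peanut
piece	piece
put	put
slice	slice
spread	spread
take	take
the	the
then	then
to	to
together	together
two	two
you	you
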