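# task_id: CatRescue
# provenance: synthetic stand-in checklist (34 items) modeled on the published single-picture norms; not the authoritative normed list
label	accepted_lemmas	extended_forms
a	a
and	and
bark	bark
be	be
call	call
cat	cat	kittycat
climb	climb
come	come
department	department
dog	dog
down	down
father	father;dad;daddy;papa;pa
fire	fire
fireman	fireman;firefighter
get	get
girl	girl
go	go
have	have
he	he
in	in
it	it
ladder	ladder
little	little
not	not
of	of
she	she
so	so
stuck	stuck;stick
the	the
to	to
tree	tree
truck	truck
up	up
with	with
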