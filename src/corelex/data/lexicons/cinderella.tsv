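# task_id: Cinderella
# provenance: synthetic stand-in checklist (94 items) modeled on the published story-narrative norms; not the authoritative normed list
label	accepted_lemmas	extended_forms
a	a
all	all
and	and
at	at
back	back
ball	ball
be	be
beautiful	beautiful
because	because
but	but
by	by
carriage	carriage
change	change
cinderella	cinderella
clock	clock
come	come
dance	dance
daughter	daughter
do	do
dress	dress
fairy	fairy
fall	fall
father	father;dad;daddy;papa;pa
find	find
fit	fit
foot	foot
for	for
from	from
get	get
girl	girl
glass	glass
go	go
godmother	godmother
have	have
he	he
her	her
home	home
horse	horse
house	house
i	i
in	in
into	into
it	it
know	know
leave	leave
like	like
little	little
live	live
look	look
lose	lose
love	love
magic	magic
make	make
marry	marry
midnight	midnight
mother	mother;mom;mama;mommy
mouse	mouse
not	not
of	of
off	off
on	on
one	one
out	out
palace	palace
prince	prince
pumpkin	pumpkin
run	run
say	say
she	she
shoe	shoe
sister	sister
slipper	slipper
so	so
stepmother	stepmother
stepsister	stepsister
strike	strike
take	take
tell	tell
that	that
the	the
then	then
they	they
time	time
to	to
try	try
turn	turn
two	two
up	up
want	want
wear	wear
when	when
will	will
with	with
you	you
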