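# Irregular-inflection table for the fallback analyzer.
# Columns: surface <TAB> lemma <TAB> inflection tags (;-separated, optional).
# Checklist matching accepts a word's plurals, conjugations and other
# inflections; regular -s/-ed/-ing forms are handled by suffix rules, this
# table lists the irregulars and a few identity guards.  Editable.
am	be	1S
is	be	3S
are	be	PRES
was	be	PAST
were	be	PAST
been	be	PERF
being	be	PRESP
has	have	3S
had	have	PAST
did	do	PAST
done	do	PERF
went	go	PAST
gone	go	PERF
said	say	PAST
got	get	PAST
gotten	get	PERF
made	make	PAST
knew	know	PAST
known	know	PERF
thought	think	PAST
took	take	PAST
taken	take	PERF
saw	see	PAST
seen	see	PERF
came	come	PAST
found	find	PAST
gave	give	PAST
given	give	PERF
told	tell	PAST
felt	feel	PAST
became	become	PAST
left	leave	PAST
meant	mean	PAST
kept	keep	PAST
began	begin	PAST
begun	begin	PERF
showed	show	PAST
shown	show	PERF
heard	hear	PAST
brought	bring	PAST
wrote	write	PAST
written	write	PERF
sat	sit	PAST
stood	stand	PAST
lost	lose	PAST
paid	pay	PAST
met	meet	PAST
ran	run	PAST
drove	drive	PAST
driven	drive	PERF
broke	break	PAST
broken	break	PERF
bought	buy	PAST
wore	wear	PAST
worn	wear	PERF
chose	choose	PAST
chosen	choose	PERF
fell	fall	PAST
fallen	fall	PERF
caught	catch	PAST
drew	draw	PAST
drawn	draw	PERF
ate	eat	PAST
eaten	eat	PERF
flew	fly	PAST
flown	fly	PERF
forgot	forget	PAST
forgotten	forget	PERF
held	hold	PAST
rode	ride	PAST
ridden	ride	PERF
rang	ring	PAST
rung	ring	PERF
rose	rise	PAST
risen	rise	PERF
slept	sleep	PAST
spoke	speak	PAST
spoken	speak	PERF
spent	spend	PAST
stole	steal	PAST
stolen	steal	PERF
struck	strike	PAST
stuck	stick	PAST
swam	swim	PAST
swum	swim	PERF
taught	teach	PAST
threw	throw	PAST
thrown	throw	PERF
understood	understand	PAST
won	win	PAST
sang	sing	PAST
sung	sing	PERF
sent	send	PAST
built	build	PAST
would	will	COND
could	can	COND
should	shall	COND
might	may	COND
children	child	PL
men	man	PL
women	woman	PL
feet	foot	PL
teeth	tooth	PL
mice	mouse	PL
geese	goose	PL
knives	knife	PL
wives	wife	PL
leaves	leave	3S
lives	live	3S
firemen	fireman	PL
policemen	policeman	PL
glasses	glass	PL
an	a
yes	yes
gas	gas
news	news
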