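# Dialect / fused-form table for the fallback analyzer.
# Columns: form <TAB> component surface forms (;-separated).
# Dialect variants are credited as their Standard American English
# components, each lemmatized separately (e.g. "gonna" credits both
# "go" and "to").  Editable.
gonna	going;to
wanna	want;to
gotta	got;to
hafta	have;to
hasta	has;to
oughta	ought;to
lemme	let;me
gimme	give;me
kinda	kind;of
sorta	sort;of
outta	out;of
lotta	lot;of
dunno	do;not;know
won't	will;not
can't	can;not
ain't	is;not
yeah	yes
yep	yes
nope	no
cuz	because
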