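# Clitic suffix table for the fallback analyzer.
# Columns: suffix <TAB> expansion surface <TAB> part-of-speech label.
# Contracted forms are credited the same as uncontracted forms: the suffix is
# detached, expanded to a full surface form and lemmatized on its own.
# Editable; ambiguous clitics ('s, 'd) resolve to the listed default.
n't	not	neg
'll	will	mod
're	are	cop
've	have	aux
'm	am	cop
'd	would	mod
's	is	cop
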