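# Default cue lexicon: phrase <TAB> normalized category.
# Seeded from the categories that matter most for clinical negation
# (no / deny / negative / without / absent / ruled_out); extensible data.
no	no
not	not
without	without
with no	no
denies	deny
denied	deny
deny	deny
negative	negative
negative for	negative
no evidence of	no
no evidence for	no
no sign of	no
no signs of	no
absence of	absent
absent	absent
free of	negative
never had	deny
ruled out	ruled_out
rules out	ruled_out
rule out	ruled_out
was ruled out	ruled_out
unlikely	unlikely
unremarkable for	negative
lacks	absent
lack of	absent
resolved	resolved
declines	deny
declined	deny
no history of	no
no complaints of	no
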