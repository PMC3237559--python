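# Charge classification: positive / negative / uncharged.
# A substitution is "radical" when it crosses groups, "conservative" within a group.
positive: RHK
negative: DE
uncharged: ACFGILMNPQSTVWY
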