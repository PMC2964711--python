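label	mutation_class	years_per_mutation	citation
a	coding_substitution	5140	coding-region substitution clock (back-computed package default; confirm against the original calibration literature)
b	coding_substitution	4610	coding-region substitution clock, alternative rate (back-computed package default)
c	synonymous_transition	6764	synonymous-transition clock (back-computed package default)
b2	synonymous_transition	7650	synonymous-transition clock, alternative rate (back-computed package default)
d	synonymous_transition	7884	synonymous-transition clock, alternative rate (back-computed package default)
e	synonymous_transition	7990	synonymous-transition clock, alternative rate (back-computed package default)
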