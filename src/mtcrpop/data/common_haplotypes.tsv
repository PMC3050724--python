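# The two most frequent control-region haplotypes of the emulated survey
# (five occurrences each): a B5a and a F1a1 profile, difference-coded.
SampleId	Range	Haplotype
B5a_common	16024-16569 1-576	73-210-263-315.1C-523del-524del-16140-16183C-16189-16266A-16519
F1a1_common	16024-16569 1-576	73-249del-263-315.1C-523del-524del-16129-16162-16172-16304-16399-16519
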