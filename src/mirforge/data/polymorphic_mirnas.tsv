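id	reference	variant
ssa-miR-16a-1-3p	CCAGTATTGTTCGTGCTGCTGA	CCAGTATTGCTCGTGCTGCTGA
ssa-miR-100a-2-3p	ACAAGCTTGTGTCTATAGGTATG	ACAAGCTCGTGTCTATAGGTATG
ssa-miR-2188-3p	GCTGTGTGAGGTCAGACCTATC	GCTGTGTGAGGTCGGACCTATC
ssa-miR-29b-1-5p	ACTGATTTCTTCTGGTGTTTAGA	ACTGATTTCCTCTGGTGTTTAGA
ssa-let-7a-2-3p	CTATACAACTTACTGTCTTTCC	CTATACAACATACTGTCTTTCC
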