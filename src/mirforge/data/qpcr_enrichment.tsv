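id	tissue	ddct	enrichment
ssa-miR-9a-5p	B	-11.13	2241
ssa-miR-9b-3p	B	-10.21	1184
ssa-miR-96-5p	B	-5.18	36
ssa-miR-129-5p	B	-3.56	12
ssa-miR-132-5p	B	-7.46	176
ssa-miR-135c-5p	B	-7.05	133
ssa-miR-153a-3p	B	-10.08	1082
ssa-miR-212ab-3p	B	-7.29	156
ssa-miR-219a-3p	B	-7.66	202
ssa-miR-723-5p	B	-6.83	114
ssa-miR-734a-3p	B	-4.68	26
ssa-miR-122-5p	L	-12.3	5043
ssa-miR-8163-3p	L	-8.6	388
ssa-miR-192a-5p	L	-7.96	249
ssa-miR-499a-5p	H	-9.7	832
ssa-miR-736-3p	H	-14.7	26616
ssa-miR-192a-5p	I	-11.9	3822
ssa-miR-459-5p	I	-12.9	7643
ssa-miR-194b-5p	I	-10.8	1783
ssa-miR-140-3p	G	-3.7	13
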