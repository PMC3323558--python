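# demographic characteristics of affected study subjects, by age band and sex:
# all affected individuals, and affected individuals with a genotyped affected relative
age_band	affected_male	affected_female	typed_rel_male	typed_rel_female
86-89	36	5	27	5
90-92	65	60	51	49
93-95	65	53	50	41
96-97	43	21	31	16
98-99	19	18	7	13
100+	19	29	14	21
Total	247	186	180	145
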