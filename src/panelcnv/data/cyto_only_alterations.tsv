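patient	disease	alteration	detected_by	validation	fish_pct_uncultured	fish_pct_cultured	karyotype_abnormal	karyotype_total	note
3	MDS	Monosomy 7	FISH		90				FISH on CD34+ isolated cells; undetectable in unfractionated sample
12	MDS/MPN	del(12p)	karyotype		3.6	6.4	2	20
14	MDS	Trisomy 8	karyotype		10.4	15.2	7	20
17	AML	inv(16)	karyotype		20	30	2	6
46	AML	Trisomy 8	karyotype		7.2	9.8	4	10
56	MDS	Trisomy 8	karyotype		9.8	13.8	3	20
64	AML	Trisomy 8	karyotype		5.4	5.2	5	11
72	MDS	Trisomy 8	karyotype		18.4	22.4	3	13
97	MPAL	del(5q)	FISH		20.5	21
101	MDS	Trisomy 8	karyotype		5	7.8	2	20
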