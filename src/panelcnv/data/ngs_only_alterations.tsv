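patient	disease	alteration	detected_by	validation	fish_pct_uncultured	fish_pct_cultured	karyotype_abnormal	karyotype_total	note
23	AML	del(12p)	NGS	MLPA					karyotype 46,XY,t(1;10)(p36;q11),inv(2)(q31q37)[14]/46,XY[6]
36	MPN	Trisomy 19	NGS	MLPA					karyotype not performed; FISH showed del(20q)
47	MPAL	del(5q)	NGS	MLPA					normal karyotype 46,XY[20]
49	MDS	del(12p)	NGS	MLPA					karyotype 46,XY,add(7)(q22)[3]/46,XY[9]; FISH del(7q)
55	AML	t(10;11)	NGS,FISH	RT-QPCR					break-apart FISH saw the KMT2A rearrangement; only NGS resolved the t(10;11) partner
60	AML	del(12p)	NGS	MLPA					no metaphases; FISH del(7q),del(5q),del(17p),loss of MECOM/RPN1
109	AML	del(12p)	NGS	MLPA					complex karyotype; FISH -7,del(5q)
110	MDS	del(12p)	NGS	MLPA					normal karyotype 46,XX[15]
123	MDS	del(12p)	NGS	MLPA					complex karyotype with add(12)(p13)
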