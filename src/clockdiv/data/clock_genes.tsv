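gene	group	model	nucleotides	relative_rate
CkIIa	PTM	Dayhoff+G+F	451	0.102
Clk	TTFL	JTT+G+F	1865	0.679
cry2	TTFL	LG+G	634	0.298
Cul3	PTM	LG+G	1771	0.348
cwo	TTFL	LG+G+F	2313	1.792
cyc	TTFL	JTT+G	851	0.390
dbt	PTM	JTT+G	527	0.866
jet	PTM	LG+G+F	1004	1.572
kaya	TTFL	LG+G+F	1162	1.625
nmo	PTM	JTT+G	2130	0.254
Pdp1	TTFL	LG+I	3083	0.602
per	TTFL	JTT+G	2670	1.500
PP2A-B'	PTM	LG+G	721	0.463
sgg	PTM	Dayhoff+G	2641	0.455
slimb	PTM	JTT+G	2355	0.559
tim	TTFL	JTT+G+F	2752	0.793
vri	TTFL	JTT+I+G+F	2465	1.234
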