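name	accessions	taxon	genome_class	longest_contig_kb	samples	rtpcr_positive	dnapcr_positive
Beult virus	MF893261,MF893262	Hepe-virga clade	plus_ss_rna	12	France2013,UK2014,UK2015,UK2016,Japan2016	true	false
Saiwaicho virus	MF893256	Hepe-virga clade	plus_ss_rna	10	Japan2016	true	false
Luckshill virus	MF893250	Hepe-virga clade	plus_ss_rna	3.5	UK2016	true	false
Teise virus	MF893259	Luteoviridae	plus_ss_rna	3.0	France2013,UK2014,UK2015,UK2016,Japan2016	true	false
Tama virus	MF893258	Sobemovirus	plus_ss_rna	3.5	Japan2016	true	false
Medway virus	MF893251	Sobemovirus	plus_ss_rna	2.7	UK2014	true	false
Dsuz Nora virus	MF893254	Picornaviridae	plus_ss_rna	12	Japan2016	true	false
Naganuma virus	MF893253	Nodaviridae	plus_ss_rna	1.6	Japan2016	true	false
Fuefuki virus	MF893247	Nidoviridae	plus_ss_rna	16	Japan2016	true	false
Cyril virus	MF893263	Hepe-virga clade	plus_ss_rna	3.2	UK2016	true	false
Eccles Virus	MF893265,MF893266,MF893267,MF893268,MF893269,MF893270	Reoviridae	ds_rna	4.2	UK2014	true	false
Larkfield virus	MF893249	Totiviridae	ds_rna	6	UK2015	true	false
Snodland virus	MF893257	Totiviridae	ds_rna	1.6	UK2015	true	false
Mogami virus	MF893252	Chuvirus	minus_ss_rna	10.5	Japan2016	true	false
Ditton virus	MF893264	Phasmaviridae	minus_ss_rna	7.3	UK2015	true	false
Barming virus	MF893260	Phleboviridae	minus_ss_rna	6.5	UK2016	true	false
Notori virus	MF893255	Phasmaviridae	minus_ss_rna	7	Japan2016	true	false
Kiln Barn virus	MF893248	Chuvirus	minus_ss_rna	3.7	UK2016	true	false
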