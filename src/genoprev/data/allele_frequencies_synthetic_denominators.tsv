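# Ancestry-stratified pathogenic allele frequencies for the ARG1 locus.
# Allele frequencies are published point estimates; allele numbers are SYNTHETIC
# (an=1,000,000 for every cell so that ac/an reproduces the 6-decimal frequency
# exactly) because the source denominators are not published.
# EAS rows carry the published pooled EAS/SAS column; no separate SAS rows exist.
rsid	group	ac	an	af
rs104893944	NFE	31	1000000	0.000031
rs104893944	AFR	0	1000000	0.000000
rs104893944	AMR	339	1000000	0.000339
rs104893944	EAS	0	1000000	0.000000
rs104893948	NFE	16	1000000	0.000016
rs104893948	AFR	0	1000000	0.000000
rs104893948	AMR	113	1000000	0.000113
rs104893948	EAS	50	1000000	0.000050
rs587776539	NFE	18	1000000	0.000018
rs587776539	AFR	0	1000000	0.000000
rs587776539	AMR	0	1000000	0.000000
rs587776539	EAS	0	1000000	0.000000
rs140549609	NFE	9	1000000	0.000009
rs140549609	AFR	0	1000000	0.000000
rs140549609	AMR	0	1000000	0.000000
rs140549609	EAS	0	1000000	0.000000
rs753829097	NFE	9	1000000	0.000009
rs753829097	AFR	0	1000000	0.000000
rs753829097	AMR	0	1000000	0.000000
rs753829097	EAS	0	1000000	0.000000
rs28941474	NFE	0	1000000	0.000000
rs28941474	AFR	0	1000000	0.000000
rs28941474	AMR	29	1000000	0.000029
rs28941474	EAS	0	1000000	0.000000
rs377280518	NFE	40	1000000	0.000040
rs377280518	AFR	80	1000000	0.000080
rs377280518	AMR	0	1000000	0.000000
rs377280518	EAS	0	1000000	0.000000
OTHER	NFE	742	1000000	0.000742
OTHER	AFR	106	1000000	0.000106
OTHER	AMR	923	1000000	0.000923
OTHER	EAS	1178	1000000	0.001178
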