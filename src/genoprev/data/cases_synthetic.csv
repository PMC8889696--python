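# Synthetic case database: 114 biallelic cases whose per-variant allele totals
# reproduce the published tally (named variants 28/21/12/8/7/7/6, rare bucket 139).
# The pairing of alleles into cases is a synthetic construction; only the marginal
# allele counts are published.
case_id,source_ref,allele_a,allele_b
C001,study:S01,local:v30,local:v08
C002,study:S02,rs104893944,local:v15
C003,study:S03,local:v18,rs700000018
C004,study:S04,local:v01,local:v21
C005,study:S05,local:v24,local:v28
C006,study:S06,rs700000012,local:v04
C007,study:S07,rs700000001,local:v17
C008,study:S08,local:v10,rs753829097
C009,study:S09,rs104893944,rs587776539
C010,study:S10,rs104893948,local:v18
C011,study:S11,local:v20,rs587776539
C012,study:S12,local:v10,rs140549609
C013,study:S13,rs104893944,rs587776539
C014,study:S14,rs700000019,local:v29
C015,study:S15,rs587776539,rs587776539
C016,study:S16,rs700000011,rs104893948
C017,study:S17,local:v34,rs104893948
C018,study:S18,rs700000009,rs104893948
C019,study:S19,rs104893948,rs28941474
C020,study:S20,local:v34,rs104893948
C021,study:S21,local:v15,local:v24
C022,study:S22,rs104893948,rs104893948
C023,study:S23,rs700000001,rs700000002
C024,study:S24,rs700000016,rs104893944
C025,study:S25,local:v13,local:v26
C026,study:S26,rs104893944,rs140549609
C027,study:S27,rs104893944,rs377280518
C028,study:S28,rs104893944,local:v31
C029,study:S29,rs104893948,rs700000017
C030,study:S30,rs587776539,local:v14
C031,study:S31,rs753829097,local:v09
C032,study:S32,rs28941474,rs700000003
C033,study:S33,rs140549609,rs753829097
C034,study:S01,rs104893944,local:v04
C035,study:S02,local:v30,local:v12
C036,study:S03,rs140549609,rs377280518
C037,study:S04,local:v20,local:v23
C038,study:S05,local:v26,rs104893948
C039,study:S06,rs377280518,rs700000017
C040,study:S07,rs700000016,rs104893948
C041,study:S08,rs700000004,local:v16
C042,study:S09,rs700000008,local:v13
C043,study:S10,local:v19,local:v13
C044,study:S11,rs104893948,local:v03
C045,study:S12,rs104893944,rs700000009
C046,study:S13,rs753829097,local:v14
C047,study:S14,rs700000015,rs104893948
C048,study:S15,local:v02,rs700000001
C049,study:S16,local:v15,local:v14
C050,study:S17,local:v08,local:v33
C051,study:S18,local:v21,rs700000018
C052,study:S19,local:v22,rs700000002
C053,study:S20,rs700000020,rs700000008
C054,study:S21,rs377280518,rs753829097
C055,study:S22,rs587776539,local:v27
C056,study:S23,rs700000010,local:v20
C057,study:S24,local:v06,rs700000013
C058,study:S25,rs104893948,rs377280518
C059,study:S26,local:v12,local:v32
C060,study:S27,rs104893948,local:v28
C061,study:S28,local:v05,local:v21
C062,study:S29,rs104893948,local:v05
C063,study:S30,rs28941474,local:v07
C064,study:S31,local:v31,local:v11
C065,study:S32,rs104893944,rs700000005
C066,study:S33,local:v04,rs104893944
C067,study:S01,rs104893944,rs104893948
C068,study:S02,local:v06,local:v29
C069,study:S03,rs700000014,rs700000006
C070,study:S04,local:v24,local:v23
C071,study:S05,local:v32,rs700000021
C072,study:S06,local:v12,local:v01
C073,study:S07,rs104893944,rs700000012
C074,study:S08,rs587776539,rs700000002
C075,study:S09,local:v16,rs700000010
C076,study:S10,rs104893944,rs140549609
C077,study:S11,local:v06,rs104893944
C078,study:S12,local:v19,local:v16
C079,study:S13,rs140549609,local:v03
C080,study:S14,local:v05,rs104893944
C081,study:S15,rs104893944,rs377280518
C082,study:S16,local:v18,rs104893944
C083,study:S17,local:v07,rs700000011
C084,study:S18,rs140549609,local:v25
C085,study:S19,rs587776539,rs140549609
C086,study:S20,local:v01,local:v17
C087,study:S21,rs28941474,local:v22
C088,study:S22,rs104893944,local:v23
C089,study:S23,rs753829097,rs587776539
C090,study:S24,rs700000005,rs104893944
C091,study:S25,local:v08,local:v27
C092,study:S26,rs700000019,rs700000004
C093,study:S27,local:v19,rs104893944
C094,study:S28,rs700000014,rs700000013
C095,study:S29,rs700000007,rs104893944
C096,study:S30,local:v27,local:v22
C097,study:S31,local:v11,local:v11
C098,study:S32,local:v26,rs104893944
C099,study:S33,rs700000003,rs104893944
C100,study:S01,local:v02,rs28941474
C101,study:S02,rs28941474,rs104893948
C102,study:S03,rs700000006,rs104893944
C103,study:S04,rs104893948,local:v33
C104,study:S05,local:v09,local:v25
C105,study:S06,local:v17,rs104893944
C106,study:S07,rs104893944,local:v10
C107,study:S08,rs700000015,rs700000020
C108,study:S09,rs104893948,rs753829097
C109,study:S10,rs700000021,rs104893948
C110,study:S11,rs587776539,rs104893944
C111,study:S12,rs700000007,rs587776539
C112,study:S13,local:v25,local:v02
C113,study:S14,local:v07,rs28941474
C114,study:S15,local:v03,local:v09
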