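# Published read counts per Synechococcus SC5.1 clade and station/depth from
# the NW Pacific amplicon pyrosequencing field survey; the final row holds
# reads assigned outside SC5.1 (Prochlorococcus).
clade	A1_0	A5_30	P3_0	P3_5	P3_15	P3_30	P3_75	P3_108
I	124	31	0	0	0	0	0	0
II	59	103	1064	884	1286	388	230	236
III	0	0	1	9	3	22	43	17
IV	294	87	0	0	0	0	0	0
VII	0	1	0	0	0	0	1	13
XVI	0	1	0	0	0	0	0	0
XVII	0	0	2	0	9	0	10	150
CRD1	0	0	10	6	20	14	0	6
CRD2	0	0	11	0	0	10	6	1
WPC1	0	0	43	49	62	15	6	45
UC-A	0	0	45	48	58	35	8	0
Prochlorococcus	0	0	0	1	67	0	0	152
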