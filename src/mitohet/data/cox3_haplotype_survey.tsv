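population	n_isolates	haplotype_counts	het_genotypes
BS-BS	35	1:10;6:42;7:12;8:2;11:4
BS-CN	4	1:2;6:4;7:2
CX-CX	5	1:4;9:4;10:2
CX-LF	6	1:4;6:2;10:4;11:2
CX-NH	11	1:8;6:8;10:4;11:2
DL-DL	14	1:5;6:9;9:12;10:2	1/6
DL-MD	5	1:4;6:4;9:2
DL-SG	5	6:8;11:2
DL-XY	12	1:4;5:2;6:8;7:6;9:2;10:2
DL-YP	2	6:4
HH-GJ	15	1:14;6:6;7:4;9:4;11:2
HH-KY	25	1:15;5:6;6:4;7:2;8:2;9:6;10:1;11:14	1/10
HH-SP	2	7:2;10:2
KM-SM	8	1:4;3:1;4:2;6:4;10:2;11:2;12:1	6/11,4/12,4/11
KM-JN	13	1:10;6:12;8:2;10:2
KM-LQ	8	1:2;7:7;9:2;10:1;11:4	7/10
KM-SL	18	1:14;6:20;7:2
KM-XD	4	3:2;6:2;8:1;11:3	3/6,8/11,3/6
KM-YL	14	1:10;6:7;7:2;10:5;11:4	6/10
LC-LC	15	1:14;6:4;7:2;9:8;11:2
PE-AL	1	3:1;6:1	3/6
QJ-ML	1	11:2
QJ-SZ	17	6:8;7:2;8:2;11:22
WS-GN	2	1:2;2:2
YX-ES	11	1:4;6:2;7:6;11:10
YX-TH	3	1:4;10:2
YX-YM	28	1:10;6:14;7:7;9:7;10:2;11:16	7/9
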