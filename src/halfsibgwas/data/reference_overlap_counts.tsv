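trait	group	E	G	P	EG	EP	GP	EGP
MY	production	7	15	6	2	2	4	1
FY	production	4	2	0	1	0	0	0
PY	production	1	5	0	0	0	0	0
FPC	production	28	23	22	23	22	22	22
PPC	production	8	3	3	1	1	3	1
PL	production	6	10	1	3	0	1	0
SCS	production	6	7	0	0	0	0	0
DPR	production	7	8	2	3	2	2	2
SCE	production	8	3	2	0	2	0	0
DCE	production	3	3	0	1	0	0	0
SSB	production	8	6	6	2	6	2	2
DSB	production	6	11	2	0	0	0	0
NM	production	4	1	0	0	0	0	0
STA	conformation	11	24	1	5	1	0	0
STR	conformation	5	12	0	1	0	0	0
BD	conformation	7	14	0	2	0	0	0
RW	conformation	12	31	2	6	1	1	1
DF	conformation	8	7	1	1	1	1	1
RA	conformation	19	22	6	10	4	6	4
FUA	conformation	6	13	1	1	1	0	0
RUH	conformation	9	13	4	2	2	0	0
UD	conformation	5	14	0	3	0	0	0
UC	conformation	13	10	3	2	3	0	0
FTP	conformation	17	16	5	6	4	2	2
RTP	conformation	12	13	3	2	3	0	0
TL	conformation	16	8	5	3	5	1	1
FA	conformation	6	15	4	4	1	2	1
RLS	conformation	2	2	6	2	1	1	1
RLR	conformation	5	18	3	4	0	1	0
FL	conformation	11	14	3	6	2	2	2
FS	conformation	10	21	4	0	2	0	0
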