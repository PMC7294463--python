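gene	neonatal	uninjured_myelinating	uninjured_nonmyelinating	injured	fold_change	injured_highest
Angpt2	2.0	6.4	BT(0.4)	BT(1.7)	4.1	0
Artn	BT(0.0)	BT(0.0)	BT(0.0)	3.1	>3.1	1
Bdnf	BT(0.0)	BT(0.0)	BT(0.0)	9.3	>9.3	1
Bmp1	10.9	3.8	4.9	46.1	9.3	1
Btc	BT(0.8)	BT(0.0)	BT(0.0)	58.8	>58.8	1
Ccl11	BT(0.8)	3.8	4.5	5.6	1.2	1
Ccl2	BT(0.7)	BT(0.0)	BT(1.6)	12.7	7.7	1
Ccl3	BT(0.0)	BT(0.0)	BT(0.0)	3.9	>3.9	1
Ccl7	BT(0.2)	2.6	2.9	6.1	2.1	1
Ccl9	BT(0.0)	2.6	BT(0.4)	6.6	16.1	1
Clcf1	BT(0.2)	BT(0.0)	BT(0.0)	18.6	>18.6	1
Crlf1	BT(1.3)	BT(0.0)	2.5	30.5	12.4	1
Csf1	2.4	BT(1.3)	9.1	9.7	1.1	1
Ctgf	BT(0.1)	BT(0.0)	BT(0.0)	3.4	>3.4	1
Cx3cl1	BT(0.0)	2.6	BT(0.0)	BT(0.2)	NA	0
Cxcl1	BT(1.4)	6.4	11.9	10.7	0.9	0
Cxcl10	2.6	BT(0.0)	BT(0.4)	5.9	14.4	1
Cxcl12	BT(1.4)	2.6	12.3	5.4	0.4	0
Cxcl2	BT(0.1)	BT(0.0)	BT(0.0)	7.1	>7.1	1
Dhh	25.3	28.2	11.9	26.8	2.2	0
Eda	4.4	2.6	3.7	2.9	0.8	0
Efna2	2.8	BT(1.3)	BT(0.8)	3.2	3.9	1
Efna4	BT(1.0)	BT(1.3)	BT(0.0)	4.9	>4.9	1
Efna5	2.2	BT(0.0)	BT(0.0)	BT(0.3)	NA	0
Efnb1	8.9	2.6	7.0	10.0	1.4	1
Efnb2	BT(0.6)	BT(0.0)	BT(0.4)	3.9	9.5	1
Fgf1	5.4	28.2	10.7	BT(1.5)	0.1	0
Fgf5	BT(0.0)	BT(0.0)	BT(0.0)	18.3	>18.3	1
Fgf7	BT(1.3)	9.0	BT(0.8)	12.9	15.7	1
Fstl1	42.6	9.0	30.9	29.0	0.9	0
Gas6	BT(0.6)	6.4	2.9	2.5	0.9	0
Gdf11	BT(1.2)	BT(0.0)	BT(0.4)	3.1	7.4	1
Gdnf	BT(0.0)	BT(0.0)	BT(0.0)	20.5	>20.5	1
Gmfb	14.2	16.7	7.0	21.9	3.1	1
Hbegf	19.0	9.0	26.7	39.0	1.5	1
Igf1	2.1	BT(1.3)	3.3	15.4	4.7	1
Igf2	11.2	BT(1.3)	BT(1.2)	3.6	2.9	0
Il16	BT(0.7)	7.7	BT(0.4)	BT(0.3)	0.8	0
Il18	BT(0.3)	BT(0.0)	2.1	BT(0.5)	0.2	0
Il1b	BT(0.0)	BT(0.0)	BT(0.0)	3.7	>3.7	1
Il33	BT(0.2)	2.6	2.9	4.2	1.5	1
Jag1	BT(0.9)	BT(1.3)	BT(1.2)	6.9	5.6	1
Lif	BT(0.0)	BT(0.0)	BT(0.0)	4.9	>4.9	1
Mdk	20.6	BT(1.3)	3.3	25.3	7.7	1
Metrn	42.8	11.5	14.0	53.6	3.8	1
Mif	32.5	17.9	11.9	26.1	2.2	0
Nenf	24.3	19.2	27.2	47.3	1.7	1
Nov	2.7	14.1	7.8	4.2	0.5	0
Ntn1	BT(0.6)	BT(0.0)	BT(0.8)	3.2	3.9	1
Pdgfa	17.5	15.4	15.6	47.5	3.0	1
Pdgfb	BT(0.2)	BT(0.0)	BT(0.0)	2.2	>2.2	1
Pdgfc	2.2	BT(1.3)	BT(1.2)	BT(1.0)	0.8	0
Ptn	42.9	BT(0.0)	57.2	47.3	0.8	0
Rtn4	26.7	21.8	24.3	70.7	2.9	1
Sema3b	34.4	56.4	43.2	51.4	1.2	0
Sema3c	7.1	BT(1.3)	9.5	19.5	2.1	1
Sema3e	BT(1.0)	BT(0.0)	14.4	29.2	2.0	1
Sema3f	BT(0.4)	BT(0.0)	2.1	2.9	1.4	1
Sema3g	7.5	2.6	BT(1.6)	8.1	4.9	1
Sema4b	BT(0.4)	BT(0.0)	BT(0.8)	7.1	8.6	1
Sema4c	8.5	21.8	5.3	15.4	2.9	0
Sema4d	BT(0.9)	BT(0.0)	2.1	BT(1.0)	0.5	0
Sema4f	BT(0.0)	BT(0.0)	BT(0.0)	17.1	>17.1	1
Sema5a	BT(0.9)	10.3	BT(0.0)	BT(1.9)	>1.9	0
Sema5b	2.6	BT(0.0)	BT(0.0)	BT(0.2)	NA	0
Sema6a	4.5	2.6	2.9	8.0	2.8	1
Sema6c	BT(1.3)	7.7	BT(1.2)	2.0	1.6	0
Sema6d	16.5	11.5	25.5	14.1	0.6	0
Sema7a	2.1	BT(0.0)	9.5	17.1	1.8	1
Sfrp1	27.6	BT(0.0)	7.0	8.0	1.1	0
Sfrp2	BT(0.4)	5.1	3.7	2.0	0.5	0
Sfrp4	BT(1.3)	6.4	4.9	8.8	1.8	1
Sfrp5	8.1	30.8	28.0	5.1	0.2	0
Shh	BT(0.0)	BT(0.0)	BT(0.0)	12.0	>12.0	1
Tgfb1	BT(0.9)	BT(1.3)	BT(0.8)	9.8	11.9	1
Tgfb2	BT(0.6)	BT(0.0)	BT(0.8)	6.1	7.4	1
Tgfb3	BT(1.8)	BT(1.3)	BT(1.6)	4.2	2.6	1
Tnfsf12	3.2	9.0	9.5	6.3	0.7	0
Tnfsf9	BT(0.6)	BT(1.3)	5.3	BT(0.7)	0.1	0
Ucn2	BT(0.1)	BT(0.0)	BT(0.0)	14.1	>14.1	1
Vegfa	BT(1.1)	2.6	BT(0.8)	2.4	2.9	0
Vegfb	4.2	7.7	3.3	7.5	2.3	0
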