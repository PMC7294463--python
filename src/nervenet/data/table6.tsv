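gene	neonatal_epineurial	neonatal_endoneurial	inj_uninj_epineurial	perineurial	uninjured_endoneurial	injured_endoneurial	injured_differentiating	proliferating	fold_change
Adm	5.2	4.8	17.3	17.0	9.0	35.1	7.6	10.1	3.9
Agt	BT(1.7)	BT(0.5)	3.3	BT(0.0)	BT(1.9)	10.7	BT(1.7)	3.9	5.6
Angpt1	3.7	BT(0.5)	11.6	5.2	BT(0.7)	23.9	24.6	20.8	33.6
Angpt2	3.4	BT(0.0)	2.0	BT(1.3)	BT(0.5)	BT(1.0)	5.1	2.9	2.0
Angpt4	BT(0.5)	BT(0.0)	4.9	BT(1.3)	BT(0.2)	BT(0.4)	2.0	2.6	1.7
Apln	BT(0.7)	2.1	BT(0.5)	BT(0.7)	BT(0.7)	5.3	BT(1.9)	6.5	7.5
Bdnf	BT(0.6)	BT(1.1)	BT(0.2)	BT(0.7)	BT(0.0)	BT(1.9)	5.2	BT(1.6)	>1.9
Bmp1	34.3	12.7	51.4	52.9	16.4	37.2	52.3	47.6	2.3
Bmp2	BT(0.2)	BT(0.0)	2.9	BT(0.7)	BT(0.9)	3.1	BT(0.7)	3.9	3.3
Bmp4	2.6	2.6	11.7	BT(0.7)	6.6	BT(1.0)	BT(0.3)	BT(1.0)	0.1
Bmp5	BT(0.4)	BT(1.6)	BT(1.8)	BT(1.3)	6.6	4.0	BT(1.1)	BT(1.6)	0.6
Bmp7	BT(1.7)	6.3	BT(1.5)	8.5	12.1	30.1	BT(1.2)	5.9	2.5
Btc	BT(0.4)	BT(0.0)	BT(1.1)	BT(0.0)	BT(0.2)	BT(1.6)	BT(1.5)	4.6	6.9
Ccl11	18.0	70.9	42.6	19.0	89.3	85.9	21.4	40.4	1.0
Ccl19	BT(0.1)	BT(0.0)	4.9	BT(0.0)	BT(0.0)	BT(0.0)	BT(0.5)	BT(0.0)	NA
Ccl2	BT(0.7)	19.8	14.4	10.5	16.1	81.6	25.6	49.5	5.1
Ccl3	BT(0.1)	BT(0.0)	2.0	2.0	BT(0.0)	5.2	5.8	3.6	>5.2
Ccl5	BT(0.2)	BT(0.0)	2.2	BT(1.3)	BT(0.2)	3.0	2.5	3.3	12.7
Ccl7	6.0	29.1	12.7	10.5	36.0	77.3	23.8	44.6	2.1
Ccl9	BT(0.2)	2.9	5.2	2.6	16.8	72.1	12.0	26.1	4.3
Clcf1	BT(0.8)	BT(0.5)	BT(1.6)	BT(1.3)	BT(0.9)	4.4	5.0	5.2	4.6
Crlf1	BT(0.2)	BT(0.0)	BT(1.1)	5.2	BT(0.0)	26.1	3.4	11.1	>26.1
Csf1	12.2	3.4	40.9	11.8	10.9	31.0	24.0	30.9	2.8
Ctgf	7.3	BT(1.9)	18.9	19.0	2.4	37.2	29.2	25.4	15.7
Cx3cl1	BT(0.0)	BT(0.8)	BT(0.9)	BT(0.7)	BT(1.7)	14.3	8.6	4.2	8.6
Cxcl1	1.9	23.3	20.1	17.6	53.1	60.7	35.9	37.8	1.1
Cxcl10	BT(0.4)	BT(1.3)	BT(0.9)	BT(0.7)	BT(1.7)	9.6	3.5	6.5	5.8
Cxcl12	17.3	63.2	42.8	10.5	61.1	52.9	50.2	48.5	0.9
Cxcl13	BT(0.0)	BT(0.3)	17.6	BT(0.0)	BT(1.2)	BT(0.4)	BT(1.0)	BT(0.7)	0.3
Cxcl16	BT(0.8)	BT(1.3)	10.3	3.9	BT(1.7)	5.1	8.2	4.6	3.0
Cxcl2	BT(0.1)	BT(1.3)	7.1	6.5	BT(0.5)	24.7	12.8	20.2	52.2
Cxcl9	BT(1.0)	BT(1.9)	BT(1.4)	BT(0.0)	BT(0.5)	2.2	7.6	7.5	4.6
Dhh	BT(1.3)	2.4	BT(0.0)	BT(0.7)	BT(0.2)	BT(0.5)	BT(0.8)	2.3	2.3
Eda	8.2	10.6	4.0	19.6	7.8	9.4	7.7	7.5	1.2
Edn3	5.3	BT(0.5)	6.6	6.5	BT(1.7)	BT(0.3)	BT(1.6)	BT(1.0)	0.2
Efna1	4.1	3.7	3.2	5.9	4.0	7.8	3.9	4.2	1.9
Efna2	3.6	3.7	2.4	BT(1.3)	BT(1.2)	4.4	4.9	5.2	3.7
Efna4	4.2	BT(1.9)	2.5	6.5	BT(0.7)	6.1	9.0	3.9	8.6
Efna5	6.1	4.2	4.7	11.1	BT(1.2)	5.2	2.0	4.9	4.4
Efnb1	27.0	25.9	9.5	39.2	14.2	37.8	31.7	32.6	2.7
Efnb2	9.5	17.2	3.4	23.5	10.9	41.9	19.7	20.5	3.8
Fgf1	7.0	3.7	5.7	15.7	BT(0.9)	4.6	9.9	7.2	4.9
Fgf10	4.0	BT(0.0)	13.6	BT(0.0)	BT(0.0)	BT(0.7)	3.9	BT(1.6)	NA
Fgf18	6.6	BT(0.0)	11.7	4.6	BT(1.9)	BT(1.5)	5.9	6.2	0.8
Fgf5	BT(1.9)	BT(0.0)	BT(0.5)	BT(0.0)	BT(0.2)	BT(0.1)	2.1	2.0	0.6
Fgf7	21.3	4.0	27.8	23.5	6.6	35.9	24.2	25.1	5.4
Figf	6.1	BT(0.8)	21.2	5.9	2.1	9.7	10.2	15.6	4.5
Fstl1	96.2	92.3	96.9	86.3	76.1	94.7	96.1	90.6	1.2
Gas6	26.6	BT(0.5)	51.4	88.2	9.7	11.1	38.7	20.5	1.1
Gdf10	5.0	BT(0.3)	42.0	3.3	4.3	4.5	17.8	12.1	1.1
Gdf11	4.0	7.1	BT(1.6)	3.3	4.3	9.8	5.3	4.6	2.3
Gmfb	13.7	18.3	15.2	28.1	9.2	34.4	25.9	30.6	3.7
Gnrh1	BT(0.8)	BT(0.8)	BT(1.9)	3.3	BT(0.5)	2.2	BT(1.5)	BT(1.6)	4.6
Hbegf	2.3	2.1	BT(1.4)	BT(1.3)	2.4	4.9	9.3	13.4	2.1
Hgf	BT(0.4)	BT(0.0)	BT(1.2)	BT(0.7)	BT(0.2)	BT(0.8)	6.0	6.2	3.5
Igf1	44.2	82.8	75.8	17.6	45.0	85.1	84.1	63.8	1.9
Igf2	91.9	92.3	4.7	20.9	8.8	9.0	26.1	25.1	1.0
Il15	BT(0.6)	BT(1.3)	BT(1.4)	9.8	4.7	9.3	4.2	2.6	2.0
Il16	BT(0.4)	BT(0.5)	2.2	BT(0.7)	BT(1.2)	3.1	BT(1.3)	BT(1.0)	2.7
Il18	BT(0.3)	BT(0.3)	9.4	BT(0.7)	4.0	5.5	5.2	5.2	1.4
Il1b	BT(0.0)	BT(0.0)	2.3	BT(0.7)	BT(0.0)	7.4	5.9	7.2	>7.4
Il33	17.2	13.8	32.7	56.2	72.7	63.7	40.8	44.6	0.9
Il6	BT(0.2)	2.1	3.7	BT(0.0)	2.8	8.1	10.0	8.8	2.8
Inha	2.0	BT(1.3)	BT(1.9)	2.0	BT(1.2)	2.3	2.3	2.3	2.0
Inhba	3.4	BT(0.5)	2.1	6.5	BT(1.4)	12.8	15.8	23.5	9.0
Inhbb	BT(0.0)	BT(0.0)	BT(1.3)	2.6	BT(0.0)	12.8	BT(1.6)	2.3	>12.8
Jag1	22.3	13.8	13.4	25.5	4.5	16.7	23.4	23.1	3.7
Lif	BT(1.3)	BT(1.1)	2.4	BT(0.0)	3.1	11.6	2.1	6.2	3.8
Mdk	58.8	70.9	16.1	30.1	16.4	54.6	65.9	45.6	3.3
Metrn	5.2	10.3	3.1	5.9	BT(1.2)	13.3	5.1	23.5	11.2
Mif	21.1	30.4	18.6	15.0	14.9	42.2	42.5	54.7	2.8
Nenf	54.7	62.7	55.7	49.0	49.8	59.7	60.5	59.6	1.2
Ngf	2.3	13.5	BT(1.2)	8.5	2.6	7.7	BT(1.7)	6.8	2.9
Nov	16.7	5.6	30.0	BT(0.7)	8.1	9.7	17.6	22.5	1.2
Nppc	2.1	7.7	BT(0.3)	BT(0.0)	2.6	6.3	8.3	4.2	2.4
Ntf3	BT(1.3)	BT(0.5)	4.6	BT(0.0)	BT(0.7)	BT(1.4)	5.3	3.6	1.9
Ntn1	21.7	BT(0.5)	24.8	61.4	12.8	25.0	11.1	18.6	2.0
Pdgfa	4.0	2.6	6.5	9.8	BT(1.7)	7.9	11.0	25.1	4.8
Pdgfc	BT(0.7)	BT(0.3)	6.0	BT(0.0)	BT(0.2)	BT(1.4)	7.2	8.1	5.8
Pf4	BT(0.8)	BT(1.1)	2.0	BT(1.3)	BT(0.0)	4.0	3.7	4.9	>4.0
Pgf	BT(1.4)	BT(1.1)	2.0	3.3	5.0	12.7	2.5	3.9	2.6
Pomc	BT(0.3)	BT(1.1)	BT(0.9)	BT(0.7)	BT(1.4)	3.1	BT(1.2)	BT(1.3)	2.2
Pthlh	5.7	6.3	9.8	20.3	7.6	13.8	13.4	11.1	1.8
Ptn	21.1	21.7	15.5	2.6	4.0	11.1	56.8	45.6	2.7
Rspo1	11.5	BT(0.0)	3.2	20.9	BT(1.2)	BT(0.5)	BT(0.5)	BT(0.3)	0.5
Rspo3	BT(0.4)	BT(0.0)	3.1	BT(1.3)	BT(0.0)	BT(0.7)	11.6	6.2	NA
Rtn4	35.1	36.2	47.9	43.8	33.9	68.6	60.5	72.3	2.0
Sema3b	5.2	9.3	14.0	11.1	33.4	11.3	5.0	6.5	0.3
Sema3c	43.0	14.8	50.5	18.3	9.2	8.6	23.0	27.7	0.9
Sema3d	18.0	3.7	11.4	45.1	BT(0.7)	BT(1.8)	6.3	7.8	2.5
Sema3e	BT(0.7)	BT(0.3)	3.7	BT(0.0)	BT(0.2)	BT(0.1)	BT(1.0)	2.9	0.6
Sema3f	2.2	BT(0.5)	BT(1.1)	2.6	BT(0.7)	4.5	2.0	3.3	6.3
Sema3g	BT(0.3)	BT(1.3)	BT(0.6)	BT(0.0)	3.1	2.7	BT(1.0)	2.0	0.9
Sema4a	BT(0.8)	BT(1.9)	BT(0.6)	4.6	BT(1.7)	3.3	BT(1.3)	BT(1.6)	2.0
Sema4b	BT(1.7)	BT(0.3)	BT(1.5)	2.0	2.1	2.9	2.6	2.3	1.3
Sema4c	5.8	5.8	5.9	13.1	6.4	11.7	9.3	10.1	1.8
Sema5a	4.7	7.4	BT(1.8)	4.6	3.6	3.6	6.1	5.9	1.0
Sema5b	5.6	9.5	BT(0.2)	BT(0.0)	BT(1.2)	BT(1.1)	BT(1.6)	5.2	0.9
Sema6a	6.2	9.8	3.1	7.8	19.0	14.6	3.2	7.5	0.8
Sema6b	BT(0.1)	BT(0.3)	2.5	BT(0.0)	2.8	7.1	BT(1.3)	7.8	2.5
Sema6c	4.3	4.8	5.4	BT(1.3)	3.3	3.4	8.0	6.2	1.0
Sema6d	2.2	3.2	3.7	7.8	3.6	11.2	3.7	9.4	3.2
Sema7a	BT(0.3)	BT(0.5)	BT(1.3)	BT(0.7)	BT(0.9)	19.4	11.0	21.5	20.5
Sfrp1	60.0	29.1	40.0	54.2	15.2	32.9	50.0	32.6	2.2
Sfrp2	11.4	BT(0.3)	47.8	3.9	5.5	7.1	21.7	18.6	1.3
Sfrp4	33.6	BT(1.9)	72.4	32.7	9.0	50.7	56.8	39.1	5.6
Sfrp5	26.7	2.6	2.6	94.8	5.9	2.6	6.3	10.4	0.4
Tgfb1	BT(0.6)	BT(0.3)	2.4	3.3	3.3	11.1	10.0	15.3	3.3
Tgfb2	10.3	BT(1.1)	10.5	3.3	2.8	3.7	17.0	12.1	1.3
Tgfb3	20.6	3.4	16.8	19.0	2.4	9.0	36.1	19.2	3.8
Tnf	BT(0.0)	BT(0.3)	BT(1.7)	BT(0.7)	BT(0.0)	2.5	BT(0.7)	2.6	>2.5
Tnfrsf11b	BT(1.9)	BT(0.0)	4.6	8.5	BT(0.5)	BT(0.7)	4.4	10.7	1.4
Tnfsf10	BT(0.0)	BT(0.0)	BT(0.4)	2.0	BT(1.7)	BT(0.7)	BT(0.2)	BT(1.0)	0.4
Tnfsf12	9.6	11.6	15.7	15.0	17.8	17.3	14.6	14.7	1.0
Tnfsf8	BT(0.3)	BT(0.0)	BT(0.8)	10.5	BT(0.0)	2.2	5.7	3.3	>2.2
Tnfsf9	BT(0.5)	BT(1.6)	BT(1.4)	BT(1.3)	4.0	5.9	4.5	7.2	1.5
Tslp	BT(1.2)	2.4	4.0	2.6	BT(0.2)	4.8	BT(1.2)	2.9	20.2
Vegfa	11.0	4.8	25.0	3.9	8.3	18.2	29.6	27.0	2.2
Vegfb	5.2	9.0	5.4	9.8	4.7	7.1	8.3	11.4	1.5
Vegfc	BT(0.7)	BT(0.0)	2.2	BT(0.7)	BT(0.2)	BT(0.7)	2.2	5.5	2.9
Wnt11	BT(1.2)	BT(0.0)	6.2	BT(0.0)	BT(0.5)	BT(0.5)	BT(0.9)	2.9	1.2
Wnt2	6.0	BT(0.3)	9.1	BT(0.0)	BT(0.2)	BT(1.5)	4.6	4.9	6.3
Wnt5a	15.5	4.0	19.1	7.8	10.4	13.9	13.0	14.0	1.3
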