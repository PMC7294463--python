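gene	mark	epineurial	endoneurial_perineurial	vsm_pericytes	endothelial	schwann	immune
Adm	**	5.1	4.7	BT	3.0	BT	BT
Agt	*	2.5	BT	12.2	BT	BT	BT
Angpt1	*	5.1	BT	11.1	BT	BT	BT
Angpt2	*	5.5	BT	18.1	6.9	2.0	BT
Apln		BT	BT	BT	29.0	BT	BT
Bdnf		BT	BT	3.6	BT	BT	BT
Bmp1	**	34.2	21.5	10.9	11.0	10.8	BT
Bmp2		BT	BT	6.7	3.4	BT	8.7
Bmp4	*	3.4	BT	BT	6.9	BT	BT
Bmp5		BT	BT	13.4	BT	BT	BT
Bmp7	**	BT	3.9	BT	BT	BT	BT
Ccl11	**	9.4	49.8	20.0	BT	BT	2.6
Ccl2	*	BT	10.0	9.9	BT	BT	20.0
Ccl24		BT	BT	BT	BT	BT	27.0
Ccl3		BT	BT	BT	BT	BT	16.5
Ccl5		BT	BT	BT	BT	BT	2.6
Ccl7	**	3.4	18.5	2.7	BT	BT	14.8
Ccl9		BT	BT	BT	BT	BT	28.7
Clcf1		BT	BT	BT	2.3	BT	BT
Csf1	**	15.2	4.3	4.8	4.1	2.4	BT
Ctgf	*	7.1	4.0	7.4	7.4	BT	BT
Cxcl1	*	BT	12.4	20.6	2.5	BT	2.6
Cxcl10		BT	BT	BT	BT	2.6	BT
Cxcl12	**	18.9	37.2	23.1	33.8	BT	BT
Cxcl16		BT	BT	BT	4.2	BT	11.3
Cxcl2		BT	BT	BT	BT	BT	4.3
Cxcl9	**	BT	2.1	BT	BT	BT	BT
Dhh		BT	BT	2.3	7.1	25.6	3.5
Dll1		BT	BT	BT	5.3	BT	BT
Dll4		BT	BT	BT	15.2	BT	BT
Ebi3		BT	BT	BT	BT	BT	13.0
Eda	**	7.1	9.0	BT	BT	4.4	BT
Edn3	**	4.1	3.5	BT	BT	BT	BT
Efna1	*	3.1	4.3	BT	34.0	BT	BT
Efna2	**	2.9	3.3	BT	BT	2.9	BT
Efna4	**	2.6	3.6	BT	BT	BT	BT
Efna5	**	6.0	4.0	BT	BT	2.3	BT
Efnb1	**	18.3	30.6	6.3	9.7	9.1	2.6
Efnb2	**	5.4	15.1	4.8	16.3	BT	BT
Fgf1	**	5.1	5.6	3.6	BT	5.4	3.5
Fgf10	**	5.7	BT	BT	BT	BT	BT
Fgf18	**	7.8	BT	BT	BT	BT	BT
Fgf7	**	21.0	10.3	BT	BT	BT	BT
Figf	**	3.8	4.8	BT	BT	BT	BT
Fstl1	**	96.0	92.2	72.9	59.3	43.0	11.3
Gas6	*	22.4	14.3	7.4	24.6	BT	45.2
Gdf10	**	8.4	BT	BT	BT	BT	BT
Gdf11	**	BT	6.6	3.8	2.7	BT	BT
Gmfb	**	9.5	17.6	6.1	13.8	14.1	9.6
Gmfg		BT	BT	BT	6.4	BT	36.5
Grp		BT	BT	BT	2.1	BT	BT
Hbegf	*	BT	2.5	14.3	15.0	19.2	3.5
Igf1	**	56.0	52.0	4.6	16.6	2.0	40.0
Igf2	**	92.3	89.5	54.0	69.7	11.1	25.2
Il15		BT	BT	BT	BT	BT	4.3
Il16		BT	BT	BT	4.6	BT	12.2
Il18		BT	BT	BT	BT	BT	9.6
Il1b		BT	BT	BT	BT	BT	3.5
Il33	**	13.7	16.1	BT	BT	BT	BT
Inha	**	2.6	BT	BT	BT	BT	BT
Inhba	**	4.1	BT	BT	BT	BT	BT
Inhbb		BT	BT	8.0	BT	BT	BT
Jag1	**	18.4	19.1	15.5	11.0	BT	BT
Jag2		BT	BT	BT	7.1	BT	BT
Ltb		BT	BT	BT	BT	BT	2.6
Mdk	**	52.3	68.1	20.2	8.8	20.9	8.7
Metrn	*	3.4	8.7	10.5	5.0	43.2	10.4
Mif	*	17.5	26.4	28.8	26.0	32.8	26.1
Nenf	**	54.3	54.6	39.7	28.8	24.5	BT
Ngf	**	BT	8.7	8.0	BT	BT	0.0
Nov	**	23.8	4.3	3.8	3.4	2.8	3.5
Nppc	**	BT	6.1	BT	BT	BT	BT
Ntf3		BT	BT	2.3	BT	BT	BT
Ntn1	**	22.2	10.0	BT	BT	BT	BT
Osm		BT	BT	BT	BT	BT	3.5
Pdgfa	*	3.4	3.6	30.5	3.0	17.8	BT
Pdgfb		BT	BT	2.9	21.9	BT	BT
Pdgfc		BT	BT	3.2	BT	2.2	2.6
Pf4		BT	BT	BT	BT	BT	61.7
Pgf		BT	BT	3.8	BT	BT	BT
Pthlh	**	7.1	4.0	BT	BT	BT	BT
Ptn	*	29.3	13.9	6.5	15.9	43.4	4.3
Rspo1	**	7.8	6.5	BT	BT	BT	BT
Rtn4	*	31.0	38.2	35.7	40.4	26.8	38.3
Sema3b	*	5.4	6.5	2.3	2.8	34.7	7.8
Sema3c	**	51.7	19.2	BT	BT	7.1	3.5
Sema3d	**	10.4	15.9	BT	BT	BT	BT
Sema3f	*	2.6	BT	BT	2.8	BT	BT
Sema3g		BT	BT	BT	9.6	7.5	BT
Sema4a		BT	BT	BT	BT	BT	10.4
Sema4b		BT	BT	BT	BT	BT	3.5
Sema4c	*	5.1	5.7	2.7	8.1	8.5	5.2
Sema4d		BT	BT	BT	BT	BT	7.8
Sema5a	*	5.4	5.5	12.4	BT	BT	BT
Sema5b	*	4.4	8.6	14.1	BT	2.6	BT
Sema6a	*	4.4	7.9	BT	22.8	4.5	BT
Sema6b		BT	BT	BT	2.5	BT	BT
Sema6c	**	4.9	3.3	2.5	BT	BT	BT
Sema6d	*	2.0	3.0	4.4	6.4	16.7	8.7
Sema7a		BT	BT	2.1	17.3	2.0	BT
Sfrp1	**	50.5	48.5	2.9	4.1	28.0	3.5
Sfrp2	**	17.2	BT	BT	BT	BT	BT
Sfrp4	**	43.7	5.5	BT	BT	BT	2.6
Sfrp5	**	5.4	30.7	BT	BT	8.1	2.6
Tgfb1		BT	BT	BT	10.3	BT	20.9
Tgfb2	*	12.1	2.7	18.3	9.9	BT	BT
Tgfb3	**	21.5	8.3	10.9	BT	BT	BT
Tnf		BT	BT	BT	BT	BT	6.1
Tnfrsf11b	*	2.9	BT	BT	3.9	BT	BT
Tnfsf10		BT	BT	BT	6.4	BT	BT
Tnfsf12	**	8.0	10.8	5.5	6.5	3.2	4.3
Tnfsf9		BT	BT	BT	BT	BT	4.3
Tslp		BT	BT	2.7	2.8	BT	3.5
Vegfa	**	16.0	3.6	3.8	3.2	BT	BT
Vegfb	**	4.0	7.7	6.3	5.5	4.3	6.1
Vegfc		BT	BT	BT	8.5	BT	BT
Wnt11		BT	BT	2.7	BT	BT	BT
Wnt2	**	7.5	BT	BT	BT	BT	BT
Wnt5a	**	17.0	6.8	BT	BT	BT	BT
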