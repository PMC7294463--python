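gene	mark	epineurial_perineurial	endoneurial	vsm_pericytes	endothelial	schwann_nonmyelinating	schwann_myelinating	immune
Adm	**	14.4	8.4	BT	3.6	BT	BT	2.9
Agt	**	2.9	BT	BT	BT	BT	BT	2.9
Angpt1	*	12.2	BT	12.4	BT	BT	BT	BT
Angpt2	*	2.2	BT	21.1	13.6	BT	6.0	BT
Angpt4	**	6.2	BT	BT	BT	BT	BT	2.9
Apln		BT	BT	BT	7.1	BT	BT	BT
Bdnf		BT	BT	3.1	BT	BT	BT	BT
Bmp1	**	42.0	16.1	6.8	6.2	4.6	4.8	BT
Bmp2	*	3.5	BT	15.5	BT	BT	BT	11.4
Bmp4	**	18.6	6.5	BT	17.6	BT	BT	BT
Bmp5	*	2.4	6.8	8.1	BT	BT	BT	BT
Bmp7	**	3.1	11.9	BT	BT	BT	BT	BT
Cck		BT	BT	3.1	BT	BT	BT	BT
Ccl11	**	35.8	88.3	22.4	9.0	5.3	3.6	2.9
Ccl19	**	6.2	BT	5.0	BT	BT	BT	BT
Ccl2	*	2.2	16.1	4.3	BT	BT	BT	28.6
Ccl3		BT	BT	BT	BT	BT	BT	11.4
Ccl5		BT	BT	BT	BT	BT	BT	11.4
Ccl7	**	6.0	35.5	2.5	5.0	2.7	3.6	8.6
Ccl9	**	BT	16.6	BT	BT	BT	2.4	14.3
Clcf1		BT	BT	BT	4.0	BT	BT	2.9
Csf1	**	31.9	10.0	4.3	15.2	8.8	2.4	8.6
Ctgf	*	16.6	2.1	10.6	28.8	BT	BT	BT
Cx3cl1		BT	BT	BT	11.2	BT	2.4	BT
Cxcl1	**	17.5	52.3	18.6	15.0	11.5	6.0	8.6
Cxcl10		BT	BT	BT	BT	BT	BT	5.7
Cxcl12	*	34.3	60.0	39.8	78.1	13.4	3.6	2.9
Cxcl13	**	16.2	BT	BT	BT	BT	BT	BT
Cxcl16	**	10.0	BT	BT	3.3	BT	BT	2.9
Cxcl2		BT	BT	BT	BT	BT	BT	8.6
Cxcl9		BT	BT	BT	3.8	BT	BT	BT
Dhh		BT	BT	BT	3.8	13.4	28.9	BT
Dll1		BT	BT	BT	10.0	BT	BT	BT
Dll4		BT	BT	BT	18.1	BT	BT	BT
Eda	**	5.1	7.7	BT	BT	3.4	2.4	2.9
Edn3	**	8.4	BT	BT	BT	BT	BT	BT
Efna1	*	4.2	4.0	3.7	30.2	BT	BT	BT
Efna2		BT	BT	BT	BT	BT	BT	2.9
Efna5	**	4.4	BT	BT	BT	BT	BT	BT
Efnb1	**	9.5	14.3	2.5	10.5	6.1	3.6	2.9
Efnb2	*	3.5	11.0	4.3	15.7	BT	BT	BT
Fgf1	*	4.9	BT	10.6	BT	10.3	26.5	2.9
Fgf10	**	9.1	BT	BT	BT	BT	BT	BT
Fgf18	**	8.4	BT	BT	BT	BT	BT	BT
Fgf7	**	28.8	6.3	2.5	2.4	BT	8.4	BT
Figf	**	12.8	BT	BT	3.1	BT	BT	BT
Fstl1	**	90.9	75.5	47.2	34.5	29.8	10.8	8.6
Gas6	**	61.5	9.3	18.0	49.8	3.8	6.0	2.9
Gdf10	**	39.4	4.0	BT	3.1	BT	2.4	2.9
Gdf11	*	BT	4.2	4.3	BT	BT	BT	2.9
Gmfb	*	14.2	8.6	5.6	10.5	7.6	15.7	5.7
Gmfg		BT	BT	BT	3.1	BT	BT	28.6
Hbegf	*	BT	2.3	12.4	17.4	25.2	8.4	5.7
Igf1	**	56.9	43.9	8.1	17.6	2.7	BT	BT
Igf2	*	3.5	8.6	7.5	14.3	BT	BT	BT
Il15	*	BT	4.7	BT	5.0	BT	BT	BT
Il16		BT	BT	BT	3.1	BT	8.4	25.7
Il18	**	7.1	3.7	BT	BT	BT	BT	BT
Il1b		BT	BT	BT	BT	BT	BT	8.6
Il33	**	29.4	71.5	BT	5.0	3.4	2.4	2.9
Il6	*	2.4	2.8	4.3	5.2	BT	BT	BT
Inha	**	2.0	BT	BT	BT	BT	BT	BT
Inhba		BT	BT	8.1	BT	BT	BT	BT
Jag1	*	12.4	4.2	20.5	19.3	BT	BT	BT
Jag2		BT	BT	BT	9.5	BT	BT	BT
Lif	**	BT	3.0	BT	BT	BT	BT	2.9
Ltb		BT	BT	BT	BT	BT	BT	11.4
Mdk	**	8.2	16.4	BT	BT	3.4	BT	2.9
Metrn	*	2.7	BT	2.5	BT	14.5	12.0	2.9
Mif	*	14.8	14.7	19.3	31.0	13.7	18.1	31.4
Nenf	**	54.2	48.6	28.0	31.0	26.7	19.3	17.1
Ngf	*	BT	2.6	11.2	BT	BT	BT	BT
Nov	**	19.2	7.9	6.8	5.0	7.3	15.7	BT
Nppc	**	BT	2.6	BT	BT	BT	BT	BT
Ntf3	*	4.0	BT	11.8	5.7	BT	BT	BT
Ntn1	**	31.2	12.6	BT	6.7	BT	BT	BT
Osm		BT	BT	BT	BT	BT	BT	8.6
Pdgfa	*	7.3	BT	32.9	9.8	14.1	16.9	5.7
Pdgfb		BT	BT	3.1	28.1	BT	BT	BT
Pdgfc	**	3.3	BT	BT	BT	BT	BT	2.9
Pgf	*	2.4	4.7	7.5	BT	BT	BT	BT
Pomc		BT	BT	BT	5.0	BT	BT	2.9
Pthlh	**	12.6	7.2	BT	BT	BT	BT	BT
Ptn	*	7.7	4.0	BT	45.7	56.5	BT	5.7
Rspo1	**	8.4	BT	BT	BT	BT	BT	BT
Rtn4	**	37.6	33.4	21.7	33.8	24.0	21.7	11.4
Sema3b	*	15.5	32.7	3.1	3.1	44.3	56.6	BT
Sema3c	**	38.1	9.1	2.5	3.6	9.2	2.4	BT
Sema3d	**	13.7	BT	BT	BT	BT	BT	BT
Sema3e	*	3.5	BT	BT	BT	14.5	BT	BT
Sema3f		BT	BT	2.5	12.6	BT	BT	BT
Sema3g	*	BT	3.0	BT	18.8	2.7	2.4	BT
Sema4a		BT	BT	BT	BT	BT	BT	5.7
Sema4b	**	2.0	2.1	BT	BT	BT	BT	BT
Sema4c	*	6.6	6.3	BT	11.2	5.7	22.9	BT
Sema4d		BT	BT	BT	BT	2.3	BT	8.6
Sema5a	*	2.7	3.5	6.8	BT	BT	9.6	BT
Sema6a	*	2.7	18.7	BT	26.2	2.7	2.4	2.9
Sema6b	*	2.0	2.8	BT	12.4	BT	BT	2.9
Sema6c	*	BT	3.3	BT	BT	BT	7.2	BT
Sema6d	*	3.3	3.5	8.1	9.5	25.2	13.3	BT
Sema7a		BT	BT	BT	28.8	8.4	BT	2.9
Sfrp1	**	45.4	15.0	2.5	4.0	6.9	BT	BT
Sfrp2	**	45.1	5.1	BT	5.2	3.8	6.0	5.7
Sfrp4	**	61.7	8.6	3.1	9.8	5.3	6.0	8.6
Sfrp5	*	18.8	5.8	3.7	4.5	26.0	31.3	5.7
Tgfa		BT	BT	BT	4.0	BT	BT	BT
Tgfb1	*	2.0	3.3	BT	7.9	BT	BT	17.1
Tgfb2	**	8.2	2.8	5.6	6.0	BT	BT	BT
Tgfb3	**	16.8	2.3	16.1	3.1	BT	BT	BT
Tnf		BT	BT	BT	BT	BT	BT	11.4
Tnfsf10		BT	BT	BT	18.6	BT	BT	BT
Tnfsf12	**	13.3	17.8	6.2	12.6	9.9	9.6	5.7
Tnfsf14		BT	BT	BT	BT	BT	BT	8.6
Tnfsf9	*	BT	4.0	BT	BT	5.7	BT	BT
Tslp	**	3.5	BT	BT	BT	BT	BT	2.9
Vegfa	**	14.2	7.9	8.1	6.2	BT	2.4	2.9
Vegfb	*	5.5	4.7	6.2	5.7	3.4	7.2	BT
Vegfc	*	3.3	BT	BT	6.2	BT	BT	BT
Wnt11	**	6.6	BT	BT	BT	BT	BT	2.9
Wnt2	**	6.9	BT	BT	BT	BT	BT	BT
Wnt5a	**	17.5	10.3	BT	BT	BT	BT	BT
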