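gene	mark	epineurial_perineurial	endoneurial	combined_mesenchymal	vsm_pericytes	endothelial	schwann	immune
Adm	**	11.6	34.2	17.4	2.8	BT	BT	BT
Agt	*	2.2	10.4	4.2	13.2	BT	BT	BT
Angpt1	**	17.3	23.7	18.9	21.1	2.1	BT	BT
Angpt2	*	3.2	BT	2.6	29.0	18.5	BT	BT
Angpt4	**	2.6	BT	2.0	BT	BT	BT	BT
Apln	*	2.0	6.0	3.0	BT	11.2	BT	BT
Artn		BT	BT	BT	BT	BT	3.3	BT
Bdnf	*	2.6	BT	2.3	2.2	BT	9.5	BT
Bmp1	**	53.1	35.7	48.7	14.8	10.8	50.6	2.7
Bmp2	*	BT	3.0	2.1	24.6	3.3	BT	BT
Bmp4	*	2.8	BT	2.3	BT	16.6	BT	BT
Bmp5	*	BT	3.8	BT	11.7	BT	BT	BT
Bmp7	**	2.2	31.1	9.5	BT	BT	BT	BT
Btc	*	BT	2.0	2.0	BT	BT	60.4	BT
Cck		BT	BT	BT	5.0	BT	BT	BT
Ccl11	**	29.4	87.0	44.0	34.1	7.5	6.2	4.7
Ccl19		BT	BT	BT	2.5	BT	BT	BT
Ccl2	**	27.0	81.5	40.9	21.1	12.9	13.8	15.2
Ccl24		BT	BT	BT	BT	BT	BT	2.4
Ccl25		BT	BT	BT	BT	BT	2.2	BT
Ccl3	*	3.0	4.2	3.3	3.2	2.3	3.1	13.7
Ccl5	*	3.0	2.8	2.9	BT	BT	BT	6.4
Ccl7	**	21.8	78.0	36.1	10.4	7.7	6.6	7.7
Ccl9	**	11.8	75.0	27.9	4.1	6.1	5.9	22.5
Clcf1	*	3.7	4.5	3.9	BT	4.3	16.0	BT
Crlf1	*	3.2	25.9	9.0	BT	BT	35.2	BT
Csf1	**	32.3	31.2	32.0	13.9	11.7	11.6	3.3
Ctgf	**	25.7	36.9	28.5	25.6	33.3	3.5	2.2
Cx3cl1	**	4.0	14.4	6.7	BT	5.3	BT	BT
Cxcl1	**	27.4	59.3	35.5	38.2	29.0	11.7	9.5
Cxcl10	**	2.6	9.8	4.4	3.2	4.1	6.6	2.0
Cxcl12	**	46.6	52.6	48.1	33.8	44.0	5.9	5.0
Cxcl13	**	6.7	BT	5.1	BT	BT	BT	BT
Cxcl16	*	6.3	4.2	5.7	2.8	3.7	BT	15.7
Cxcl2	*	12.3	22.9	15.0	7.3	10.4	7.2	22.9
Cxcl9	**	5.3	2.7	4.6	BT	4.6	BT	BT
Dhh		BT	BT	BT	BT	6.3	30.1	BT
Dll1		BT	BT	BT	BT	6.4	BT	BT
Dll4		BT	BT	BT	BT	10.0	BT	BT
Ebi3		BT	BT	BT	BT	BT	BT	2.5
Eda	**	6.0	9.7	7.0	BT	BT	3.7	BT
Edn3	**	3.1	BT	2.3	BT	BT	BT	BT
Efna1	*	3.4	8.0	4.5	BT	24.9	BT	BT
Efna2	**	3.3	3.8	3.4	2.5	BT	3.5	BT
Efna4	**	4.8	6.2	5.2	3.2	BT	4.0	BT
Efna5	**	5.1	6.7	5.5	BT	BT	BT	BT
Efnb1	**	22.5	39.2	26.8	9.5	11.4	11.4	2.3
Efnb2	**	13.0	42.4	20.4	4.1	16.4	4.0	BT
Fgf1	*	7.1	4.8	6.5	9.8	BT	2.2	BT
Fgf10	**	7.5	BT	5.8	BT	BT	BT	BT
Fgf18	**	8.5	BT	6.8	BT	BT	BT	BT
Fgf5		BT	BT	BT	BT	BT	19.4	BT
Fgf7	**	26.1	37.7	29.1	3.2	BT	12.5	BT
Figf	**	15.8	11.2	14.6	BT	BT	BT	BT
Fstl1	**	96.8	96.5	96.7	85.8	56.5	33.4	19.6
Gas6	**	44.3	2.3	35.9	13.6	22.5	2.2	6.2
Gdf10	**	24.5	4.7	19.5	BT	3.3	2.0	BT
Gdf11	**	4.3	10.4	5.9	10.1	3.4	3.9	BT
Gdnf		BT	BT	BT	BT	BT	21.8	BT
Gmfb	**	23.4	34.6	26.3	10.7	17.5	27.9	11.6
Gmfg		BT	BT	BT	BT	5.7	BT	17.9
Gnrh1	**	BT	2.3	BT	BT	BT	BT	BT
Grp		BT	BT	BT	BT	3.4	BT	BT
Hbegf	*	6.5	5.2	6.2	10.7	19.2	43.9	BT
Hgf	**	4.0	BT	3.1	BT	BT	BT	BT
Igf1	**	76.6	84.3	78.6	15.8	31.7	16.7	13.8
Igf2	*	15.5	8.2	13.6	16.4	6.1	2.4	BT
Il15	**	2.2	9.0	3.9	BT	7.4	BT	BT
Il16	*	BT	3.0	BT	BT	2.3	BT	7.9
Il18	**	6.4	5.3	6.1	BT	BT	BT	2.5
Il1b	*	5.6	7.3	6.1	5.0	5.7	5.0	18.6
Il33	**	39.1	63.3	45.3	2.5	3.6	6.4	2.2
Il6	*	7.2	7.0	7.1	12.6	15.2	BT	BT
Inha	**	BT	2.0	BT	BT	BT	BT	BT
Inhba	**	12.6	11.9	12.4	9.8	BT	BT	1.9
Inhbb	**	BT	12.7	4.5	BT	9.2	BT	BT
Jag1	*	20.3	17.2	19.5	33.1	17.8	8.4	2.8
Jag2		BT	BT	BT	BT	8.4	BT	BT
Lif	**	2.6	13.2	5.3	BT	BT	5.9	BT
Ltb		BT	BT	BT	BT	BT	BT	12.2
Mdk	**	39.0	51.1	42.1	9.1	4.0	25.1	BT
Metrn	*	7.1	14.5	9.0	8.5	3.0	57.8	2.6
Mif	**	32.7	40.2	34.6	26.5	31.4	29.5	26.0
Nenf	**	54.7	59.1	55.8	42.6	29.4	50.8	8.4
Ngf	*	2.4	6.7	3.5	10.4	BT	BT	BT
Nov	**	25.0	11.4	21.5	6.0	5.4	5.0	BT
Nppc	**	2.2	5.3	3.0	BT	BT	BT	BT
Ntf3	*	3.4	BT	2.9	4.4	4.8	BT	BT
Ntn1	**	19.2	25.5	20.8	BT	6.0	4.6	BT
Osm		BT	BT	BT	BT	BT	BT	8.3
Pdgfa	*	12.1	7.8	11.0	49.5	6.8	50.6	5.7
Pdgfb		BT	BT	BT	2.5	22.3	BT	2.4
Pdgfc	**	7.2	BT	5.8	6.0	4.3	BT	BT
Pf4	*	2.3	4.3	2.8	BT	BT	BT	10.0
Pgf	**	2.0	12.2	4.6	7.6	BT	BT	BT
Pomc	**	BT	3.3	BT	BT	3.3	2.2	BT
Pthlh	**	10.4	13.7	11.2	BT	BT	2.4	BT
Ptn	*	35.9	10.4	29.4	2.2	19.9	52.5	BT
Rspo1	**	2.2	BT	BT	BT	BT	BT	BT
Rspo3	**	6.0	BT	4.7	BT	2.4	BT	BT
Rtn4	*	57.9	68.3	60.5	51.7	47.1	73.6	28.3
Sema3b	*	7.7	12.4	8.9	BT	BT	53.8	BT
Sema3c	**	35.4	9.0	28.7	BT	BT	25.1	BT
Sema3d	**	9.6	2.0	7.6	BT	BT	BT	BT
Sema3e	*	2.0	BT	BT	BT	BT	31.0	BT
Sema3f	*	2.3	4.5	2.9	2.8	14.5	2.9	BT
Sema3g	*	BT	3.0	BT	BT	11.8	9.0	BT
Sema4a	*	BT	3.7	2.0	BT	BT	BT	6.9
Sema4b	*	2.0	3.2	2.3	3.5	BT	7.7	BT
Sema4c	*	8.4	12.0	9.3	6.3	10.2	16.0	BT
Sema4d		BT	BT	BT	BT	BT	BT	14.5
Sema4f		BT	BT	BT	BT	BT	18.3	BT
Sema5a	*	4.3	3.5	4.1	13.2	BT	BT	BT
Sema5b		BT	BT	BT	10.4	BT	BT	BT
Sema6a	*	4.0	14.5	6.7	BT	35.6	9.4	BT
Sema6b	*	3.1	7.0	4.1	BT	18.1	BT	BT
Sema6c	**	7.2	4.0	6.4	BT	BT	2.0	BT
Sema6d	*	5.9	11.7	7.3	18.9	9.5	16.7	BT
Sema7a	*	7.5	19.5	10.5	BT	17.4	20.0	BT
Sfrp1	**	42.3	31.9	39.6	4.1	3.4	8.8	BT
Sfrp2	**	29.6	6.5	23.8	2.2	3.3	BT	2.4
Sfrp4	**	61.5	51.9	59.1	8.5	9.4	11.0	6.3
Sfrp5	**	8.8	3.2	7.4	BT	2.1	8.1	BT
Shh		BT	BT	BT	BT	BT	12.8	BT
Tgfa		BT	BT	BT	BT	2.6	BT	BT
Tgfb1	*	6.5	12.0	7.9	6.0	13.4	10.3	12.4
Tgfb2	*	13.3	2.7	10.6	16.4	5.1	6.2	BT
Tgfb3	*	26.3	8.7	21.8	27.4	2.3	4.6	BT
Tnf	*	BT	2.2	BT	BT	BT	BT	7.7
Tnfrsf11b	**	6.6	BT	5.0	BT	BT	BT	BT
Tnfsf10		BT	BT	BT	BT	22.8	1.1	BT
Tnfsf12	**	15.0	16.7	15.4	11.4	9.1	6.8	7.3
Tnfsf14		BT	BT	BT	BT	BT	BT	2.3
Tnfsf8	**	3.8	2.0	3.3	BT	BT	BT	BT
Tnfsf9	**	2.8	5.8	3.6	5.4	BT	BT	BT
Tslp	**	2.5	4.8	3.1	2.8	2.4	BT	BT
Ucn2		BT	BT	BT	BT	BT	15.0	BT
Vegfa	**	28.2	18.7	25.8	3.8	4.1	2.6	7.0
Vegfb	*	7.1	7.0	7.0	7.3	6.0	8.4	3.3
Vegfc	*	2.0	BT	BT	BT	5.5	BT	BT
Wnt11	**	2.7	BT	2.2	BT	BT	BT	BT
Wnt2	**	6.5	BT	5.3	BT	BT	BT	BT
Wnt5a	**	15.9	14.4	15.5	4.4	BT	BT	BT
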