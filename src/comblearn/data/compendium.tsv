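accession	species	cell_type	signal_x	signal_y	time_point
GSE5054	Human	Thyroid cells	IFNγ	IL1β	1d
GSE36331	Human	ARPE-19 cells	IFNγ	TNF	2d
GSE43409	Human	Innate lymphoid cells	cocktail (IL-1/IL-7/IL-23)	aNKp44	3.5 hr
GSE53712	Human	Monocytic THP-1	LPS	SB203580	4h
GSE53712	Human	Monocytic THP-1	LPS	SB203580	1d
GSE59179	Human	Hut78 cells	Enzastaurin	AR-A014418	3d
GSE63038	Human	NK cells	FcR activation	IL-12	12 hr
GSE79077	Human	MDMs	Dexamethasone	IFNγ	20 hr
GSE57915	Human	pDC	IL3	Flu	6h
GSE57915	Human	pDC	GM-CSF	Flu	6h
GSE57915	Human	pDC	GM-CSF	Flu	1d
GSE57915	Human	pDC	GM-CSF	LL37	1d
GSE57915	Human	Monocytes	NOD2	TLRs	6h
GSE57915	Human	Monocytes	NOD2	TLRs	1d
GSE57915	Human	Monocytes	IFNγ	TLRs	6h
GSE46903	Human	Macrophage	IFNγ	TNF	3d
GSE46903	Human	Macrophage	TNF	P3C	3d
GSE36323	Human	Monocytic THP-1	D3	TsA	2.5 hr
GSE52819	Human	Macrophage	Vitamin D	H37Rv	24 hr
GSE44392	Human	CD4+ T cell	edelfosine	beads	30 hr
GSE24767	Human	Keratinocyte	IL-17	TNF	1d
GSE77814	Human	BMSC	IFNγ	TNF (1.5 ng/ml)	2d
GSE77814	Human	BMSC	IFNγ	TNF (15 ng/ml)	2d
GSE134209	Human	moDC	TNF	IFNβ	1h
GSE134209	Human	moDC	TNF	IFNβ	2.5 hr
GSE20302	Mouse	DC	Lact acidophilus	Bifid bifidum	10 hr
GSE28994	Mouse	Lung	Pam2CSK4	ODN2395	4h
GSE32986	Mouse	DC	Curdlan (1 mg/ml)	GM-CSF	4h
GSE32986	Mouse	DC	Curdlan (100 mg/ml)	GM-CSF	4h
GSE35291	Mouse	HSPCs	Valproic acid	lithium	7d
GSE53986	Mouse	macrophage	IFNγ	LPS	1d
GSE62249	Mouse	SB-3123p cells	Cocktail (TNF/IFNγ)	Vemurafenib	4d
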