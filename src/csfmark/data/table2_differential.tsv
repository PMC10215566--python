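# Differential proteins from the TMT discovery phase, transcribed verbatim from the published
# table (including q=0 entries and one p/q non-monotonicity for MEGF8). Note: the accompanying
# text reports 15 up / 4 down among the q<0.05 tier, while this table contains 5 negative
# log2fc values in that tier; the table values are kept as printed.
protein_name	gene_symbol	p_value	q_value	log2fc	detectable_by_prm	q_band
Chitinase-3-like protein 2	CHI3L2	2.01e-8	0	2.527697	False	lt_0.05
Chitotriosidase-1	CHIT1	1.88e-5	0	3.99428	True	lt_0.05
Neurofilament light polypeptide	NEFL	1.47e-7	0	1.722488	False	lt_0.05
Neurofilament medium polypeptide	NEFM	6.97e-11	0	3.784436	False	lt_0.05
Neurofilament heavy polypeptide	NEFH	5.91e-5	0.001333	2.779995	False	lt_0.05
Alpha-1-antichymotrypsin	SERPINA3	6.94e-6	0.008571	1.077944	True	lt_0.05
Ubiquitin carboxyl-terminal hydrolase isozyme L1	UCHL1	1.48e-5	0.015	1.012955	True	lt_0.05
Transmembrane glycoprotein NMB	GPNMB	8.06e-5	0.0244	1.069444	True	lt_0.05
Multiple epidermal-growth-factor-like domains protein 8	MEGF8	4.36e-6	0.026182	-0.72796	True	lt_0.05
Aspartate aminotransferase, mitochondrial	GOT2	0.00032	0.026222	1.511867	False	lt_0.05
Centromere protein F	CENPF	0.001221	0.028	2.205369	False	lt_0.05
Neuronal pentraxin-2	NPTX2	0.00016	0.028667	-1.13379	True	lt_0.05
Calcium/calmodulin-dependent protein kinase type II subunit alpha	CAMK2A	0.000116	0.033143	-0.95518	True	lt_0.05
Apolipoprotein B-100	APOB	0.002532	0.041053	2.13572	True	lt_0.05
Amyloid-beta A4 protein	APP	6.85e-5	0.042444	-0.75982	True	lt_0.05
Neural cell adhesion molecule L1	L1CAM	7.59e-5	0.043	-0.74116	True	lt_0.05
Chitinase-3-like protein 1	CHI3L1	0.000583	0.044	1.137858	True	lt_0.05
Platelet factor 4	PF4	0.002747	0.044533	2.573066	False	lt_0.05
Lysozyme C	LYZ	0.000368	0.0465	1.015916	False	lt_0.05
Calsyntenin-1	CLSTN1	0.000146	0.051429	-0.75724	True	lt_0.1
Contactin-associated protein-like 2	CNTNAP2	0.000225	0.052182	-0.79877	True	lt_0.1
Macrophage-capping protein	CAPG	0.00037	0.056522	0.840849	False	lt_0.1
Triosephosphate isomerase	TPI1	2.87e-5	0.05712	-0.59761	True	lt_0.1
Microfibril-associated glycoprotein 4	MFAP4	0.00012	0.058429	-0.66703	True	lt_0.1
Endoplasmic reticulum aminopeptidase 2	ERAP2	0.001754	0.058897	1.147899	True	lt_0.1
Gamma-crystallin D	CRYGD	0.007001	0.058963	-2.86543	False	lt_0.1
Syndecan binding protein (Syntenin), isoform CRA_a	SDCBP	0.000461	0.059	0.846597	False	lt_0.1
Follistatin-related protein 4	FSTL4	0.000542	0.059333	-0.82485	True	lt_0.1
Transport and Golgi organization protein 1 homolog	MIA3	4.14e-7	0.061231	-0.45853	False	lt_0.1
Neurocan core protein	NCAN	0.000476	0.070545	-0.73593	True	lt_0.1
Platelet basic protein	PPBP	0.006893	0.072625	2.127046	True	lt_0.1
Leukotriene A-4 hydrolase	LTA4H	8.72e-5	0.073677	0.593814	True	lt_0.1
Chondroitin sulfate proteoglycan 5	CSPG5	0.001286	0.083412	-0.84017	True	lt_0.1
Band 4.1-like protein 3	EPB41L3	0.004408	0.092686	1.101059	False	lt_0.1
Immunoglobulin heavy variable 2-5	IGHV2-5	0.010187	0.096522	1.802516	False	lt_0.1
Plectin	PLEC	0.00037	0.096681	0.586559	False	lt_0.1
Myosin light chain kinase, smooth muscle	MYLK	0.000406	0.09688	0.572703	False	lt_0.1
Calsyntenin-3	CLSTN3	8.53e-5	0.097255	-0.49128	True	lt_0.1
Serine/threonine-protein phosphatase 2A activator	PTPA	0.000505	0.0978	0.637236	False	lt_0.1
UMP-CMP kinase	CMPK1	0.002623	0.097956	0.843523	False	lt_0.1
Neuronal pentraxin-1	NPTX1	0.002511	0.098222	-0.79414	True	lt_0.1
Alpha-1-antitrypsin	SERPINA1	0.002667	0.098449	0.842153	True	lt_0.1
Leucine-rich repeat and immunoglobulin-like domain-containing nogo receptor-interacting protein 1	LINGO1	0.000955	0.098462	-0.65034	True	lt_0.1
Immunoglobulin lambda variable 3-19	IGLV3-19	0.006846	0.098537	1.408966	True	lt_0.1
Immunoglobulin lambda variable 3-27	IGLV3-27	0.003614	0.098566	0.886375	False	lt_0.1
Alpha-2,8-sialyltransferase 8E	ST8SIA5	0.000228	0.098974	-0.5754	True	lt_0.1
Butyrophilin subfamily 3 member A2	BTN3A2	0.005124	0.099	1.036734	False	lt_0.1
Reticulon-4 receptor-like 2	RTN4RL2	0.00064	0.099111	-0.67662	True	lt_0.1
Protein kinase C-binding protein NELL2	NELL2	0.001377	0.099135	-0.78332	True	lt_0.1
Immunoglobulin J chain	JCHAIN	0.010018	0.099167	1.661328	True	lt_0.1
Multiple epidermal-growth-factor-like domains protein 9	MEGF9	0.000603	0.099263	-0.66189	False	lt_0.1
Glutathione S-transferase Mu 1	GSTM1	0.008847	0.09981	1.620058	False	lt_0.1
Neurofascin	NFASC	0.00052	0.099907	-0.62704	True	lt_0.1
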