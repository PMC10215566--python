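subject_id	sample_type	group	alsfrs	sex	race	age	application
ALS01	CSF	ALS	40	Male	White	62	Discovery and Validation
ALS02	CSF	ALS	36	Female	White	68	Discovery and Validation
ALS03	CSF	ALS	44	Male	White	54	Discovery and Validation
ALS04	CSF	ALS	33	Female	White	55	Discovery and Validation
ALS05	CSF	ALS	37	Female	White	44	Discovery and Validation
ALS06	CSF	ALS	42	Female	White	51	Discovery and Validation
ALS07	CSF	ALS	42	Male	White	64	Discovery and Validation
ALS08	CSF	ALS	33	Female	White	52	Discovery and Validation
ALS09	CSF	ALS	35	Male	White	68	Discovery and Validation
ALS10	CSF	ALS	34	Male	White	55	Discovery and Validation
ALS11	CSF	ALS	34	Male	White	61	Discovery and Validation
ALS12	CSF	ALS	35	Male	White	79	Discovery and Validation
ALS13	CSF	ALS	42	Male	White	63	Discovery and Validation
ALS14	CSF	ALS	40	Male	White	59	Discovery and Validation
ALS15	CSF	ALS	44	Female	White	66	Discovery and Validation
ALS16	CSF	ALS	43	Male	White	73	Discovery and Validation
ALS17	CSF	ALS	41	Male	White	55	Discovery and Validation
ALS18	CSF	ALS	48	Male	White	65	Discovery and Validation
ALS19	CSF	ALS	46	Male	White	40	Discovery and Validation
ALS20	CSF	ALS	34	Female	White	53	Discovery and Validation
ALS21	CSF	ALS	NA	Male	White	64	Validation
ALS22	CSF	ALS	32	Male	White	58	Validation
ALS23	CSF	ALS	42	Male	White	45	Validation
ALS24	CSF	ALS	40	Female	White	41	Validation
ALS25	CSF	ALS	47	Male	White	44	Validation
ALS26	CSF	ALS	41	Male	White	51	Validation
ALS27	CSF	ALS	40	Male	White	68	Validation
ALS28	CSF	ALS	27	Female	White	44	Validation
ALS29	CSF	ALS	48	Male	White	57	Validation
ALS30	CSF	ALS	15	Female	White	63	Validation
HC01	CSF	HC	NA	Male	White	38	Discovery and Validation
HC02	CSF	HC	NA	Male	White	58	Discovery and Validation
HC03	CSF	HC	NA	Female	White	23	Discovery and Validation
HC04	CSF	HC	NA	Female	White	58	Discovery and Validation
HC05	CSF	HC	NA	Female	Asian	43	Discovery and Validation
HC06	CSF	HC	NA	Male	White	35	Discovery and Validation
HC07	CSF	HC	NA	Male	White	57	Discovery and Validation
HC08	CSF	HC	NA	Female	White	46	Discovery and Validation
HC09	CSF	HC	NA	Male	White	76	Discovery and Validation
HC10	CSF	HC	NA	Female	White	44	Discovery and Validation
HC11	CSF	HC	NA	Female	White	47	Discovery and Validation
HC12	CSF	HC	NA	Male	White	70	Discovery and Validation
HC13	CSF	HC	NA	Female	White	62	Discovery and Validation
HC14	CSF	HC	NA	Male	White	74	Discovery and Validation
HC15	CSF	HC	NA	Male	White	66	Discovery and Validation
HC16	CSF	HC	NA	Male	White	72	Discovery and Validation
HC17	CSF	HC	NA	Female	White	62	Discovery and Validation
HC18	CSF	HC	NA	Female	White	66	Discovery and Validation
HC19	CSF	HC	NA	Male	White	69	Discovery and Validation
HC20	CSF	HC	NA	Female	White	55	Discovery and Validation
HC21	CSF	HC	NA	Female	White	61	Validation
HC22	CSF	HC	NA	Male	White	66	Validation
HC23	CSF	HC	NA	Male	White	67	Validation
HC24	CSF	HC	NA	Female	White	64	Validation
HC25	CSF	HC	NA	Female	ND	59	Validation
HC26	CSF	HC	NA	Male	White	65	Validation
HC27	CSF	HC	NA	Male	White	66	Validation
HC28	CSF	HC	NA	Female	White	58	Validation
HC29	CSF	HC	NA	Male	White	54	Validation
HC30	CSF	HC	NA	Female	White	59	Validation
HC31	CSF	HC	NA	Female	ND	60	Validation
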