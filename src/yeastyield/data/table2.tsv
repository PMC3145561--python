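Reference	Product	Yield	PrimaryStep	SecondStep	OVE_C2	OVE_C3	KNO_C2	NUT_C2	INT_C2	CUL_C2	OXY_C2
B41	(E, E, E)-Geranylgeraniol	0.00025	10	10	1	0	0	1	0	0	0
B41	(E, E, E)-Geranylgeraniol	0.014	10	10	0	1	0	1	0	0	0
B41	(E, E, E)-Geranylgeraniol	0.047	10	10	0	1	0	1	0	0	0
B41	(E, E, E)-Geranylgeraniol	0.018	10	10	0	1	0	1	0	0	0
B41	(E, E, E)-Geranylgeraniol	0.031	10	10	0	1	0	1	0	0	0
B41	(E, E, E)-Geranylgeraniol	0.058	10	10	0	1	0	1	0	0	0
B41	(E, E, E)-Geranylgeraniol	0.14	10	10	0	1	0	1	0	1	0
B42	1,2-Propanediol	0.014	4	3	1	0	0	1	0	0	0
B43	1,2-Propanediol	0.010	4	3	1	0	0	1	0	1	0
B43	1,2-Propanediol	0.026	4	3	1	0	0	1	0	1	0
B44	5-epi-aristolochene	0.010	10	9	1	0	1	1	0	0	0
B44	5-epi-aristolochene	0.0090	10	9	1	0	1	1	0	0	0
B45	Acetate	0.13	9	2	0	0	1	0	0	1	0
B46	Acetate	0.015	9	2	0	0	1	0	0	1	0
B47	Acetate	0.26	9	2	0	1	0	0	0	0	1
B48	Amorphadiene	0.00049	12	9	1	0	0	0	0	0	0
B48	Amorphadiene	0.0020	12	9	1	0	0	0	0	0	0
B48	Amorphadiene	0.0040	12	9	1	0	1	0	0	0	0
B48	Amorphadiene	0.011	12	9	1	0	1	0	0	0	0
B48	Amorphadiene	0.016	12	9	0	1	1	0	0	0	0
B48	Amorphadiene	0.016	12	9	0	1	1	0	0	0	0
B49	Amorphadiene	0.0080	12	9	1	0	1	0	0	0	0
B49	Amorphadiene	0.0090	12	9	0	1	1	0	0	0	0
B49	Amorphadiene	0.011	12	9	0	1	1	0	0	0	0
B49	Amorphadiene	0.013	12	9	0	1	1	0	0	0	0
B48	Artemisinic acid	0.0030	12	10	0	1	1	0	0	0	0
B48	Artemisinic acid	0.011	12	10	0	1	1	0	0	1	0
B50	Cyanophycin	0.12	10(0)	2(1)	1	0	1	1	1	0	0
B50	Cyanophycin	0.10	10(0)	2(1)	1	0	1	1	1	0	0
B50	Cyanophycin	0.15	10(0)	2(1)	1	0	1	1	1	0	0
B51	Dihydroxyacetone	0.0040	4	3	1	0	0	0	0	0	0
B51	Dihydroxyacetone	0.034	4	3	1	0	1	0	0	0	0
B52	D-Lactic acid	0.61	9	1	1	0	1	1	0	0	1
B53	Dolichol	0.00010	10	11	0	0	0	1	0	0	0
B53	Dolichol	0.00018	10	11	1	0	0	0	0	0	0
B53	Ergosterol	0.00015	10	21	0	0	0	1	0	0	0
B53	Ergosterol	0.00020	10	21	1	0	0	0	0	0	0
B20	Ethanol	0.55	9	2	1	0	0	0	0	1	1
B20	Ethanol	0.47	8	2	0	1	0	0	0	1	1
B54	Ethanol	0.080	8	2	0	1	0	0	0	1	0
B54	Ethanol	0.12	8	2	0	1	0	0	0	1	1
B54	Ethanol	0.15	8	2	0	1	0	0	0	1	1
B55	Ethanol	0.53	9	2	1	0	0	1	0	0	0
B55	Ethanol	0.20	9	2	1	0	0	1	0	0	0
B55	Ethanol	0.47	9	2	1	0	0	1	0	0	0
B55	Ethanol	0.42	9	2	0	0	0	1	0	0	0
B55	Ethanol	0.36	9	2	0	0	0	1	0	0	0
B46	Ethanol	0.44	9	2	0	0	1	0	0	1	0
B46	Ethanol	0.32	8	2	0	0	1	0	0	1	1
B56	Ethanol	0.52	9	2	1	0	0	0	0	0	0
B47	Ethanol	0.55	9	2	0	1	0	0	0	0	1
B47	Ethanol	0.39	9	2	0	1	0	0	0	0	1
B47	Ethanol	0.51	9	2	0	1	1	0	0	0	1
B57	Ethylene	0.00069	13	10	1	0	0	0	0	1	0
B44	Farnesol	0.036	10	9	0	0	1	1	0	0	0
B58	Flavanones	0.030	10(0)	14(3)	0	1	0	0	1	0	0
B58	Flavanones	0.053	10(0)	14(3)	0	1	0	0	1	0	0
B59	Formate	0.00024	6	7	0	0	1	0	0	0	0
B59	Formate	0.00030	6	7	0	0	1	0	0	0	0
B60	Geraniol	0.00011	10	8	1	0	0	0	0	0	0
B60	Geraniol	0.00019	10	8	1	0	1	0	0	0	0
B60	Geraniol	0.00019	10	8	1	0	1	0	0	0	0
B61	Glycerol	0.12	4	2	1	0	0	0	0	1	0
B61	Glycerol	0.12	4	2	1	0	0	0	0	1	0
B45	Glycerol	0.41	4	2	1	0	1	0	0	1	0
B45	Glycerol	0.45	4	2	1	0	1	0	0	1	0
B45	Glycerol	0.45	4	2	1	0	1	0	0	0	0
B62	Glycerol	0.49	4	2	0	0	1	1	0	1	0
B62	Glycerol	0.41	4	2	0	0	1	1	0	1	0
B46	Glycerol	0.050	4	2	0	0	1	0	0	1	0
B46	Glycerol	0.037	2	4	0	0	1	0	0	1	1
B63	Glycerol	0.45	4	2	0	0	1	0	0	1	0
B63	Glycerol	0.54	4	2	1	0	1	0	0	1	0
B30	Glycerol 3-phosphate	0.0010	4	1	1	0	1	0	0	0	1
B64	Hydrocortisone	0.0020	10(0)	19(2)	1	0	0	1	1	0	0
B64	Hydrocortisone	0.0020	10(0)	19(2)	1	0	1	1	1	0	0
B64	Hydrocortisone	0.021	10(0)	19(2)	1	0	1	1	1	0	0
B64	Hydrocortisone	0.026	10(0)	19(2)	1	0	1	1	1	0	0
B65	Lactate	0.44	9	1	1	0	0	1	0	1	0
B66	Lactate	0.21	9	1	1	0	0	0	0	1	0
B67	L-Ascorbic acid	0.14	2(0)	8(2)	1	0	0	0	1	0	0
B67	L-Ascorbic acid	0.066	2(0)	8(2)	1	0	0	0	1	0	0
B60	Linalool	8.8e-5	10	8	1	0	0	0	0	0	0
B60	Linalool	2.3e-5	10	8	1	0	1	0	0	0	0
B68	L-Lactic Acid	0.65	9	1	1	0	1	1	0	0	0
B32	Malate	0.28	11	0	0	1	0	0	0	0	0
B49	Mevalonate	0.022	12	3	0	1	1	0	0	0	0
B49	Mevalonate	0.022	12	3	0	1	1	0	0	0	0
B69	Naringenin	0.0070	8(0)	15(3)	0	1	0	0	1	0	0
B69	Naringenin	0.0020	8(0)	15(5)	0	1	0	0	1	0	0
B15	Naringenin	0.00058	10	14	0	1	0	1	0	0	0
B70	n-Butanol	0.00020	12	6	0	1	0	0	0	0	1
B69	p-Coumaric Acid	0.033	8(0)	12(2)	0	1	0	0	1	0	0
B71	p-Hydroxycinnamic acid	0.00020	8	12	1	0	0	0	0	0	0
B71	p-Hydroxycinnamic acid	0.20	8(0)	12(2)	1	0	0	0	1	0	0
B15	Pinocembrin	6.6e-5	10	14	0	1	0	1	0	0	0
B72	Poly[(R)-3-hydroxybutyrate]	0.00056	10	3	1	0	0	0	0	0	0
B72	Poly[(R)-3-hydroxybutyrate]	0.003	10	3	1	0	0	0	0	0	0
B72	Poly[(R)-3-hydroxybutyrate]	0.012	10	3	0	1	0	0	0	0	0
B72	Poly[(R)-3-hydroxybutyrate]	0.00047	10	3	1	0	0	0	0	1	0
B72	Poly[(R)-3-hydroxybutyrate]	0.0090	10	3	1	0	0	0	0	1	0
B72	Poly[(R)-3-hydroxybutyrate]	0.018	10	3	0	1	0	0	0	1	0
B72	Poly[(R)-3-hydroxybutyrate]	0.0010	10	3	0	1	0	0	0	1	1
B72	Poly[(R)-3-hydroxybutyrate]	0.017	10	3	0	1	0	1	0	0	0
B44	Premnaspirodiene	0.011	10	9	1	0	1	1	0	0	0
B44	Premnaspirodiene	0.0090	10	9	1	0	1	1	0	0	0
B73	Pyruvate	0.55	9	0	0	0	1	0	0	1	0
B46	Pyruvate	0.0050	9	0	0	0	1	0	0	1	0
B74	Reticuline	0.051	8(0)	16(3)	0	1	0	0	1	0	0
B75	Ribitol	0.0020	5	2	0	0	1	0	0	0	0
B75	Ribitol	0.027	5	2	1	0	1	0	0	0	0
B75	Ribitol	0.017	5	2	1	0	1	0	0	0	0
B75	Ribitol	0.021	5	2	1	0	1	0	0	0	0
B41	Squalene	0.042	10	9	1	0	0	1	0	0	0
B76	Taxadiene	7.7e-5	12	8	0	1	0	1	0	0	0
B77	Vanillin	0.0030	3	6	0	1	1	1	0	0	0
B75	Xylitol	0.0070	5	2	1	0	1	0	0	0	0
B75	Xylitol	0.014	5	2	1	0	1	0	0	0	0
B75	Xylitol	0.014	5	2	1	0	1	0	0	0	0
B47	Xylitol	0.27	5	2	0	1	0	0	0	0	1
B47	Xylitol	0.29	5	2	0	1	1	0	0	0	1
B78	β-carotene	4.5e-7	10	14	1	0	0	0	0	0	0
B78	β-carotene	2.9e-6	10	14	0	1	0	0	0	0	0
B78	β-carotene	0.00011	10	14	0	1	0	0	0	0	0
B78	β-carotene	0.00036	10	14	0	1	0	0	0	0	0
B78	β-carotene	0.0010	10	14	0	1	0	0	0	0	0
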