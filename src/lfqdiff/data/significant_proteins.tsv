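gene_names	protein_names	welch_p	fold_change	coefficient_of_variation	peptides	unique_peptides
MAP1B	Microtubule-associated protein 1B;MAP1 light chain LC1	0.007	10.21	1.43	24	23
HLA-DQA1	Major histocompatibility complex, class II, DQ alpha 1	0.002	6.23	1.12	4	2
C19orf52	Uncharacterized protein C19orf52	0.012	4.90	1.92	3	3
IGHD	Ig delta chain C region	0.022	3.88	1.82	7	7
MCM2	DNA replication licensing factor MCM2	0.002	3.40	0.80	12	12
MLIP	Muscular LMNA-interacting protein	0.001	3.11	0.74	4	4
STMN2	Stathmin-2	0.021	3.02	0.93	1	1
Q7Z7K6	Centromere protein V	0.013	2.84	1.37	8	3
MCM4	DNA replication licensing factor MCM4	0.007	2.71	0.82	7	7
EMG1	Ribosomal RNA small subunit methyltransferase NEP1	0.017	2.63	1.17	4	4
NUDT12	Peroxisomal NADH pyrophosphatase NUDT12	0.009	2.38	0.73	8	8
DHFR;DHFRL1	Dihydrofolate reductase;Dihydrofolate reductase, mitochondrial	0.014	2.31	0.62	2	2
OSBPL6	Oxysterol-binding protein-related protein 6	0.010	2.25	0.84	3	3
MCM7	DNA replication licensing factor MCM7	0.012	2.20	0.71	11	11
ANGPTL3	Angiopoietin-related protein 3	0.009	2.14	0.62	5	5
TMEM2	Transmembrane protein 2	0.002	2.02	0.51	4	4
DDX20	Probable ATP-dependent RNA helicase DDX20	0.006	1.94	0.54	4	4
ISG15	Ubiquitin-like protein ISG15	0.010	1.82	0.67	5	5
CCDC25	Coiled-coil domain-containing protein 25	0.004	1.79	0.59	9	9
NBEAL1	Neurobeachin-like protein 1	0.009	1.63	0.52	10	10
BCO2	Beta,beta-carotene 9,10-oxygenase	0.009	1.57	0.43	22	22
HAL	Histidine ammonia-lyase	0.013	-1.65	0.46	25	25
ASAH1	Acid ceramidase;Acid ceramidase subunit alpha;Acid ceramidase subunit beta	0.000	-1.66	0.38	15	15
CYP2S1	Cytochrome P450 2S1	0.008	-1.72	0.45	2	2
GPX1	Glutathione peroxidase 1	0.011	-1.76	0.55	13	13
CLEC16A	Protein CLEC16A	0.013	-1.76	0.60	1	1
ACTR1B	Beta-centractin	0.015	-1.83	0.51	9	4
CHMP1A	Charged multivesicular body protein 1a	0.009	-1.87	0.56	1	1
CTBS	Di-N-acetylchitobiase	0.012	-1.98	0.71	5	5
FOLH1;FOLH1B	Glutamate carboxypeptidase 2;Putative N-acetylated-alpha-linked acidic dipeptidase	0.014	-2.01	0.74	8	8
KHNYN	Protein KHNYN	0.002	-2.02	0.59	2	2
FRG1	Protein FRG1	0.017	-2.17	0.92	3	3
SRP72	Signal recognition particle 72 kDa protein	0.001	-2.22	0.68	19	19
PLSCR3	Phospholipid scramblase 3	0.012	-2.23	0.56	2	2
ERF	ETS domain-containing transcription factor ERF	0.013	-2.25	0.66	3	3
FNBP1	Formin-binding protein 1	0.014	-2.28	0.75	5	5
SEPP1	Selenoprotein P	0.018	-2.34	0.69	2	2
RHPN2	Rhophilin-2	0.009	-2.40	0.89	4	4
ELOVL1	Elongation of very long chain fatty acids protein 1	0.019	-2.46	1.61	2	2
MRPS7	28S ribosomal protein S7, mitochondrial	0.015	-2.48	0.76	9	9
RIN1	Ras and Rab interactor 1	0.012	-2.82	0.55	2	2
ITIH5	Inter-alpha-trypsin inhibitor heavy chain H5	0.008	-2.95	1.23	3	3
CAMK2G;CAMK2A;CAMK2B	Calcium/calmodulin-dependent protein kinase type II subunit gamma;Calcium/calmodulin-dependent protein kinase type II subunit alpha	0.011	-2.96	0.88	8	2
NT5DC2	5-nucleotidase domain-containing protein 2	0.006	-3.04	0.92	4	4
FAN1	Fanconi-associated nuclease 1	0.011	-3.09	1.02	3	3
OXNAD1	Oxidoreductase NAD-binding domain-containing protein 1	0.003	-3.20	1.04	5	5
ALOX5AP	Arachidonate 5-lipoxygenase-activating protein	0.014	-3.34	1.25	2	2
MACF1	Microtubule-actin cross-linking factor 1, isoforms 1/2/3/5	0.016	-3.52	1.57	83	0
CPA3	Mast cell carboxypeptidase A	0.008	-3.67	1.72	4	4
KRT80	Keratin, type II cytoskeletal 80	0.005	-3.67	0.64	5	4
MYBPC2	Myosin-binding protein C, fast-type	0.004	-4.29	0.96	4	3
ERAP2	Endoplasmic reticulum aminopeptidase 2	0.022	-4.59	0.99	20	20
YOD1	Ubiquitin thioesterase OTU1	0.017	-4.95	1.56	3	3
TLCD1	TLC domain-containing protein 1	0.022	-5.37	2.22	2	2
UBE3B	Ubiquitin-protein ligase E3B	0.024	-6.17	0.96	7	7
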