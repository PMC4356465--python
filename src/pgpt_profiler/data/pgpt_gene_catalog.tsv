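gene_name	ko_id	uniref_id	length_kbp	category
ACC deaminase	K01505	UniRef50_A5EJ46	1.020	ACC deaminase
tryptophan 2-monooxygenase (iaaM)	K00466	UniRef50_A6W7Y1	1.707	IAA
indolepyruvate decarboxylase (ipdC)	K04103	UniRef50_I0BL41	1.755	IAA
nitrogenase iron protein (nifH)	K02588	UniRef50_O07641	0.984	N2 fixation
nitrogenase molybdenum-iron protein alpha chain (nifD)	K02586	UniRef50_P19066	1.515	N2 fixation
nitrogenase molybdenum-iron protein beta chain (nifK)	K02591	UniRef50_P25314	1.566	N2 fixation
nitrogenase delta subunit (anfG)	K00531	UniRef50_O68940	0.351	N2 fixation
PQQ biosynthesis protein (pqqC)		UniRef50_Q6F9J1	0.768	PQQ biosynthesis
quinoprotein glucose dehydrogenase (GDH)	K00117	UniRef50_P27175	2.427	Phosphate solubilization
3-phytase	K01083	UniRef50_G2IPZ8	1.074	Phosphate solubilization
4-phytase	K01093	UniRef50_B0UQX3	1.635	Phosphate solubilization
isochorismate pyruvate lyase (pchB)	K04782	UniRef50_Q51507	0.306	Siderophore
nonribosomal peptide synthetase (dhbF)	K04780	UniRef50_C6U462	3.270	Siderophore
enterobactin synthetase component F (entF)	K02364	UniRef50_P11454	3.882	Siderophore
beta-1,3-glucanase	K01210	UniRef50_R4MQJ4	0.885	Plant disease suppression
chitinase	K01183	UniRef50_I4XS16	1.464	Plant disease suppression
undetermined MDH		UniRef90_C5ATJ3	1.800	Methanol utilization
xoxF gene type		UniRef90_C5ATJ3	1.800	Methanol utilization
sacA	K01193	UniRef50_P07819	1.440	Sucrose utilization
PTS system sucrose-specific IIA component	M00269	UniRef50_S6C6M4	1.968	Sucrose utilization
glycine betaine/proline transport system (proX)	K02002	UniRef50_P0AFM3	0.993	Betaine utilization
glycine betaine/proline transport system (proW)	K02001	UniRef50_P17327	1.065	Betaine utilization
glycine betaine/proline transport system (proV)	K02000	UniRef50_P14175	1.203	Betaine utilization
betaine-homocysteine S-methyltransferase	K00544	UniRef50_A4WQF1	1.074	Betaine utilization
glutamine synthetase (glnA)	K01915	UniRef50_A0R079	1.437	N metabolism
carbonic anhydrase (cynT, can)	K01673	UniRef50_Q9I262	0.663	N metabolism
nitronate monooxygenase (ncd2, npd)	K00459	UniRef50_F8GQA6	1.254	N metabolism
glutamate dehydrogenase (gudB, rocG)	K00260	UniRef50_B2RKJ1	1.338	N metabolism
glutamate synthase small chain (gltD)	K00266	UniRef50_P9WN18	1.467	N metabolism
glutamate synthase large chain (gltB)	K00265	UniRef50_Q05755	4.548	N metabolism
nitrite reductase NO-forming (nirK)	K00368	UniRef50_P81445	0.993	N metabolism
nitrite reductase NADH large subunit (nirB)	K00362	UniRef90_A6UI45	2.463	N metabolism
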