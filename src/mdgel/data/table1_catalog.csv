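spot_no,protein,molecular_function,accession,mw_kda,pi,matched_peptides,ms_score,functional_class
4,Alpha-1-antitrypsin,Serine protease inhibitor,P01009,46.9,5.4,17,600,inflammatory
5,Protein S100-A14,Calcium binding protein,Q9HCY8,11.7,5.2,2,21,inflammatory
49,Phosphatidylethanolamine-binding protein 1,Protease inhibitor/Serine protease inhibitor,P30086,21.1,7.0,2,89,inflammatory
64,Haptoglobin,Serine protease homolog,P00738,45.9,6.1,2,98,inflammatory
66,Protein DJ-1,Protease,Q99497,20.0,6.3,1,53,inflammatory
68,Phosphatidylethanolamine-binding protein 1,Protease inhibitor,P30086,21.1,7.0,7,288,inflammatory
82,Protein S100-A9,Calcium binding protein,P06702,13.3,5.7,4,122,inflammatory
83,Protein S100-A9,Ca-binding protein,P06702,13.3,5.7,5,145,inflammatory
88,Beta-2-microglobulin,Other,P61769,13.8,6.1,1,50,inflammatory
97,Beta-nerve growth factor,Growth factor activity,P01138,27.0,9.8,5,218,inflammatory
1,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,25,761,transporter
2,Serotransferrin,Iron binding protein,P02787,79.3,6.8,12,451,transporter
6,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,7,175,transporter
8,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,8,213,transporter
9,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,7,221,transporter
19,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,3,59,transporter
21,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,7,153,transporter
22,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,8,221,transporter
32,Myoglobin,Muscle protein,P02144,17.2,7.1,5,193,transporter
34,Vacuolar protein sorting-associated protein 28 homolog,Regulation of vesicular trafficking,Q9UK41,25.6,5.3,5,34,transporter
48,Retinol-binding protein 4,Other,P02753,23.3,5.8,2,47,transporter
56,Serum albumin,Ca2+/Na+/K+/fatty acids/drug binding protein,P02768,71.3,5.9,6,161,transporter
61,Apolipoprotein A-1,Lipid metabolism,P02647,30.7,5.6,8,267,transporter
62,Apolipoprotein A-1,Lipid metabolism,P02647,30.7,5.6,8,331,transporter
70,Transthyretin,Thyroid hormone-binding,P02766,16.0,5.5,4,186,transporter
75,Myoglobin,Muscle protein,P02144,17.2,7.1,6,195,transporter
76,Myoglobin,Muscle protein,P02144,17.2,7.1,4,135,transporter
77,Myoglobin,Muscle protein,P02144,17.2,7.1,5,277,transporter
78,Myoglobin,Muscle protein,P02144,17.2,7.1,7,432,transporter
79,Myoglobin,Muscle protein,P02144,17.2,7.1,4,201,transporter
81,Syntaxin-8,Transport,Q9UNK0,27.0,4.9,1,31,transporter
85,Fatty acid-binding protein,Lipid transport,P05413,14.9,6.3,7,227,transporter
87,Fatty acid-binding protein,Lipid transport,P05413,14.9,6.3,10,312,transporter
89,Hemoglobin subunit beta,Hypotensive agent,P68871,16.1,6.7,1,62,transporter
90,"Chain B, Deoxy hemoglobin",Hypotensive agnet,gi|27574248,15.9,6.7,4,193,transporter
91,Hemoglobin subunit beta,Hypotensive agent,P68871,16.1,6.7,7,514,transporter
92,Hemoglobin subunit beta,Hypotensive agent,P68871,16.1,6.7,12,724,transporter
93,Hemoglobin subunit alpha,Other,P69905,15.3,8.7,5,803,transporter
94,Hemoglobin subunit alpha,Other,P69905,15.3,8.7,6,229,transporter
10,"Actin, cytoplasmic 1",Other,P60709,42.0,5.3,2,48,contractile
16,"Actin, aortic smooth muscle",Muscle protein,P62736,42.4,5.2,2,83,contractile
17,"Actin, aortic smooth muscle",Muscle protein,P62736,42.4,5.2,9,243,contractile
18,Myosin light chain 5,Muscle protein,Q02045,19.5,4.9,3,376,contractile
60,Calponin-3,Actin binding protein,Q15417,36.4,5.7,4,981,contractile
69,Cofilin-1,Other,P23528,18.7,8.2,1,27,contractile
7,Glomulin,Muscle cell differentiation,Q92990,68.9,5.2,1,47,regulatory
41,"rRNA methyltransferase 1, mitochondrial",Methyltransferase,Q6IN84,38.6,8.2,11,1.06e+6,regulatory
47,Rho GDP-dissociation inhibitor2,GTPase activation,P52566,23.0,5.1,5,166,regulatory
50,Glutathione S-transferase P,Transferase,P09211,23.6,5.4,5,275,regulatory
73,Transforming growth factor beta-1,Growth factor/Mitogen,P01137,44.3,8.8,5,679,regulatory
74,Host cell factor C1 regulator 1,Other,Q9NWW0,15.4,6.8,1,58,regulatory
80,26S protease regulatory subunit 4,ATP binding protein,P62191,49.2,5.9,6,104,regulatory
20,"Keratin, type I cytoskeletal 9",Other,P35527,62.2,5.1,4,195,structural
30,Four and a half LIM domains protein 1,Developmental protein,Q13642,38.0,9.2,2,86,structural
31,Four and a half LIM domains protein 1,Developmental protein,Q13642,38.0,9.2,1,75,structural
33,Four and a half LIM domains protein 1,Developmental protein,Q13642,38.0,9.2,1,68,structural
37,Four and a half LIM domains protein 1,Developmental protein,Q13642,38.0,9.2,1,59,structural
38,"Keratin, type I cytoskeletal 9",Other,P35527,62.2,5.1,12,746,structural
58,Four and a half LIM domains protein 1,Developmental protein,Q13642,38.0,9.2,1,48,structural
3,Carbonic anhydrase 3,Lyase,P07451,29.8,6.9,5,142,metabolic
11,Carbonic anhydrase 3,Lyase,P07451,29.8,6.9,5,178,metabolic
12,Carbonic anhydrase 3,Lyase,P07451,29.8,6.9,6,210,metabolic
13,Acyl-coenzyme A synthetase ACSM2A,Ligase,Q08AH3,64.8,8.3,1,37,metabolic
23,Beta-enolase,Lyase,P13929,47.2,7.6,4,223,metabolic
25,Beta-enolase,Lyase,P13929,47.2,7.6,4,211,metabolic
26,Beta-enolase,Lyase,P13929,47.2,7.6,5,211,metabolic
28,Phosphoglycerate kinase 1,Transferase/Kinase,P00558,45.0,8.3,3,81,metabolic
29,Fructose-bisphosphate aldolase A,Lyase,P04075,39.8,8.3,7,257,metabolic
35,Creatine kinase M-type,Transferase/Kinase,P06732,43.3,6.8,9,386,metabolic
36,Creatine kinase M-type,Transferase/Kinase,P06732,43.3,6.8,10,476,metabolic
42,Carbonic anhydrase 1,Lyase,P00915,28.9,6.6,6,174,metabolic
43,Carbonic anhydrase 1,Lyase,P00915,28.9,6.6,8,276,metabolic
44,Glycosyltransferase 1 domain-containing protein 1,Glycotransferase,Q96MS3,38.5,6.0,7,421,metabolic
45,Carbonic anhydrase 3,Lyase,P07451,29.8,6.9,6,206,metabolic
46,Carbonic anhydrase 3,Lyase,P07451,29.8,6.9,7,264,metabolic
52,Carbonic anhydrase 3,Lyase,P07451,29.8,6.9,1,52,metabolic
53,Acetylcholine receptor subunit alpha,"Ligand-gated ion channel,",P02708,54.5,5.8,1,39,metabolic
54,Triosephosphate isomerase,Isomerase,P60174,31.0,5.6,5,196,metabolic
55,Triosephosphate isomerase,Isomerase,P60174,31.0,5.6,5,302,metabolic
57,Carbonic anhydrase 3,Lyase,P07451,29.8,6.9,1,42,metabolic
84,Acyl-protein thioesterase 2,Hydrolase,O95372,25.1,6.7,1,37,metabolic
14,Ig gamma-1 chain C region,Antigen binding,P01857,36.6,8.5,2,75,other
15,Ig gamma-1 chain C region,Antigen binding,P01857,36.6,8.5,5,122,other
24,Centromere protein M,Mitotic progression,Q9NSP4,19.7,6.7,2,12,other
27,E3 ubiquitin-protein ligase RNF149,Ligase,Q8NC42,43.1,6.1,1,40,other
39,E3 ubiquitin-protein ligase RNF149,Ligase,Q8NC42,43.1,6.1,1,36,other
40,WD repeat domain phosphoinositide-interacting protein 3,"phosphatidylinositol-3,5-bisphosphate binding",Q5MNZ6,38.1,7.5,1,32,other
51,Carboxypeptidase-like 3,Metalloprotease,O75976,44.7,6.5,1,33,other
59,Flavin reductase (NADPH),Oxidoreductase,P30043,22.2,7.1,3,133,other
63,Histone H2A.2,DNA-binding,P04908,14.2,11,1,44,other
65,DDB1- and CUL4-associated factor 8,Other,Q5TAQ9,67.5,5.2,1,29,other
67,Apoptosis-associated speck-like protein containing a CARD,Apoptosis,Q9ULZ3,21.7,5.9,1,87,other
71,Superoxide dismutase [Cu-Zn],Antioxidant,P00441,16.1,5.7,2,88,other
72,Cysteine and glycine-rich protein 2,Zinc ion binding proteins,Q16527,21.0,9.0,8,9981,other
86,Unnamed protein product,Other,gi|29446,16.0,7.1,2,130,other
95,ADP-ribosyl cyclase 1,Hydrolase,P28907-2,13.8,9.0,1,35,other
96,Ubiquitin-60S ribosomal protein L40,Ribonucleoprotein,P62987,15.0,9.9,5,142,other
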