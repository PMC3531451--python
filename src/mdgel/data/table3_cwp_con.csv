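spot_id,gel_id,protein,pi,mw_kda,iod_raw,ppm
1001,CWP,Protein S100-A14,,,,2347.4
1003,CWP,Syntaxin-8,,,,415.9
1203,CWP,Apolipoprotein AI,,,,1200.8
1301,CWP,Rho GDP-dissociation inhibitor2,,,,1280.1
1704,CWP,Alpha-1-antitrypsin,,,,98.5
1705,CWP,Alpha-1-antitrypsin,,,,17217.1
1706,CWP,Alpha-1-antitrypsin,,,,1672.9
1708,CWP,Alpha-1-antitrypsin,,,,7056.7
2202,CWP,Apolipoprotein A-1,,,,4468.5
2503,CWP,"Actin, aortic smooth muscle",,,,58.3
2506,CWP,Serum albumin,,,,2552.5
2702,CWP,Alpha-1-antitrypsin,,,,7331.1
3001,CWP,Protein S100-A9,,,,983.3
3003,CWP,Protein S100-A9,,,,2912.9
3201,CWP,Histone H2A.2,,,,895.8
3202,CWP,Glutathione S-transferase P,,,,1701.4
4704,CWP,Serum albumin,,,,315.6
4705,CWP,Serum albumin,,,,421.8
5201,CWP,Host cell factor C1 regulator 1,,,,411.6
5904,CWP,Serotransferrin,,,,19626.1
6701,CWP,Carbonic anhydrase 3,,,,1182.2
6902,CWP,Serotransferrin,,,,1508.9
7202,CWP,Cofilin-1,,,,818.8
7302,CWP,Carbonic anhydrase 3,,,,946.9
7701,CWP,Carbonic anhydrase 3,,,,3331.8
8103,CWP,Hemoglobin subunit beta,,,,4326.8
8201,CWP,Flavin reductase (NADPH),,,,1133.7
8202,CWP,Flavin reductase (NADPH),,,,2208.9
8203,CWP,Phosphatidylethanolamine-binding protein 1,,,,1035.6
8701,CWP,Carbonic anhydrase 3,,,,1485.2
1001,CON,Protein S100-A14,,,,849.4
1003,CON,Syntaxin-8,,,,125.7
1203,CON,Apolipoprotein AI,,,,345.8
1301,CON,Rho GDP-dissociation inhibitor2,,,,265.7
1704,CON,Alpha-1-antitrypsin,,,,2477.5
1705,CON,Alpha-1-antitrypsin,,,,4911.3
1706,CON,Alpha-1-antitrypsin,,,,3950.6
1708,CON,Alpha-1-antitrypsin,,,,2585.2
2202,CON,Apolipoprotein A-1,,,,1366.7
2503,CON,"Actin, aortic smooth muscle",,,,157.4
2506,CON,Serum albumin,,,,1214.7
2702,CON,Alpha-1-antitrypsin,,,,2935.8
3001,CON,Protein S100-A9,,,,463.9
3003,CON,Protein S100-A9,,,,1308.2
3201,CON,Histone H2A.2,,,,274.8
3202,CON,Glutathione S-transferase P,,,,646.9
4704,CON,Serum albumin,,,,896.0
4705,CON,Serum albumin,,,,2356.3
5201,CON,Host cell factor C1 regulator 1,,,,79.1
5904,CON,Serotransferrin,,,,4499.9
6701,CON,Carbonic anhydrase 3,,,,2518.9
6902,CON,Serotransferrin,,,,7660.9
7202,CON,Cofilin-1,,,,380.7
7302,CON,Carbonic anhydrase 3,,,,213.5
7701,CON,Carbonic anhydrase 3,,,,1253.1
8103,CON,Hemoglobin subunit beta,,,,1213.3
8201,CON,Flavin reductase (NADPH),,,,565.3
8202,CON,Flavin reductase (NADPH),,,,704.0
8203,CON,Phosphatidylethanolamine-binding protein 1,,,,2450.5
8701,CON,Carbonic anhydrase 3,,,,3562.7
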