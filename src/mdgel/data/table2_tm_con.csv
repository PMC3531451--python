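spot_id,gel_id,protein,pi,mw_kda,iod_raw,ppm
1203,TM,Apolipoprotein AI,,,,1526.9
1301,TM,Rho GDP-dissociation inhibitor2,,,,604.3
1601,TM,"Actin, aortic smooth muscle",,,,2839.5
1602,TM,"Actin, aortic smooth muscle",,,,4033.9
1702,TM,Alpha-1-antitrypsin,,,,2596.4
1704,TM,Alpha-1-antitrypsin,,,,10548.6
1705,TM,Alpha-1-antitrypsin,,,,1835.1
1706,TM,Alpha-1-antitrypsin,,,,8631.6
1708,TM,Alpha-1-antitrypsin,,,,5425.6
2201,TM,Apolipoprotein A-1,,,,3042.8
2503,TM,"Actin, aortic smooth muscle",,,,873.0
2505,TM,Serum albumin,,,,211.9
3001,TM,Protein S100-A9,,,,940.2
3004,TM,Acyl-protein thioesterase 2,,,,535.8
3401,TM,Serum albumin,,,,209.3
3504,TM,Serum albumin,,,,195.9
3604,TM,"Keratin, type I cytoskeletal 9",,,,211.6
4302,TM,Carbonic anhydrase 3,,,,205.8
4303,TM,Acetylcholine receptor subunit alpha,,,,681.6
4704,TM,Serum albumin,,,,201.7
4705,TM,Serum albumin,,,,171.3
4805,TM,Serum albumin,,,,4958.1
5001,TM,Beta-2-microglobulin,,,,535.7
5201,TM,Host cell factor C1 regulator 1,,,,273.0
5301,TM,Triosephosphate isomerase,,,,5092.9
5404,TM,Beta-nerve growth factor,,,,232.9
5701,TM,"Actin, cytoplasmic 1",,,,753.7
5705,TM,Carbonic anhydrase 3,,,,3655.2
6001,TM,ADP-ribosyl cyclase 1,,,,799.9
6102,TM,"Chain B, Deoxy hemoglobin",,,,10021.0
6105,TM,Myoglobin,,,,480.4
6303,TM,Carbonic anhydrase 1,,,,3526.5
6902,TM,Serotransferrin,,,,3102.4
7501,TM,Creatine kinase M-type,,,,2284.1
7601,TM,Beta-enolase,,,,303.4
7701,TM,Carbonic anhydrase 3,,,,4035.0
7702,TM,Carbonic anhydrase 3,,,,4615.4
8103,TM,Hemoglobin subunit beta,,,,13345.5
8201,TM,Flavin reductase (NADPH),,,,1514.9
8202,TM,Flavin reductase (NADPH),,,,2456.0
8405,TM,Four and a half LIM domains protein 1,,,,1138.9
8501,TM,Creatine kinase M-type,,,,4416.1
8601,TM,Beta-enolase,,,,2580.2
8701,TM,Carbonic anhydrase 3,,,,15598.1
9105,TM,Hemoglobin subunit alpha,,,,63347.9
9401,TM,Four and a half LIM domains protein 1,,,,1552.0
9402,TM,Four and a half LIM domains protein 1,,,,1256.5
9701,TM,Ig gamma-1 chain C region,,,,19206.2
1203,CON,Apolipoprotein AI,,,,345.8
1301,CON,Rho GDP-dissociation inhibitor2,,,,265.7
1601,CON,"Actin, aortic smooth muscle",,,,1411.2
1602,CON,"Actin, aortic smooth muscle",,,,1781.2
1702,CON,Alpha-1-antitrypsin,,,,882.5
1704,CON,Alpha-1-antitrypsin,,,,2477.5
1705,CON,Alpha-1-antitrypsin,,,,4911.3
1706,CON,Alpha-1-antitrypsin,,,,3950.6
1708,CON,Alpha-1-antitrypsin,,,,2585.2
2201,CON,Apolipoprotein A-1,,,,891.0
2503,CON,"Actin, aortic smooth muscle",,,,157.4
2505,CON,Serum albumin,,,,609.9
3001,CON,Protein S100-A9,,,,463.9
3004,CON,Acyl-protein thioesterase 2,,,,248.2
3401,CON,Serum albumin,,,,429.7
3504,CON,Serum albumin,,,,552.8
3604,CON,"Keratin, type I cytoskeletal 9",,,,807.1
4302,CON,Carbonic anhydrase 3,,,,791.6
4303,CON,Acetylcholine receptor subunit alpha,,,,330.2
4704,CON,Serum albumin,,,,896.0
4705,CON,Serum albumin,,,,2356.3
4805,CON,Serum albumin,,,,11312.5
5001,CON,Beta-2-microglobulin,,,,152.8
5201,CON,Host cell factor C1 regulator 1,,,,79.1
5301,CON,Triosephosphate isomerase,,,,624.9
5404,CON,Beta-nerve growth factor,,,,527.3
5701,CON,"Actin, cytoplasmic 1",,,,2737.6
5705,CON,Carbonic anhydrase 3,,,,1046.3
6001,CON,ADP-ribosyl cyclase 1,,,,321.4
6102,CON,"Chain B, Deoxy hemoglobin",,,,2834.8
6105,CON,Myoglobin,,,,1075.2
6303,CON,Carbonic anhydrase 1,,,,8509.4
6902,CON,Serotransferrin,,,,7660.9
7501,CON,Creatine kinase M-type,,,,933.3
7601,CON,Beta-enolase,,,,1074.5
7701,CON,Carbonic anhydrase 3,,,,1253.1
7702,CON,Carbonic anhydrase 3,,,,10836.0
8103,CON,Hemoglobin subunit beta,,,,1213.3
8201,CON,Flavin reductase (NADPH),,,,565.3
8202,CON,Flavin reductase (NADPH),,,,704.0
8405,CON,Four and a half LIM domains protein 1,,,,2494.5
8501,CON,Creatine kinase M-type,,,,1596.1
8601,CON,Beta-enolase,,,,1264.8
8701,CON,Carbonic anhydrase 3,,,,3562.7
9105,CON,Hemoglobin subunit alpha,,,,29012.7
9401,CON,Four and a half LIM domains protein 1,,,,706.8
9402,CON,Four and a half LIM domains protein 1,,,,5112.5
9701,CON,Ig gamma-1 chain C region,,,,6056.2
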