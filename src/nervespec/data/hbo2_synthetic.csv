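wavelength_nm,absorption_cm-1
400,1774.25
402,1963.78
404,2139.9
406,2295.69
408,2424.67
410,2521.21
412,2580.97
414,2601.2
416,2580.97
418,2521.21
420,2424.67
422,2295.69
424,2139.9
426,1963.78
428,1774.25
430,1578.18
432,1382.05
434,1191.57
436,1011.45
438,845.297
440,695.535
442,563.49
444,449.497
446,353.073
448,273.106
450,208.056
452,156.128
454,115.437
456,84.1276
458,60.4661
460,42.8994
462,30.0848
464,20.8983
466,14.4254
468,9.94211
470,6.88933
472,4.84552
474,3.50009
476,2.62916
478,2.0748
480,1.72793
482,1.51481
484,1.38678
486,1.3127
488,1.27384
490,1.26058
492,1.271
494,1.311
496,1.3963
498,1.55638
500,1.84062
502,2.32699
504,3.13291
506,4.42764
508,6.44458
510,9.49066
512,13.9488
514,20.2688
516,28.9419
518,40.4557
520,55.2274
522,73.5218
524,95.3597
526,120.434
528,148.052
530,177.114
532,206.16
534,233.473
536,257.242
538,275.77
540,287.692
542,292.174
544,289.071
546,278.991
548,263.295
550,243.99
552,223.552
554,204.683
556,190.016
558,181.798
560,181.569
562,189.888
564,206.143
566,228.505
568,254.075
570,279.232
572,300.146
574,313.386
576,316.481
578,308.328
580,289.341
582,261.305
584,226.993
586,189.629
588,152.338
590,117.705
592,87.505
594,62.6403
596,43.2365
598,28.8456
600,18.6824
602,11.8379
604,7.43732
606,4.73433
608,3.1474
610,2.25688
612,1.77963
614,1.53599
616,1.41832
618,1.36554
620,1.34475
622,1.33911
624,1.34041
626,1.34482
628,1.35068
630,1.35725
632,1.36428
634,1.37164
636,1.3793
638,1.38726
640,1.39553
642,1.4041
644,1.41299
646,1.42221
648,1.43176
650,1.44165
652,1.4519
654,1.46251
656,1.47349
658,1.48485
660,1.49659
662,1.50874
664,1.5213
666,1.53427
668,1.54767
670,1.56151
672,1.57579
674,1.59053
676,1.60573
678,1.62141
680,1.63758
682,1.65423
684,1.6714
686,1.68907
688,1.70726
690,1.72599
692,1.74525
694,1.76507
696,1.78544
698,1.80638
700,1.82789
702,1.84998
704,1.87267
706,1.89595
708,1.91984
710,1.94434
712,1.96947
714,1.99522
716,2.0216
718,2.04862
720,2.07629
722,2.10461
724,2.13358
726,2.16322
728,2.19352
730,2.22449
732,2.25613
734,2.28844
736,2.32144
738,2.35511
740,2.38946
742,2.42449
744,2.46021
746,2.4966
748,2.53368
750,2.57144
752,2.60987
754,2.64898
756,2.68876
758,2.72921
760,2.77031
762,2.81208
764,2.8545
766,2.89756
768,2.94126
770,2.98559
772,3.03054
774,3.0761
776,3.12225
778,3.169
780,3.21632
782,3.26421
784,3.31265
786,3.36162
788,3.41112
790,3.46112
792,3.51161
794,3.56257
796,3.61398
798,3.66582
800,3.71808
802,3.77074
804,3.82376
806,3.87714
808,3.93084
810,3.98485
812,4.03913
814,4.09367
816,4.14844
818,4.20341
820,4.25855
822,4.31385
824,4.36926
826,4.42476
828,4.48033
830,4.53592
832,4.59151
834,4.64707
836,4.70257
838,4.75798
840,4.81326
842,4.86837
844,4.9233
846,4.97799
848,5.03243
850,5.08657
852,5.14037
854,5.19382
856,5.24687
858,5.29948
860,5.35162
862,5.40325
864,5.45435
866,5.50487
868,5.55479
870,5.60406
872,5.65264
874,5.70052
876,5.74764
878,5.79399
880,5.83951
882,5.88419
884,5.92798
886,5.97086
888,6.01278
890,6.05373
892,6.09367
894,6.13257
896,6.17039
898,6.20711
900,6.2427
902,6.27714
904,6.31039
906,6.34243
908,6.37323
910,6.40278
912,6.43104
914,6.45799
916,6.48361
918,6.50788
920,6.53078
922,6.5523
924,6.57241
926,6.59109
928,6.60834
930,6.62414
932,6.63847
934,6.65133
936,6.6627
938,6.67257
940,6.68094
942,6.68779
944,6.69313
946,6.69695
948,6.69924
950,6.7
952,6.69924
954,6.69695
956,6.69313
958,6.68779
960,6.68094
962,6.67257
964,6.6627
966,6.65133
968,6.63847
970,6.62414
972,6.60834
974,6.59109
976,6.57241
978,6.5523
980,6.53078
982,6.50788
984,6.48361
986,6.45799
988,6.43104
990,6.40278
992,6.37323
994,6.34243
996,6.31039
998,6.27714
1000,6.2427
1002,6.20711
1004,6.17039
1006,6.13257
1008,6.09367
1010,6.05373
1012,6.01278
1014,5.97086
1016,5.92798
1018,5.88419
1020,5.83951
1022,5.79399
1024,5.74764
1026,5.70052
1028,5.65264
1030,5.60406
1032,5.55479
1034,5.50487
1036,5.45435
1038,5.40325
1040,5.35162
1042,5.29948
1044,5.24687
1046,5.19382
1048,5.14037
1050,5.08657
1052,5.03243
1054,4.97799
1056,4.9233
1058,4.86837
1060,4.81326
1062,4.75798
1064,4.70257
1066,4.64707
1068,4.59151
1070,4.53592
1072,4.48033
1074,4.42476
1076,4.36926
1078,4.31385
1080,4.25855
1082,4.20341
1084,4.14844
1086,4.09367
1088,4.03913
1090,3.98485
1092,3.93084
1094,3.87714
1096,3.82376
1098,3.77074
1100,3.71808
1102,3.66582
1104,3.61398
1106,3.56257
1108,3.51161
1110,3.46112
1112,3.41112
1114,3.36162
1116,3.31265
1118,3.26421
1120,3.21632
1122,3.169
1124,3.12225
1126,3.0761
1128,3.03054
1130,2.98559
1132,2.94126
1134,2.89756
1136,2.8545
1138,2.81208
1140,2.77031
1142,2.72921
1144,2.68876
1146,2.64898
1148,2.60987
1150,2.57144
1152,2.53368
1154,2.4966
1156,2.46021
1158,2.42449
1160,2.38946
1162,2.35511
1164,2.32144
1166,2.28844
1168,2.25613
1170,2.22449
1172,2.19352
1174,2.16322
1176,2.13358
1178,2.10461
1180,2.07629
1182,2.04862
1184,2.0216
1186,1.99522
1188,1.96947
1190,1.94434
1192,1.91984
1194,1.89595
1196,1.87267
1198,1.84998
1200,1.82789
1202,1.80638
1204,1.78544
1206,1.76507
1208,1.74525
1210,1.72599
1212,1.70726
1214,1.68907
1216,1.6714
1218,1.65423
1220,1.63758
1222,1.62141
1224,1.60573
1226,1.59053
1228,1.57579
1230,1.56151
1232,1.54767
1234,1.53427
1236,1.5213
1238,1.50874
1240,1.49659
1242,1.48485
1244,1.47349
1246,1.46251
1248,1.4519
1250,1.44165
1252,1.43176
1254,1.42221
1256,1.41299
1258,1.4041
1260,1.39553
1262,1.38726
1264,1.37929
1266,1.37162
1268,1.36423
1270,1.35711
1272,1.35026
1274,1.34367
1276,1.33733
1278,1.33123
1280,1.32537
1282,1.31974
1284,1.31432
1286,1.30913
1288,1.30414
1290,1.29935
1292,1.29475
1294,1.29034
1296,1.28612
1298,1.28206
1300,1.27818
1302,1.27446
1304,1.2709
1306,1.26749
1308,1.26422
1310,1.2611
1312,1.25811
1314,1.25525
1316,1.25252
1318,1.24991
1320,1.24742
1322,1.24504
1324,1.24276
1326,1.24059
1328,1.23852
1330,1.23655
1332,1.23466
1334,1.23287
1336,1.23116
1338,1.22953
1340,1.22797
1342,1.22649
1344,1.22509
1346,1.22375
1348,1.22247
1350,1.22126
1352,1.22011
1354,1.21902
1356,1.21798
1358,1.21699
1360,1.21605
1362,1.21516
1364,1.21431
1366,1.21351
1368,1.21275
1370,1.21203
1372,1.21135
1374,1.2107
1376,1.21009
1378,1.20951
1380,1.20896
1382,1.20844
1384,1.20794
1386,1.20748
1388,1.20704
1390,1.20662
1392,1.20623
1394,1.20586
1396,1.20551
1398,1.20517
1400,1.20486
1402,1.20457
1404,1.20429
1406,1.20402
1408,1.20378
1410,1.20354
1412,1.20332
1414,1.20312
1416,1.20292
1418,1.20274
1420,1.20257
1422,1.2024
1424,1.20225
1426,1.20211
1428,1.20197
1430,1.20185
1432,1.20173
1434,1.20161
1436,1.20151
1438,1.20141
1440,1.20132
1442,1.20123
1444,1.20115
1446,1.20107
1448,1.201
1450,1.20093
1452,1.20087
1454,1.20081
1456,1.20076
1458,1.20071
1460,1.20066
1462,1.20061
1464,1.20057
1466,1.20053
1468,1.20049
1470,1.20046
1472,1.20043
1474,1.2004
1476,1.20037
1478,1.20034
1480,1.20032
1482,1.2003
1484,1.20028
1486,1.20026
1488,1.20024
1490,1.20022
1492,1.2002
1494,1.20019
1496,1.20018
1498,1.20016
1500,1.20015
1502,1.20014
1504,1.20013
1506,1.20012
1508,1.20011
1510,1.2001
1512,1.20009
1514,1.20009
1516,1.20008
1518,1.20008
1520,1.20007
1522,1.20006
1524,1.20006
1526,1.20005
1528,1.20005
1530,1.20005
1532,1.20004
1534,1.20004
1536,1.20004
1538,1.20003
1540,1.20003
1542,1.20003
1544,1.20003
1546,1.20002
1548,1.20002
1550,1.20002
1552,1.20002
1554,1.20002
1556,1.20002
1558,1.20001
1560,1.20001
1562,1.20001
1564,1.20001
1566,1.20001
1568,1.20001
1570,1.20001
1572,1.20001
1574,1.20001
1576,1.20001
1578,1.20001
1580,1.20001
1582,1.20001
1584,1.2
1586,1.2
1588,1.2
1590,1.2
1592,1.2
1594,1.2
1596,1.2
1598,1.2
1600,1.2
1602,1.2
1604,1.2
1606,1.2
1608,1.2
1610,1.2
1612,1.2
1614,1.2
1616,1.2
1618,1.2
1620,1.2
1622,1.2
1624,1.2
1626,1.2
1628,1.2
1630,1.2
1632,1.2
1634,1.2
1636,1.2
1638,1.2
1640,1.2
1642,1.2
1644,1.2
1646,1.2
1648,1.2
1650,1.2
1652,1.2
1654,1.2
1656,1.2
1658,1.2
1660,1.2
1662,1.2
1664,1.2
1666,1.2
1668,1.2
1670,1.2
1672,1.2
1674,1.2
1676,1.2
1678,1.2
1680,1.2
1682,1.2
1684,1.2
1686,1.2
1688,1.2
1690,1.2
1692,1.2
1694,1.2
1696,1.2
1698,1.2
1700,1.2
1702,1.2
1704,1.2
1706,1.2
1708,1.2
1710,1.2
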