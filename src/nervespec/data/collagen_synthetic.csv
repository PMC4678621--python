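wavelength_nm,absorption_cm-1
400,0.12
402,0.12
404,0.12
406,0.12
408,0.12
410,0.12
412,0.12
414,0.12
416,0.12
418,0.12
420,0.12
422,0.12
424,0.12
426,0.12
428,0.12
430,0.12
432,0.12
434,0.12
436,0.12
438,0.12
440,0.12
442,0.12
444,0.12
446,0.12
448,0.12
450,0.12
452,0.12
454,0.12
456,0.12
458,0.12
460,0.12
462,0.12
464,0.12
466,0.12
468,0.12
470,0.12
472,0.12
474,0.12
476,0.12
478,0.12
480,0.12
482,0.12
484,0.12
486,0.12
488,0.12
490,0.12
492,0.12
494,0.12
496,0.12
498,0.12
500,0.12
502,0.12
504,0.12
506,0.12
508,0.12
510,0.12
512,0.12
514,0.12
516,0.12
518,0.12
520,0.12
522,0.12
524,0.12
526,0.12
528,0.12
530,0.12
532,0.12
534,0.12
536,0.12
538,0.12
540,0.12
542,0.12
544,0.12
546,0.12
548,0.12
550,0.12
552,0.12
554,0.12
556,0.12
558,0.12
560,0.12
562,0.12
564,0.12
566,0.12
568,0.12
570,0.12
572,0.12
574,0.12
576,0.12
578,0.12
580,0.12
582,0.12
584,0.12
586,0.12
588,0.12
590,0.12
592,0.12
594,0.12
596,0.12
598,0.12
600,0.12
602,0.12
604,0.12
606,0.12
608,0.12
610,0.12
612,0.12
614,0.12
616,0.12
618,0.12
620,0.12
622,0.12
624,0.12
626,0.12
628,0.12
630,0.12
632,0.12
634,0.12
636,0.12
638,0.12
640,0.12
642,0.12
644,0.12
646,0.12
648,0.12
650,0.12
652,0.12
654,0.12
656,0.12
658,0.12
660,0.12
662,0.12
664,0.12
666,0.12
668,0.12
670,0.12
672,0.12
674,0.12
676,0.12
678,0.12
680,0.12
682,0.12
684,0.12
686,0.12
688,0.12
690,0.12
692,0.12
694,0.12
696,0.12
698,0.12
700,0.12
702,0.12
704,0.12
706,0.12
708,0.12
710,0.12
712,0.12
714,0.12
716,0.12
718,0.12
720,0.12
722,0.12
724,0.12
726,0.12
728,0.12
730,0.12
732,0.12
734,0.12
736,0.12
738,0.12
740,0.12
742,0.12
744,0.12
746,0.12
748,0.12
750,0.12
752,0.12
754,0.12
756,0.12
758,0.12
760,0.12
762,0.12
764,0.12
766,0.12
768,0.12
770,0.12
772,0.12
774,0.12
776,0.12
778,0.12
780,0.12
782,0.12
784,0.12
786,0.12
788,0.12
790,0.12
792,0.12
794,0.12
796,0.12
798,0.12
800,0.12
802,0.12
804,0.12
806,0.12
808,0.12
810,0.12
812,0.12
814,0.12
816,0.12
818,0.12
820,0.12
822,0.12
824,0.12
826,0.12
828,0.12
830,0.12
832,0.12
834,0.12
836,0.12
838,0.12
840,0.12
842,0.12
844,0.12
846,0.12
848,0.12
850,0.12
852,0.12
854,0.12
856,0.12
858,0.12
860,0.12
862,0.12
864,0.12
866,0.12
868,0.12
870,0.12
872,0.12
874,0.12
876,0.12
878,0.12
880,0.12
882,0.12
884,0.120001
886,0.120001
888,0.120001
890,0.120001
892,0.120001
894,0.120001
896,0.120001
898,0.120002
900,0.120002
902,0.120002
904,0.120003
906,0.120003
908,0.120004
910,0.120005
912,0.120005
914,0.120006
916,0.120008
918,0.120009
920,0.12001
922,0.120012
924,0.120014
926,0.120016
928,0.120019
930,0.120022
932,0.120026
934,0.12003
936,0.120034
938,0.12004
940,0.120046
942,0.120053
944,0.120061
946,0.120071
948,0.120081
950,0.120093
952,0.120107
954,0.120123
956,0.120141
958,0.120161
960,0.120185
962,0.120211
964,0.12024
966,0.120274
968,0.120312
970,0.120354
972,0.120402
974,0.120457
976,0.120517
978,0.120586
980,0.120662
982,0.120748
984,0.120844
986,0.120951
988,0.12107
990,0.121203
992,0.121351
994,0.121516
996,0.121699
998,0.121902
1000,0.122126
1002,0.122375
1004,0.122649
1006,0.122953
1008,0.123287
1010,0.123655
1012,0.124059
1014,0.124504
1016,0.124991
1018,0.125525
1020,0.12611
1022,0.126749
1024,0.127446
1026,0.128206
1028,0.129034
1030,0.129935
1032,0.130913
1034,0.131974
1036,0.133123
1038,0.134367
1040,0.135711
1042,0.137162
1044,0.138726
1046,0.14041
1048,0.142221
1050,0.144165
1052,0.146251
1054,0.148485
1056,0.150874
1058,0.153427
1060,0.156151
1062,0.159053
1064,0.162142
1066,0.165424
1068,0.168907
1070,0.172599
1072,0.176507
1074,0.180638
1076,0.184999
1078,0.189596
1080,0.194435
1082,0.199523
1084,0.204863
1086,0.210462
1088,0.216323
1090,0.22245
1092,0.228846
1094,0.235513
1096,0.242452
1098,0.249663
1100,0.257147
1102,0.264902
1104,0.272925
1106,0.281213
1108,0.289761
1110,0.298565
1112,0.307616
1114,0.316908
1116,0.32643
1118,0.336172
1120,0.346123
1122,0.356269
1124,0.366596
1126,0.37709
1128,0.387732
1130,0.398505
1132,0.40939
1134,0.420366
1136,0.431414
1138,0.442508
1140,0.453628
1142,0.464748
1144,0.475843
1146,0.486888
1148,0.497856
1150,0.508721
1152,0.519454
1154,0.530028
1156,0.540415
1158,0.550588
1160,0.560517
1162,0.570176
1164,0.579537
1166,0.588573
1168,0.597258
1170,0.605565
1172,0.613469
1174,0.620948
1176,0.627976
1178,0.634534
1180,0.640601
1182,0.646157
1184,0.651185
1186,0.655669
1188,0.659595
1190,0.662951
1192,0.665726
1194,0.667912
1196,0.669502
1198,0.670491
1200,0.670878
1202,0.670662
1204,0.669844
1206,0.668428
1208,0.66642
1210,0.663828
1212,0.660662
1214,0.656933
1216,0.652656
1218,0.647846
1220,0.64252
1222,0.636697
1224,0.630398
1226,0.623646
1228,0.616462
1230,0.608873
1232,0.600904
1234,0.592583
1236,0.583936
1238,0.574994
1240,0.565784
1242,0.556338
1244,0.546685
1246,0.536856
1248,0.526882
1250,0.516794
1252,0.506623
1254,0.496399
1256,0.486153
1258,0.475914
1260,0.465713
1262,0.455578
1264,0.445538
1266,0.43562
1268,0.425852
1270,0.416259
1272,0.406866
1274,0.397699
1276,0.388779
1278,0.38013
1280,0.371772
1282,0.363726
1284,0.356011
1286,0.348646
1288,0.341646
1290,0.33503
1292,0.32881
1294,0.323002
1296,0.317619
1298,0.312673
1300,0.308175
1302,0.304136
1304,0.300565
1306,0.297472
1308,0.294864
1310,0.292748
1312,0.291132
1314,0.290021
1316,0.289421
1318,0.289337
1320,0.289774
1322,0.290736
1324,0.292225
1326,0.294246
1328,0.296802
1330,0.299894
1332,0.303526
1334,0.307698
1336,0.312413
1338,0.317673
1340,0.323477
1342,0.329828
1344,0.336725
1346,0.34417
1348,0.352162
1350,0.360702
1352,0.369788
1354,0.379421
1356,0.389599
1358,0.400321
1360,0.411586
1362,0.423391
1364,0.435734
1366,0.448612
1368,0.462022
1370,0.47596
1372,0.490421
1374,0.505401
1376,0.520894
1378,0.536894
1380,0.553395
1382,0.570387
1384,0.587864
1386,0.605815
1388,0.624232
1390,0.643103
1392,0.662416
1394,0.682159
1396,0.702319
1398,0.72288
1400,0.743829
1402,0.765147
1404,0.786818
1406,0.808823
1408,0.831143
1410,0.853758
1412,0.876645
1414,0.899783
1416,0.923149
1418,0.946717
1420,0.970462
1422,0.994359
1424,1.01838
1426,1.0425
1428,1.06668
1430,1.0909
1432,1.11513
1434,1.13934
1436,1.16349
1438,1.18755
1440,1.2115
1442,1.23529
1444,1.2589
1446,1.28228
1448,1.30542
1450,1.32826
1452,1.35079
1454,1.37296
1456,1.39474
1458,1.4161
1460,1.43701
1462,1.45743
1464,1.47733
1466,1.49669
1468,1.51546
1470,1.53363
1472,1.55116
1474,1.56802
1476,1.5842
1478,1.59966
1480,1.61438
1482,1.62835
1484,1.64153
1486,1.65392
1488,1.6655
1490,1.67625
1492,1.68615
1494,1.69521
1496,1.70341
1498,1.71075
1500,1.71722
1502,1.72282
1504,1.72755
1506,1.73142
1508,1.73444
1510,1.73661
1512,1.73795
1514,1.73847
1516,1.73819
1518,1.73714
1520,1.73532
1522,1.73278
1524,1.72953
1526,1.72562
1528,1.72107
1530,1.71593
1532,1.71023
1534,1.70402
1536,1.69734
1538,1.69024
1540,1.68278
1542,1.675
1544,1.66695
1546,1.6587
1548,1.65031
1550,1.64184
1552,1.63334
1554,1.62489
1556,1.61654
1558,1.60837
1560,1.60045
1562,1.59283
1564,1.58559
1566,1.5788
1568,1.57252
1570,1.56683
1572,1.56179
1574,1.55746
1576,1.55392
1578,1.55123
1580,1.54944
1582,1.54862
1584,1.54883
1586,1.55012
1588,1.55253
1590,1.55613
1592,1.56094
1594,1.56701
1596,1.57439
1598,1.58308
1600,1.59313
1602,1.60456
1604,1.61736
1606,1.63157
1608,1.64717
1610,1.66416
1612,1.68254
1614,1.70229
1616,1.72338
1618,1.74579
1620,1.76947
1622,1.79439
1624,1.82049
1626,1.84772
1628,1.87601
1630,1.90528
1632,1.93547
1634,1.96649
1636,1.99826
1638,2.03066
1640,2.06361
1642,2.097
1644,2.13071
1646,2.16464
1648,2.19865
1650,2.23264
1652,2.26648
1654,2.30004
1656,2.33318
1658,2.36579
1660,2.39772
1662,2.42885
1664,2.45905
1666,2.48819
1668,2.51614
1670,2.54278
1672,2.56799
1674,2.59165
1676,2.61364
1678,2.63387
1680,2.65223
1682,2.66861
1684,2.68294
1686,2.69514
1688,2.70512
1690,2.71281
1692,2.71817
1694,2.72114
1696,2.72168
1698,2.71975
1700,2.71534
1702,2.70843
1704,2.69901
1706,2.68709
1708,2.67269
1710,2.65582
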