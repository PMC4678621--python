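wavelength_nm,absorption_cm-1
400,454.533
402,550.075
404,657.615
406,776.608
408,905.947
410,1043.92
412,1188.2
414,1335.87
416,1483.5
418,1627.28
420,1763.12
422,1886.89
424,1994.6
426,2082.61
428,2147.84
430,2187.96
432,2201.5
434,2187.96
436,2147.84
438,2082.61
440,1994.6
442,1886.89
444,1763.12
446,1627.28
448,1483.5
450,1335.87
452,1188.2
454,1043.92
456,905.947
458,776.608
460,657.615
462,550.075
464,454.534
466,371.041
468,299.238
470,238.443
472,187.748
474,146.104
476,112.394
478,85.4992
480,64.348
482,47.948
484,35.4103
486,25.9598
488,18.9381
490,13.7989
492,10.0996
494,7.49076
496,5.7042
498,4.5417
500,3.86478
502,3.58619
504,3.66317
506,4.09262
508,4.90777
510,6.17593
512,7.99683
514,10.5007
516,13.8451
518,18.2106
520,23.7929
522,30.7925
524,39.4009
526,49.7832
528,62.0584
530,76.2782
532,92.4063
534,110.3
536,129.697
538,150.211
540,171.333
542,192.448
544,212.86
546,231.827
548,248.605
550,262.495
552,272.892
554,279.328
556,281.508
558,279.329
560,272.894
562,262.498
564,248.609
566,231.832
568,212.867
570,192.456
572,171.342
574,150.221
576,129.708
578,110.312
580,92.42
582,76.293
584,62.0739
586,49.7991
588,39.4163
590,30.806
592,23.8021
594,18.2116
596,13.8313
598,10.4613
600,7.91513
602,6.0254
604,4.64757
606,3.66057
608,2.96594
610,2.48571
612,2.15968
614,1.94245
616,1.80059
618,1.70999
620,1.65364
622,1.6198
624,1.60052
626,1.59051
628,1.58636
630,1.58586
632,1.58767
634,1.59093
636,1.59517
638,1.60009
640,1.60555
642,1.61145
644,1.61779
646,1.62456
648,1.6318
650,1.63954
652,1.64784
654,1.65679
656,1.66647
658,1.67699
660,1.68849
662,1.70113
664,1.71509
666,1.7306
668,1.74792
670,1.76735
672,1.78926
674,1.81404
676,1.84217
678,1.87416
680,1.91062
682,1.9522
684,1.99962
686,2.05368
688,2.11524
690,2.18521
692,2.26456
694,2.35429
696,2.45542
698,2.56899
700,2.69602
702,2.83748
704,2.99428
706,3.16722
708,3.35699
710,3.56409
712,3.78882
714,4.03125
716,4.29119
718,4.56813
720,4.86126
722,5.16939
724,5.49102
726,5.82424
728,6.16683
730,6.51619
732,6.86943
734,7.22336
736,7.57456
738,7.91943
740,8.25427
742,8.57529
744,8.87877
746,9.16109
748,9.41881
750,9.64877
752,9.84812
754,10.0145
756,10.1459
758,10.2409
760,10.2986
762,10.3188
764,10.3017
766,10.2481
768,10.1595
770,10.0379
772,9.88547
774,9.70517
776,9.5001
778,9.27368
780,9.02951
782,8.77129
784,8.50276
786,8.22762
788,7.94944
790,7.6716
792,7.39728
794,7.12934
796,6.87034
798,6.62249
800,6.38766
802,6.16733
804,5.96266
806,5.77442
808,5.6031
810,5.44887
812,5.31162
814,5.19102
816,5.08653
818,4.99744
820,4.92292
822,4.86203
824,4.81376
826,4.77706
828,4.75087
830,4.73412
832,4.72579
834,4.72487
836,4.73042
838,4.74154
840,4.75742
842,4.77729
844,4.80046
846,4.82632
848,4.85429
850,4.88389
852,4.91468
854,4.94627
856,4.97833
858,5.01057
860,5.04273
862,5.0746
864,5.10599
866,5.13674
868,5.16672
870,5.1958
872,5.2239
874,5.25091
876,5.27676
878,5.3014
880,5.32476
882,5.3468
884,5.36747
886,5.38674
888,5.40458
890,5.42095
892,5.43583
894,5.44921
896,5.46105
898,5.47134
900,5.48008
902,5.48724
904,5.49282
906,5.49681
908,5.49921
910,5.5
912,5.4992
914,5.4968
916,5.49281
918,5.48722
920,5.48005
922,5.4713
924,5.46099
926,5.44913
928,5.43572
930,5.42079
932,5.40436
934,5.38644
936,5.36706
938,5.34623
940,5.32399
942,5.30035
944,5.27535
946,5.24902
948,5.22138
950,5.19247
952,5.16231
954,5.13095
956,5.09842
958,5.06475
960,5.02999
962,4.99416
964,4.95732
966,4.9195
968,4.88074
970,4.84108
972,4.80057
974,4.75924
976,4.71715
978,4.67432
980,4.63082
982,4.58667
984,4.54194
986,4.49665
988,4.45085
990,4.4046
992,4.35792
994,4.31087
996,4.26349
998,4.21582
1000,4.16791
1002,4.11979
1004,4.07151
1006,4.02312
1008,3.97464
1010,3.92612
1012,3.87761
1014,3.82913
1016,3.78073
1018,3.73244
1020,3.6843
1022,3.63634
1024,3.5886
1026,3.54111
1028,3.4939
1030,3.44701
1032,3.40046
1034,3.35428
1036,3.30849
1038,3.26314
1040,3.21823
1042,3.1738
1044,3.12986
1046,3.08644
1048,3.04356
1050,3.00124
1052,2.9595
1054,2.91835
1056,2.87781
1058,2.83789
1060,2.79861
1062,2.75998
1064,2.72201
1066,2.68471
1068,2.64808
1070,2.61215
1072,2.57691
1074,2.54237
1076,2.50853
1078,2.4754
1080,2.44298
1082,2.41128
1084,2.38029
1086,2.35001
1088,2.32045
1090,2.29159
1092,2.26345
1094,2.23601
1096,2.20928
1098,2.18324
1100,2.1579
1102,2.13324
1104,2.10926
1106,2.08596
1108,2.06332
1110,2.04134
1112,2.02001
1114,1.99932
1116,1.97926
1118,1.95983
1120,1.941
1122,1.92278
1124,1.90515
1126,1.88809
1128,1.87161
1130,1.85569
1132,1.84031
1134,1.82546
1136,1.81114
1138,1.79733
1140,1.78402
1142,1.7712
1144,1.75885
1146,1.74697
1148,1.73553
1150,1.72454
1152,1.71397
1154,1.70382
1156,1.69408
1158,1.68472
1160,1.67575
1162,1.66714
1164,1.6589
1166,1.651
1168,1.64343
1170,1.63619
1172,1.62926
1174,1.62264
1176,1.61631
1178,1.61026
1180,1.60449
1182,1.59897
1184,1.59371
1186,1.5887
1188,1.58392
1190,1.57936
1192,1.57503
1194,1.5709
1196,1.56697
1198,1.56323
1200,1.55968
1202,1.55631
1204,1.5531
1206,1.55006
1208,1.54717
1210,1.54444
1212,1.54184
1214,1.53938
1216,1.53705
1218,1.53484
1220,1.53275
1222,1.53078
1224,1.52891
1226,1.52715
1228,1.52548
1230,1.5239
1232,1.52242
1234,1.52102
1236,1.51969
1238,1.51845
1240,1.51727
1242,1.51617
1244,1.51512
1246,1.51414
1248,1.51322
1250,1.51235
1252,1.51154
1254,1.51078
1256,1.51006
1258,1.50938
1260,1.50875
1262,1.50816
1264,1.5076
1266,1.50708
1268,1.50659
1270,1.50614
1272,1.50571
1274,1.50531
1276,1.50493
1278,1.50459
1280,1.50426
1282,1.50395
1284,1.50367
1286,1.50341
1288,1.50316
1290,1.50293
1292,1.50271
1294,1.50251
1296,1.50233
1298,1.50215
1300,1.50199
1302,1.50184
1304,1.5017
1306,1.50157
1308,1.50145
1310,1.50134
1312,1.50124
1314,1.50114
1316,1.50105
1318,1.50097
1320,1.50089
1322,1.50082
1324,1.50076
1326,1.5007
1328,1.50064
1330,1.50059
1332,1.50054
1334,1.5005
1336,1.50046
1338,1.50042
1340,1.50039
1342,1.50035
1344,1.50033
1346,1.5003
1348,1.50027
1350,1.50025
1352,1.50023
1354,1.50021
1356,1.50019
1358,1.50018
1360,1.50016
1362,1.50015
1364,1.50013
1366,1.50012
1368,1.50011
1370,1.5001
1372,1.50009
1374,1.50008
1376,1.50008
1378,1.50007
1380,1.50006
1382,1.50006
1384,1.50005
1386,1.50005
1388,1.50004
1390,1.50004
1392,1.50004
1394,1.50003
1396,1.50003
1398,1.50003
1400,1.50002
1402,1.50002
1404,1.50002
1406,1.50002
1408,1.50002
1410,1.50001
1412,1.50001
1414,1.50001
1416,1.50001
1418,1.50001
1420,1.50001
1422,1.50001
1424,1.50001
1426,1.50001
1428,1.50001
1430,1.50001
1432,1.5
1434,1.5
1436,1.5
1438,1.5
1440,1.5
1442,1.5
1444,1.5
1446,1.5
1448,1.5
1450,1.5
1452,1.5
1454,1.5
1456,1.5
1458,1.5
1460,1.5
1462,1.5
1464,1.5
1466,1.5
1468,1.5
1470,1.5
1472,1.5
1474,1.5
1476,1.5
1478,1.5
1480,1.5
1482,1.5
1484,1.5
1486,1.5
1488,1.5
1490,1.5
1492,1.5
1494,1.5
1496,1.5
1498,1.5
1500,1.5
1502,1.5
1504,1.5
1506,1.5
1508,1.5
1510,1.5
1512,1.5
1514,1.5
1516,1.5
1518,1.5
1520,1.5
1522,1.5
1524,1.5
1526,1.5
1528,1.5
1530,1.5
1532,1.5
1534,1.5
1536,1.5
1538,1.5
1540,1.5
1542,1.5
1544,1.5
1546,1.5
1548,1.5
1550,1.5
1552,1.5
1554,1.5
1556,1.5
1558,1.5
1560,1.5
1562,1.5
1564,1.5
1566,1.5
1568,1.5
1570,1.5
1572,1.5
1574,1.5
1576,1.5
1578,1.5
1580,1.5
1582,1.5
1584,1.5
1586,1.5
1588,1.5
1590,1.5
1592,1.5
1594,1.5
1596,1.5
1598,1.5
1600,1.5
1602,1.5
1604,1.5
1606,1.5
1608,1.5
1610,1.5
1612,1.5
1614,1.5
1616,1.5
1618,1.5
1620,1.5
1622,1.5
1624,1.5
1626,1.5
1628,1.5
1630,1.5
1632,1.5
1634,1.5
1636,1.5
1638,1.5
1640,1.5
1642,1.5
1644,1.5
1646,1.5
1648,1.5
1650,1.5
1652,1.5
1654,1.5
1656,1.5
1658,1.5
1660,1.5
1662,1.5
1664,1.5
1666,1.5
1668,1.5
1670,1.5
1672,1.5
1674,1.5
1676,1.5
1678,1.5
1680,1.5
1682,1.5
1684,1.5
1686,1.5
1688,1.5
1690,1.5
1692,1.5
1694,1.5
1696,1.5
1698,1.5
1700,1.5
1702,1.5
1704,1.5
1706,1.5
1708,1.5
1710,1.5
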