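wavelength_nm,value
340,0.95
342,0.95
344,0.95
346,0.95
348,0.95
350,0.95
352,0.95
354,0.95
356,0.95
358,0.95
360,0.95
362,0.95
364,0.95
366,0.95
368,0.95
370,0.95
372,0.95
374,0.95
376,0.94999
378,0.94998
380,0.94996
382,0.94988
384,0.94968
386,0.94913
388,0.94765
390,0.94364
392,0.93291
394,0.90495
396,0.83676
398,0.69451
400,0.475
402,0.25549
404,0.11324
406,0.045055
408,0.017087
410,0.0063582
412,0.002349
414,0.0008655
416,0.00031858
418,0.00011722
420,4.3128e-05
422,1.5866e-05
424,5.837e-06
426,2.1473e-06
428,7.8995e-07
430,2.9061e-07
432,1.0691e-07
434,3.9329e-08
436,1.4468e-08
438,5.3227e-09
440,1.9581e-09
442,7.2034e-10
444,2.65e-10
446,9.7488e-11
448,3.5864e-11
450,1.3194e-11
452,4.8536e-12
454,1.7856e-12
456,6.5687e-13
458,2.4165e-13
460,8.8897e-14
462,3.2704e-14
464,1.2031e-14
466,4.4259e-15
468,1.6282e-15
470,5.9899e-16
472,2.2035e-16
474,8.1064e-17
476,2.9822e-17
478,1.0971e-17
480,4.0359e-18
482,1.4847e-18
484,5.462e-19
486,2.0094e-19
488,7.3921e-20
490,2.7194e-20
492,1.0004e-20
494,3.6803e-21
496,1.3539e-21
498,4.9807e-22
500,1.8323e-22
502,6.7407e-23
504,2.4798e-23
506,9.1225e-24
508,3.356e-24
510,1.2346e-24
512,4.5418e-25
514,1.6709e-25
516,6.1467e-26
518,2.2613e-26
520,8.3187e-27
522,3.0603e-27
524,1.1258e-27
526,4.1416e-28
528,1.5236e-28
530,5.6051e-29
532,2.062e-29
534,7.5857e-30
536,2.7906e-30
538,1.0266e-30
540,3.7767e-31
542,1.3894e-31
544,5.1112e-32
546,1.8803e-32
548,6.9172e-33
550,2.5447e-33
552,9.3614e-34
554,3.4439e-34
556,1.2669e-34
558,4.6608e-35
560,1.7146e-35
562,6.3077e-36
564,2.3205e-36
566,8.5365e-37
568,3.1404e-37
570,1.1553e-37
572,4.2501e-38
574,1.5635e-38
576,5.7519e-39
578,2.116e-39
580,7.7843e-40
582,2.8637e-40
584,1.0535e-40
586,3.8756e-41
588,1.4257e-41
590,5.245e-42
592,1.9295e-42
594,7.0984e-43
596,2.6113e-43
598,9.6066e-44
600,3.5341e-44
602,1.3001e-44
604,4.7828e-45
606,1.7595e-45
608,6.4729e-46
610,2.3812e-46
612,8.7601e-47
614,3.2227e-47
616,1.1855e-47
618,4.3614e-48
620,1.6045e-48
622,5.9025e-49
624,2.1714e-49
626,7.9882e-50
628,2.9387e-50
630,1.0811e-50
632,3.9771e-51
634,1.4631e-51
636,5.3824e-52
638,1.9801e-52
640,7.2843e-53
642,2.6797e-53
644,9.8582e-54
646,3.6266e-54
648,1.3342e-54
650,4.9081e-55
652,1.8056e-55
654,6.6424e-56
656,2.4436e-56
658,8.9895e-57
660,3.3071e-57
662,1.2166e-57
664,4.4756e-58
666,1.6465e-58
668,6.0571e-59
670,2.2283e-59
672,8.1974e-60
674,3.0156e-60
676,1.1094e-60
678,4.0812e-61
680,1.5014e-61
682,5.5233e-62
684,2.0319e-62
686,7.475e-63
688,2.7499e-63
690,1.0116e-63
692,3.7216e-64
694,1.3691e-64
696,5.0366e-65
698,1.8529e-65
700,6.8163e-66
702,2.5076e-66
704,9.2249e-67
706,3.3937e-67
708,1.2485e-67
710,4.5928e-68
712,1.6896e-68
714,6.2157e-69
716,2.2866e-69
718,8.412e-70
720,3.0946e-70
722,1.1384e-70
724,4.1881e-71
726,1.5407e-71
728,5.668e-72
730,2.0851e-72
732,7.6708e-73
734,2.8219e-73
736,1.0381e-73
738,3.8191e-74
740,1.405e-74
742,5.1685e-75
744,1.9014e-75
746,6.9948e-76
748,2.5733e-76
750,9.4665e-77
752,3.4825e-77
754,1.2812e-77
756,4.7131e-78
758,1.7338e-78
760,6.3785e-79
762,2.3465e-79
764,8.6323e-80
766,3.1757e-80
768,1.1683e-80
770,4.2978e-81
772,1.5811e-81
774,5.8164e-82
776,2.1397e-82
778,7.8717e-83
780,2.8958e-83
782,1.0653e-83
784,3.9191e-84
786,1.4417e-84
788,5.3039e-85
790,1.9512e-85
792,7.178e-86
794,2.6406e-86
796,9.7144e-87
798,3.5737e-87
800,1.3147e-87
802,4.8365e-88
804,1.7793e-88
806,6.5455e-89
808,2.408e-89
810,8.8584e-90
812,3.2588e-90
814,1.1989e-90
816,4.4103e-91
818,1.6225e-91
820,5.9687e-92
822,2.1958e-92
824,8.0778e-93
826,2.9717e-93
828,1.0932e-93
830,4.0217e-94
832,1.4795e-94
834,5.4428e-95
836,2.0023e-95
838,7.366e-96
840,2.7098e-96
842,9.9688e-97
844,3.6673e-97
846,1.3491e-97
848,4.9632e-98
850,1.8259e-98
852,6.7169e-99
854,2.471e-99
856,9.0904e-100
858,3.3442e-100
860,1.2302e-100
862,4.5258e-101
864,1.665e-101
866,6.125e-102
868,2.2533e-102
870,8.2893e-103
872,3.0495e-103
874,1.1218e-103
876,4.127e-104
878,1.5182e-104
880,5.5853e-105
882,2.0547e-105
884,7.5589e-106
886,2.7808e-106
888,1.023e-106
890,3.7634e-107
892,1.3845e-107
894,5.0932e-108
896,1.8737e-108
898,6.8928e-109
900,2.5357e-109
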