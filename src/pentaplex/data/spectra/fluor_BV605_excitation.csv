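wavelength_nm,value
340,0.055323
342,0.067293
344,0.081063
346,0.096717
348,0.11431
350,0.13384
352,0.15529
354,0.17857
356,0.20359
358,0.23021
360,0.25828
362,0.28765
364,0.31819
366,0.34982
368,0.38248
370,0.4162
372,0.45104
374,0.48713
376,0.52462
378,0.56363
380,0.60426
382,0.64646
384,0.69005
386,0.73461
388,0.7795
390,0.82378
392,0.86629
394,0.9056
396,0.94016
398,0.96836
400,0.98862
402,0.99954
404,1
406,0.98929
408,0.96717
410,0.93389
412,0.89022
414,0.8374
416,0.77705
418,0.71109
420,0.64157
422,0.57059
424,0.50013
426,0.43197
428,0.36761
430,0.3082
432,0.25453
434,0.20706
436,0.16591
438,0.13093
440,0.10176
442,0.077889
444,0.05871
446,0.043579
448,0.031855
450,0.022929
452,0.016252
454,0.011343
456,0.0077961
458,0.0052762
460,0.0035163
462,0.0023075
464,0.0014912
466,0.00094896
468,0.00059469
470,0.00036701
472,0.00022306
474,0.00013352
476,7.8711e-05
478,4.5704e-05
480,2.6141e-05
482,1.4728e-05
484,8.1752e-06
486,4.471e-06
488,2.4095e-06
490,1.2798e-06
492,6.7002e-07
494,3.4585e-07
496,1.7606e-07
498,8.8409e-08
500,4.381e-08
502,2.1432e-08
504,1.0355e-08
506,4.9445e-09
508,2.3345e-09
510,1.0907e-09
512,5.0465e-10
514,2.3144e-10
516,1.0531e-10
518,4.7583e-11
520,2.1374e-11
522,9.5536e-12
524,4.2529e-12
526,1.8871e-12
528,8.3508e-13
530,3.6871e-13
532,1.6246e-13
534,7.1428e-14
536,3.1329e-14
538,1.3702e-14
540,5.9726e-15
542,2.5927e-15
544,1.1201e-15
546,4.8127e-16
548,2.0552e-16
550,8.7167e-17
552,3.67e-17
554,1.5331e-17
556,6.352e-18
558,2.6092e-18
560,1.0623e-18
562,4.2855e-19
564,1.7128e-19
566,6.7813e-20
568,2.6591e-20
570,1.0327e-20
572,3.9713e-21
574,1.5123e-21
576,5.7022e-22
578,2.1289e-22
580,7.8697e-23
582,2.8803e-23
584,1.0437e-23
586,3.7446e-24
588,1.3301e-24
590,4.6778e-25
592,1.6287e-25
594,5.6147e-26
596,1.9162e-26
598,6.475e-27
600,2.1661e-27
602,7.1744e-28
604,2.3526e-28
606,7.6378e-29
608,2.4549e-29
610,7.8122e-30
612,2.4613e-30
614,7.6773e-31
616,2.3709e-31
618,7.249e-32
620,2.1943e-32
622,6.5761e-33
624,1.9512e-33
626,5.7318e-34
628,1.667e-34
630,4.8e-35
632,1.3684e-35
634,3.8621e-36
636,1.0792e-36
638,2.9855e-37
640,8.1774e-38
642,2.2175e-38
644,5.9534e-39
646,1.5824e-39
648,4.1643e-40
650,1.085e-40
652,2.7986e-41
654,7.1471e-42
656,1.8071e-42
658,4.5235e-43
660,1.1211e-43
662,2.7508e-44
664,6.6823e-45
666,1.6072e-45
668,3.8269e-46
670,9.0217e-47
672,2.1057e-47
674,4.8657e-48
676,1.1132e-48
678,2.5214e-49
680,5.6542e-50
682,1.2553e-50
684,2.7593e-51
686,6.0048e-52
688,1.2938e-52
690,2.7598e-53
692,5.8283e-54
694,1.2186e-54
696,2.5227e-55
698,5.1701e-56
700,1.0491e-56
702,2.1075e-57
704,4.1916e-58
706,8.2537e-59
708,1.6091e-59
710,3.1057e-60
712,5.9348e-61
714,1.1228e-61
716,2.1031e-62
718,3.9001e-63
720,7.1605e-64
722,1.3016e-64
724,2.3424e-65
726,4.1735e-66
728,7.362e-67
730,1.2857e-67
732,2.2231e-68
734,3.8057e-69
736,6.4501e-70
738,1.0823e-70
740,1.798e-71
742,2.9573e-72
744,4.8155e-73
746,7.7635e-74
748,1.2392e-74
750,1.9582e-75
752,3.0636e-76
754,4.7455e-77
756,7.2774e-78
758,1.1049e-78
760,1.6609e-79
762,2.4718e-80
764,3.642e-81
766,5.3128e-82
768,7.6729e-83
770,1.0971e-83
772,1.5531e-84
774,2.1768e-85
776,3.0206e-86
778,4.1497e-87
780,5.6442e-88
782,7.6005e-89
784,1.0133e-89
786,1.3375e-90
788,1.7478e-91
790,2.2614e-92
792,2.8966e-93
794,3.6735e-94
796,4.6123e-95
798,5.7334e-96
800,7.0561e-97
802,8.5975e-98
804,1.0371e-98
806,1.2387e-99
808,1.4647e-100
810,1.7147e-101
812,1.9874e-102
814,2.2805e-103
816,2.5908e-104
818,2.9141e-105
820,3.2451e-106
822,3.5778e-107
824,3.9053e-108
826,4.2203e-109
828,4.5154e-110
830,4.7831e-111
832,5.0162e-112
834,5.2083e-113
836,5.354e-114
838,5.4489e-115
840,5.4904e-116
842,5.4772e-117
844,5.4096e-118
846,5.2897e-119
848,5.121e-120
850,4.9083e-121
852,4.6577e-122
854,4.3759e-123
856,4.0702e-124
858,3.7482e-125
860,3.4173e-126
862,3.0847e-127
864,2.7567e-128
866,2.4391e-129
868,2.1366e-130
870,1.853e-131
872,1.591e-132
874,1.3525e-133
876,1.1383e-134
878,9.485e-136
880,7.8248e-137
882,6.3909e-138
884,5.1679e-139
886,4.1373e-140
888,3.2793e-141
890,2.5734e-142
892,1.9993e-143
894,1.5379e-144
896,1.1711e-145
898,8.8299e-147
900,6.5912e-148
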