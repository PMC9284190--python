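wavelength_nm,value
340,1.0474e-160
342,5.008e-159
344,2.3462e-157
346,1.077e-155
348,4.8438e-154
350,2.1345e-152
352,9.2162e-151
354,3.8989e-149
356,1.6161e-147
358,6.5634e-146
360,2.6117e-144
362,1.0183e-142
364,3.8899e-141
366,1.4559e-139
368,5.3394e-138
370,1.9186e-136
372,6.7545e-135
374,2.33e-133
376,7.8749e-132
378,2.6078e-130
380,8.4614e-129
382,2.69e-127
384,8.3789e-126
386,2.5572e-124
388,7.6468e-123
390,2.2404e-121
392,6.4317e-120
394,1.809e-118
396,4.9855e-117
398,1.3462e-115
400,3.5616e-114
402,9.2325e-113
404,2.3449e-111
406,5.8355e-110
408,1.4228e-108
410,3.3992e-107
412,7.9567e-106
414,1.8249e-104
416,4.1007e-103
418,9.0288e-102
420,1.9477e-100
422,4.1169e-99
424,8.5261e-98
426,1.7301e-96
428,3.4397e-95
430,6.7005e-94
432,1.2789e-92
434,2.3916e-91
436,4.3822e-90
438,7.8674e-89
440,1.3839e-87
442,2.3851e-86
444,4.0277e-85
446,6.6641e-84
448,1.0803e-82
450,1.716e-81
452,2.6706e-80
454,4.0724e-79
456,6.0843e-78
458,8.9067e-77
460,1.2775e-75
462,1.7953e-74
464,2.472e-73
466,3.3351e-72
468,4.4085e-71
470,5.7098e-70
472,7.2457e-69
474,9.0091e-68
476,1.0975e-66
478,1.3101e-65
480,1.5321e-64
482,1.7557e-63
484,1.9712e-62
486,2.1685e-61
488,2.3373e-60
490,2.4683e-59
492,2.5541e-58
494,2.5894e-57
496,2.5722e-56
498,2.5035e-55
500,2.3874e-54
502,2.2307e-53
504,2.0422e-52
506,1.8318e-51
508,1.6099e-50
510,1.3863e-49
512,1.1697e-48
514,9.6696e-48
516,7.8321e-47
518,6.2157e-46
520,4.8332e-45
522,3.6823e-44
524,2.7488e-43
526,2.0105e-42
528,1.4408e-41
530,1.0116e-40
532,6.9597e-40
534,4.6913e-39
536,3.0984e-38
538,2.005e-37
540,1.2713e-36
542,7.8974e-36
544,4.807e-35
546,2.8668e-34
548,1.6752e-33
550,9.5909e-33
552,5.3802e-32
554,2.9571e-31
556,1.5925e-30
558,8.4029e-30
560,4.3442e-29
562,2.2006e-28
564,1.0922e-27
566,5.3111e-27
568,2.5306e-26
570,1.1814e-25
572,5.4037e-25
574,2.4218e-24
576,1.0634e-23
578,4.5753e-23
580,1.9287e-22
582,7.9665e-22
584,3.224e-21
586,1.2784e-20
588,4.9665e-20
590,1.8906e-19
592,7.0512e-19
594,2.5768e-18
596,9.2262e-18
598,3.2367e-17
600,1.1126e-16
602,3.747e-16
604,1.2365e-15
606,3.9977e-15
608,1.2664e-14
610,3.9308e-14
612,1.1954e-13
614,3.5621e-13
616,1.04e-12
618,2.9749e-12
620,8.3379e-12
622,2.2897e-11
624,6.161e-11
626,1.6242e-10
628,4.1955e-10
630,1.0618e-09
632,2.6331e-09
634,6.3976e-09
636,1.523e-08
638,3.5524e-08
640,8.1185e-08
642,1.8179e-07
644,3.9884e-07
646,8.5738e-07
648,1.8058e-06
650,3.7267e-06
652,7.5353e-06
654,1.4928e-05
656,2.8978e-05
658,5.5113e-05
660,0.0001027
662,0.00018752
664,0.00033546
666,0.000588
668,0.0010098
670,0.0016993
672,0.0028016
674,0.0045258
676,0.0071634
678,0.011109
680,0.01688
682,0.02513
684,0.036658
686,0.052393
688,0.07337
690,0.10067
692,0.13534
694,0.17826
696,0.23007
698,0.29092
700,0.36045
702,0.43756
704,0.52045
706,0.60653
708,0.69257
710,0.77484
712,0.84937
714,0.91225
716,0.96001
718,0.98985
720,1
722,0.98985
724,0.96001
726,0.91225
728,0.84937
730,0.77484
732,0.69257
734,0.60653
736,0.52045
738,0.43756
740,0.36045
742,0.29092
744,0.23007
746,0.17826
748,0.13534
750,0.10067
752,0.07337
754,0.052393
756,0.036658
758,0.02513
760,0.01688
762,0.011109
764,0.0071634
766,0.0045258
768,0.0028016
770,0.0016993
772,0.0010098
774,0.000588
776,0.00033546
778,0.00018752
780,0.0001027
782,5.5113e-05
784,2.8978e-05
786,1.4928e-05
788,7.5353e-06
790,3.7267e-06
792,1.8058e-06
794,8.5738e-07
796,3.9884e-07
798,1.8179e-07
800,8.1185e-08
802,3.5524e-08
804,1.523e-08
806,6.3976e-09
808,2.6331e-09
810,1.0618e-09
812,4.1955e-10
814,1.6242e-10
816,6.161e-11
818,2.2897e-11
820,8.3379e-12
822,2.9749e-12
824,1.04e-12
826,3.5621e-13
828,1.1954e-13
830,3.9308e-14
832,1.2664e-14
834,3.9977e-15
836,1.2365e-15
838,3.747e-16
840,1.1126e-16
842,3.2367e-17
844,9.2262e-18
846,2.5768e-18
848,7.0512e-19
850,1.8906e-19
852,4.9665e-20
854,1.2784e-20
856,3.224e-21
858,7.9665e-22
860,1.9287e-22
862,4.5753e-23
864,1.0634e-23
866,2.4218e-24
868,5.4037e-25
870,1.1814e-25
872,2.5306e-26
874,5.3111e-27
876,1.0922e-27
878,2.2006e-28
880,4.3442e-29
882,8.4029e-30
884,1.5925e-30
886,2.9571e-31
888,5.3802e-32
890,9.5909e-33
892,1.6752e-33
894,2.8668e-34
896,4.807e-35
898,7.8974e-36
900,1.2713e-36
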