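wavelength_nm,value
340,1.523e-221
342,1.7765e-218
344,1.9724e-215
346,2.0844e-212
348,2.0965e-209
350,2.0072e-206
352,1.829e-203
354,1.5864e-200
356,1.3096e-197
358,1.0291e-194
360,7.6966e-192
362,5.479e-189
364,3.7124e-186
366,2.3943e-183
368,1.4697e-180
370,8.5872e-178
372,4.7755e-175
374,2.5278e-172
376,1.2736e-169
378,6.1073e-167
380,2.7876e-164
382,1.2111e-161
384,5.008e-159
386,1.9711e-156
388,7.3842e-154
390,2.633e-151
392,8.9363e-149
394,2.8868e-146
396,8.8761e-144
398,2.5977e-141
400,7.2361e-139
402,1.9186e-136
404,4.8417e-134
406,1.163e-131
408,2.6589e-129
410,5.7862e-127
412,1.1985e-124
414,2.3627e-122
416,4.4337e-120
418,7.9188e-118
420,1.3462e-115
422,2.1783e-113
424,3.3548e-111
426,4.9179e-109
428,6.8619e-107
430,9.113e-105
432,1.152e-102
434,1.386e-100
436,1.5872e-98
438,1.7301e-96
440,1.7949e-94
442,1.7725e-92
444,1.666e-90
446,1.4905e-88
448,1.2692e-86
450,1.0287e-84
452,7.9356e-83
454,5.8269e-81
456,4.0724e-79
458,2.709e-77
460,1.7153e-75
462,1.0337e-73
464,5.9296e-72
466,3.2374e-70
468,1.6824e-68
470,8.3218e-67
472,3.9179e-65
474,1.7557e-63
476,7.4885e-62
478,3.0401e-60
480,1.1747e-58
482,4.3206e-57
484,1.5125e-55
486,5.0398e-54
488,1.5984e-52
490,4.825e-51
492,1.3863e-49
494,3.7914e-48
496,9.869e-47
498,2.4452e-45
500,5.7662e-44
502,1.2943e-42
504,2.7652e-41
506,5.623e-40
508,1.0883e-38
510,2.005e-37
512,3.5158e-36
514,5.8679e-35
516,9.3216e-34
518,1.4095e-32
520,2.0285e-31
522,2.7787e-30
524,3.623e-29
526,4.4963e-28
528,5.3111e-27
530,5.9713e-26
532,6.3901e-25
534,6.5088e-24
536,6.3102e-23
538,5.823e-22
540,5.1144e-21
542,4.2757e-20
544,3.4022e-19
546,2.5768e-18
548,1.8575e-17
550,1.2746e-16
552,8.324e-16
554,5.1744e-15
556,3.0615e-14
558,1.7241e-13
560,9.2417e-13
562,4.7151e-12
564,2.2897e-11
566,1.0584e-10
568,4.6562e-10
570,1.9498e-09
572,7.7712e-09
574,2.9481e-08
576,1.0645e-07
578,3.6587e-07
580,1.1969e-06
582,3.7267e-06
584,1.1044e-05
586,3.1155e-05
588,8.3648e-05
590,0.00021377
592,0.00051998
594,0.0012039
596,0.0026529
598,0.0055644
600,0.011109
602,0.02111
604,0.03818
606,0.065729
608,0.1077
610,0.16797
612,0.24935
614,0.35232
616,0.47383
618,0.60653
620,0.73899
622,0.857
624,0.94596
626,0.99385
628,0.99385
630,0.94596
632,0.857
634,0.73899
636,0.60653
638,0.47383
640,0.35232
642,0.24935
644,0.16797
646,0.1077
648,0.065729
650,0.03818
652,0.02111
654,0.011109
656,0.0055644
658,0.0026529
660,0.0012039
662,0.00051998
664,0.00021377
666,8.3648e-05
668,3.1155e-05
670,1.1044e-05
672,3.7267e-06
674,1.1969e-06
676,3.6587e-07
678,1.0645e-07
680,2.9481e-08
682,7.7712e-09
684,1.9498e-09
686,4.6562e-10
688,1.0584e-10
690,2.2897e-11
692,4.7151e-12
694,9.2417e-13
696,1.7241e-13
698,3.0615e-14
700,5.1744e-15
702,8.324e-16
704,1.2746e-16
706,1.8575e-17
708,2.5768e-18
710,3.4022e-19
712,4.2757e-20
714,5.1144e-21
716,5.823e-22
718,6.3102e-23
720,6.5088e-24
722,6.3901e-25
724,5.9713e-26
726,5.3111e-27
728,4.4963e-28
730,3.623e-29
732,2.7787e-30
734,2.0285e-31
736,1.4095e-32
738,9.3216e-34
740,5.8679e-35
742,3.5158e-36
744,2.005e-37
746,1.0883e-38
748,5.623e-40
750,2.7652e-41
752,1.2943e-42
754,5.7662e-44
756,2.4452e-45
758,9.869e-47
760,3.7914e-48
762,1.3863e-49
764,4.825e-51
766,1.5984e-52
768,5.0398e-54
770,1.5125e-55
772,4.3206e-57
774,1.1747e-58
776,3.0401e-60
778,7.4885e-62
780,1.7557e-63
782,3.9179e-65
784,8.3218e-67
786,1.6824e-68
788,3.2374e-70
790,5.9296e-72
792,1.0337e-73
794,1.7153e-75
796,2.709e-77
798,4.0724e-79
800,5.8269e-81
802,7.9356e-83
804,1.0287e-84
806,1.2692e-86
808,1.4905e-88
810,1.666e-90
812,1.7725e-92
814,1.7949e-94
816,1.7301e-96
818,1.5872e-98
820,1.386e-100
822,1.152e-102
824,9.113e-105
826,6.8619e-107
828,4.9179e-109
830,3.3548e-111
832,2.1783e-113
834,1.3462e-115
836,7.9188e-118
838,4.4337e-120
840,2.3627e-122
842,1.1985e-124
844,5.7862e-127
846,2.6589e-129
848,1.163e-131
850,4.8417e-134
852,1.9186e-136
854,7.2361e-139
856,2.5977e-141
858,8.8761e-144
860,2.8868e-146
862,8.9363e-149
864,2.633e-151
866,7.3842e-154
868,1.9711e-156
870,5.008e-159
872,1.2111e-161
874,2.7876e-164
876,6.1073e-167
878,1.2736e-169
880,2.5278e-172
882,4.7755e-175
884,8.5872e-178
886,1.4697e-180
888,2.3943e-183
890,3.7124e-186
892,5.479e-189
894,7.6966e-192
896,1.0291e-194
898,1.3096e-197
900,1.5864e-200
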