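wavelength_nm,value
340,6.8284e-28
342,1.8561e-27
344,5.0455e-27
346,1.3715e-26
348,3.7282e-26
350,1.0134e-25
352,2.7548e-25
354,7.4882e-25
356,2.0355e-24
358,5.5331e-24
360,1.5041e-23
362,4.0884e-23
364,1.1114e-22
366,3.021e-22
368,8.2119e-22
370,2.2322e-21
372,6.0678e-21
374,1.6494e-20
376,4.4835e-20
378,1.2187e-19
380,3.3129e-19
382,9.0054e-19
384,2.4479e-18
386,6.6541e-18
388,1.8088e-17
390,4.9168e-17
392,1.3365e-16
394,3.633e-16
396,9.8756e-16
398,2.6845e-15
400,7.2971e-15
402,1.9836e-14
404,5.3919e-14
406,1.4657e-13
408,3.9841e-13
410,1.083e-12
412,2.9439e-12
414,8.0023e-12
416,2.1752e-11
418,5.9129e-11
420,1.6073e-10
422,4.3691e-10
424,1.1876e-09
426,3.2284e-09
428,8.7756e-09
430,2.3854e-08
432,6.4843e-08
434,1.7626e-07
436,4.7913e-07
438,1.3024e-06
440,3.5403e-06
442,9.6235e-06
444,2.6159e-05
446,7.1104e-05
448,0.00019326
450,0.00052514
452,0.0014261
454,0.0038665
456,0.010437
458,0.027841
460,0.072025
462,0.17304
464,0.3572
466,0.58484
468,0.75393
470,0.81134
472,0.75393
474,0.58484
476,0.3572
478,0.17304
480,0.072025
482,0.027841
484,0.010437
486,0.0038665
488,0.0014261
490,0.00052514
492,0.00019326
494,7.1104e-05
496,2.6159e-05
498,9.6235e-06
500,3.5403e-06
502,1.3024e-06
504,4.7913e-07
506,1.7626e-07
508,6.4843e-08
510,2.3854e-08
512,8.7756e-09
514,3.2284e-09
516,1.1876e-09
518,4.3691e-10
520,1.6073e-10
522,5.9129e-11
524,2.1752e-11
526,8.0023e-12
528,2.9439e-12
530,1.083e-12
532,3.9841e-13
534,1.4657e-13
536,5.3919e-14
538,1.9836e-14
540,7.2971e-15
542,2.6845e-15
544,9.8756e-16
546,3.633e-16
548,1.3365e-16
550,4.9168e-17
552,1.8088e-17
554,6.6541e-18
556,2.4479e-18
558,9.0054e-19
560,3.3129e-19
562,1.2187e-19
564,4.4835e-20
566,1.6494e-20
568,6.0678e-21
570,2.2322e-21
572,8.2119e-22
574,3.021e-22
576,1.1114e-22
578,4.0884e-23
580,1.5041e-23
582,5.5331e-24
584,2.0355e-24
586,7.4882e-25
588,2.7548e-25
590,1.0134e-25
592,3.7282e-26
594,1.3715e-26
596,5.0455e-27
598,1.8561e-27
600,6.8284e-28
602,2.512e-28
604,9.2412e-29
606,3.3997e-29
608,1.2507e-29
610,4.6009e-30
612,1.6926e-30
614,6.2267e-31
616,2.2907e-31
618,8.4269e-32
620,3.1001e-32
622,1.1405e-32
624,4.1955e-33
626,1.5434e-33
628,5.678e-34
630,2.0888e-34
632,7.6843e-35
634,2.8269e-35
636,1.04e-35
638,3.8258e-36
640,1.4074e-36
642,5.1777e-37
644,1.9048e-37
646,7.0072e-38
648,2.5778e-38
650,9.4832e-39
652,3.4887e-39
654,1.2834e-39
656,4.7214e-40
658,1.7369e-40
660,6.3898e-41
662,2.3507e-41
664,8.6476e-42
666,3.1813e-42
668,1.1703e-42
670,4.3054e-43
672,1.5839e-43
674,5.8267e-44
676,2.1435e-44
678,7.8856e-45
680,2.9009e-45
682,1.0672e-45
684,3.926e-46
686,1.4443e-46
688,5.3133e-47
690,1.9546e-47
692,7.1907e-48
694,2.6453e-48
696,9.7316e-49
698,3.58e-49
700,1.317e-49
702,4.8451e-50
704,1.7824e-50
706,6.5571e-51
708,2.4122e-51
710,8.8741e-52
712,3.2646e-52
714,1.201e-52
716,4.4181e-53
718,1.6253e-53
720,5.9793e-54
722,2.1997e-54
724,8.0921e-55
726,2.9769e-55
728,1.0951e-55
730,4.0288e-56
732,1.4821e-56
734,5.4524e-57
736,2.0058e-57
738,7.379e-58
740,2.7146e-58
742,9.9864e-59
744,3.6738e-59
746,1.3515e-59
748,4.972e-60
750,1.8291e-60
752,6.7288e-61
754,2.4754e-61
756,9.1064e-62
758,3.3501e-62
760,1.2324e-62
762,4.5338e-63
764,1.6679e-63
766,6.1359e-64
768,2.2573e-64
770,8.304e-65
772,3.0549e-65
774,1.1238e-65
776,4.1343e-66
778,1.5209e-66
780,5.5952e-67
782,2.0584e-67
784,7.5723e-68
786,2.7857e-68
788,1.0248e-68
790,3.77e-69
792,1.3869e-69
794,5.1022e-70
796,1.877e-70
798,6.905e-71
800,2.5402e-71
802,9.3449e-72
804,3.4378e-72
806,1.2647e-72
808,4.6526e-73
810,1.7116e-73
812,6.2966e-74
814,2.3164e-74
816,8.5215e-75
818,3.1349e-75
820,1.1533e-75
822,4.2426e-76
824,1.5608e-76
826,5.7417e-77
828,2.1123e-77
830,7.7706e-78
832,2.8586e-78
834,1.0516e-78
836,3.8687e-79
838,1.4232e-79
840,5.2358e-80
842,1.9261e-80
844,7.0858e-81
846,2.6067e-81
848,9.5896e-82
850,3.5278e-82
852,1.2978e-82
854,4.7744e-83
856,1.7564e-83
858,6.4615e-84
860,2.377e-84
862,8.7446e-85
864,3.217e-85
866,1.1835e-85
868,4.3537e-86
870,1.6016e-86
872,5.8921e-87
874,2.1676e-87
876,7.9741e-88
878,2.9335e-88
880,1.0792e-88
882,3.9701e-89
884,1.4605e-89
886,5.3729e-90
888,1.9766e-90
890,7.2714e-91
892,2.675e-91
894,9.8408e-92
896,3.6202e-92
898,1.3318e-92
900,4.8994e-93
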