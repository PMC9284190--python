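wavelength_nm,value
340,8.304e-65
342,2.2573e-64
344,6.1359e-64
346,1.6679e-63
348,4.5338e-63
350,1.2324e-62
352,3.3501e-62
354,9.1064e-62
356,2.4754e-61
358,6.7288e-61
360,1.8291e-60
362,4.972e-60
364,1.3515e-59
366,3.6738e-59
368,9.9864e-59
370,2.7146e-58
372,7.379e-58
374,2.0058e-57
376,5.4524e-57
378,1.4821e-56
380,4.0288e-56
382,1.0951e-55
384,2.9769e-55
386,8.0921e-55
388,2.1997e-54
390,5.9793e-54
392,1.6253e-53
394,4.4181e-53
396,1.201e-52
398,3.2646e-52
400,8.8741e-52
402,2.4122e-51
404,6.5571e-51
406,1.7824e-50
408,4.8451e-50
410,1.317e-49
412,3.58e-49
414,9.7316e-49
416,2.6453e-48
418,7.1907e-48
420,1.9546e-47
422,5.3133e-47
424,1.4443e-46
426,3.926e-46
428,1.0672e-45
430,2.9009e-45
432,7.8856e-45
434,2.1435e-44
436,5.8267e-44
438,1.5839e-43
440,4.3054e-43
442,1.1703e-42
444,3.1813e-42
446,8.6476e-42
448,2.3507e-41
450,6.3898e-41
452,1.7369e-40
454,4.7214e-40
456,1.2834e-39
458,3.4887e-39
460,9.4832e-39
462,2.5778e-38
464,7.0072e-38
466,1.9048e-37
468,5.1777e-37
470,1.4074e-36
472,3.8258e-36
474,1.04e-35
476,2.8269e-35
478,7.6843e-35
480,2.0888e-34
482,5.678e-34
484,1.5434e-33
486,4.1955e-33
488,1.1405e-32
490,3.1001e-32
492,8.4269e-32
494,2.2907e-31
496,6.2267e-31
498,1.6926e-30
500,4.6009e-30
502,1.2507e-29
504,3.3997e-29
506,9.2412e-29
508,2.512e-28
510,6.8284e-28
512,1.8561e-27
514,5.0455e-27
516,1.3715e-26
518,3.7282e-26
520,1.0134e-25
522,2.7548e-25
524,7.4882e-25
526,2.0355e-24
528,5.5331e-24
530,1.5041e-23
532,4.0884e-23
534,1.1114e-22
536,3.021e-22
538,8.2119e-22
540,2.2322e-21
542,6.0678e-21
544,1.6494e-20
546,4.4835e-20
548,1.2187e-19
550,3.3129e-19
552,9.0054e-19
554,2.4479e-18
556,6.6541e-18
558,1.8088e-17
560,4.9168e-17
562,1.3365e-16
564,3.633e-16
566,9.8756e-16
568,2.6845e-15
570,7.2971e-15
572,1.9836e-14
574,5.3919e-14
576,1.4657e-13
578,3.9841e-13
580,1.083e-12
582,2.9439e-12
584,8.0023e-12
586,2.1752e-11
588,5.9129e-11
590,1.6073e-10
592,4.3691e-10
594,1.1876e-09
596,3.2284e-09
598,8.7756e-09
600,2.3854e-08
602,6.4843e-08
604,1.7626e-07
606,4.7913e-07
608,1.3024e-06
610,3.5403e-06
612,9.6235e-06
614,2.6159e-05
616,7.1104e-05
618,0.00019326
620,0.00052514
622,0.0014261
624,0.0038665
626,0.010437
628,0.027841
630,0.072025
632,0.17304
634,0.3572
636,0.58484
638,0.75393
640,0.81134
642,0.75393
644,0.58484
646,0.3572
648,0.17304
650,0.072025
652,0.027841
654,0.010437
656,0.0038665
658,0.0014261
660,0.00052514
662,0.00019326
664,7.1104e-05
666,2.6159e-05
668,9.6235e-06
670,3.5403e-06
672,1.3024e-06
674,4.7913e-07
676,1.7626e-07
678,6.4843e-08
680,2.3854e-08
682,8.7756e-09
684,3.2284e-09
686,1.1876e-09
688,4.3691e-10
690,1.6073e-10
692,5.9129e-11
694,2.1752e-11
696,8.0023e-12
698,2.9439e-12
700,1.083e-12
702,3.9841e-13
704,1.4657e-13
706,5.3919e-14
708,1.9836e-14
710,7.2971e-15
712,2.6845e-15
714,9.8756e-16
716,3.633e-16
718,1.3365e-16
720,4.9168e-17
722,1.8088e-17
724,6.6541e-18
726,2.4479e-18
728,9.0054e-19
730,3.3129e-19
732,1.2187e-19
734,4.4835e-20
736,1.6494e-20
738,6.0678e-21
740,2.2322e-21
742,8.2119e-22
744,3.021e-22
746,1.1114e-22
748,4.0884e-23
750,1.5041e-23
752,5.5331e-24
754,2.0355e-24
756,7.4882e-25
758,2.7548e-25
760,1.0134e-25
762,3.7282e-26
764,1.3715e-26
766,5.0455e-27
768,1.8561e-27
770,6.8284e-28
772,2.512e-28
774,9.2412e-29
776,3.3997e-29
778,1.2507e-29
780,4.6009e-30
782,1.6926e-30
784,6.2267e-31
786,2.2907e-31
788,8.4269e-32
790,3.1001e-32
792,1.1405e-32
794,4.1955e-33
796,1.5434e-33
798,5.678e-34
800,2.0888e-34
802,7.6843e-35
804,2.8269e-35
806,1.04e-35
808,3.8258e-36
810,1.4074e-36
812,5.1777e-37
814,1.9048e-37
816,7.0072e-38
818,2.5778e-38
820,9.4832e-39
822,3.4887e-39
824,1.2834e-39
826,4.7214e-40
828,1.7369e-40
830,6.3898e-41
832,2.3507e-41
834,8.6476e-42
836,3.1813e-42
838,1.1703e-42
840,4.3054e-43
842,1.5839e-43
844,5.8267e-44
846,2.1435e-44
848,7.8856e-45
850,2.9009e-45
852,1.0672e-45
854,3.926e-46
856,1.4443e-46
858,5.3133e-47
860,1.9546e-47
862,7.1907e-48
864,2.6453e-48
866,9.7316e-49
868,3.58e-49
870,1.317e-49
872,4.8451e-50
874,1.7824e-50
876,6.5571e-51
878,2.4122e-51
880,8.8741e-52
882,3.2646e-52
884,1.201e-52
886,4.4181e-53
888,1.6253e-53
890,5.9793e-54
892,2.1997e-54
894,8.0921e-55
896,2.9769e-55
898,1.0951e-55
900,4.0288e-56
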