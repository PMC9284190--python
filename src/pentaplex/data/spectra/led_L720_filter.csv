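wavelength_nm,value
340,4.5888e-87
342,1.2474e-86
344,3.3907e-86
346,9.2168e-86
348,2.5054e-85
350,6.8103e-85
352,1.8512e-84
354,5.0322e-84
356,1.3679e-83
358,3.7183e-83
360,1.0107e-82
362,2.7475e-82
364,7.4684e-82
366,2.0301e-81
368,5.5185e-81
370,1.5001e-80
372,4.0776e-80
374,1.1084e-79
376,3.013e-79
378,8.1901e-79
380,2.2263e-78
382,6.0517e-78
384,1.645e-77
386,4.4717e-77
388,1.2155e-76
390,3.3041e-76
392,8.9816e-76
394,2.4414e-75
396,6.6365e-75
398,1.804e-74
400,4.9038e-74
402,1.333e-73
404,3.6234e-73
406,9.8495e-73
408,2.6774e-72
410,7.2778e-72
412,1.9783e-71
414,5.3776e-71
416,1.4618e-70
418,3.9736e-70
420,1.0801e-69
422,2.9361e-69
424,7.9811e-69
426,2.1695e-68
428,5.8973e-68
430,1.603e-67
432,4.3575e-67
434,1.1845e-66
436,3.2198e-66
438,8.7524e-66
440,2.3791e-65
442,6.4672e-65
444,1.758e-64
446,4.7786e-64
448,1.299e-63
450,3.531e-63
452,9.5981e-63
454,2.609e-62
456,7.0921e-62
458,1.9278e-61
460,5.2404e-61
462,1.4245e-60
464,3.8722e-60
466,1.0526e-59
468,2.8612e-59
470,7.7774e-59
472,2.1141e-58
474,5.7468e-58
476,1.5621e-57
478,4.2463e-57
480,1.1543e-56
482,3.1376e-56
484,8.529e-56
486,2.3184e-55
488,6.3021e-55
490,1.7131e-54
492,4.6567e-54
494,1.2658e-53
496,3.4408e-53
498,9.3532e-53
500,2.5425e-52
502,6.9111e-52
504,1.8786e-51
506,5.1067e-51
508,1.3881e-50
510,3.7733e-50
512,1.0257e-49
514,2.7881e-49
516,7.579e-49
518,2.0602e-48
520,5.6001e-48
522,1.5223e-47
524,4.138e-47
526,1.1248e-46
528,3.0576e-46
530,8.3113e-46
532,2.2593e-45
534,6.1413e-45
536,1.6694e-44
538,4.5378e-44
540,1.2335e-43
542,3.353e-43
544,9.1145e-43
546,2.4776e-42
548,6.7347e-42
550,1.8307e-41
552,4.9763e-41
554,1.3527e-40
556,3.677e-40
558,9.9953e-40
560,2.717e-39
562,7.3855e-39
564,2.0076e-38
566,5.4572e-38
568,1.4834e-37
570,4.0324e-37
572,1.0961e-36
574,2.9795e-36
576,8.0992e-36
578,2.2016e-35
580,5.9846e-35
582,1.6268e-34
584,4.422e-34
586,1.202e-33
588,3.2675e-33
590,8.8819e-33
592,2.4143e-32
594,6.5629e-32
596,1.784e-31
598,4.8493e-31
600,1.3182e-30
602,3.5832e-30
604,9.7402e-30
606,2.6477e-29
608,7.1971e-29
610,1.9564e-28
612,5.318e-28
614,1.4456e-27
616,3.9295e-27
618,1.0681e-26
620,2.9035e-26
622,7.8925e-26
624,2.1454e-25
626,5.8318e-25
628,1.5853e-24
630,4.3092e-24
632,1.1714e-23
634,3.1841e-23
636,8.6552e-23
638,2.3527e-22
640,6.3954e-22
642,1.7384e-21
644,4.7256e-21
646,1.2846e-20
648,3.4918e-20
650,9.4916e-20
652,2.5801e-19
654,7.0134e-19
656,1.9064e-18
658,5.1822e-18
660,1.4087e-17
662,3.8292e-17
664,1.0409e-16
666,2.8294e-16
668,7.6911e-16
670,2.0907e-15
672,5.683e-15
674,1.5448e-14
676,4.1992e-14
678,1.1415e-13
680,3.1028e-13
682,8.4344e-13
684,2.2927e-12
686,6.2322e-12
688,1.6941e-11
690,4.605e-11
692,1.2518e-10
694,3.4027e-10
696,9.2494e-10
698,2.5142e-09
700,6.8344e-09
702,1.8578e-08
704,5.05e-08
706,1.3727e-07
708,3.7315e-07
710,1.0143e-06
712,2.7572e-06
714,7.4948e-06
716,2.0373e-05
718,5.5377e-05
720,0.00015051
722,0.00040903
724,0.001111
726,0.003014
728,0.0081486
730,0.021828
732,0.057082
734,0.14064
736,0.30478
738,0.53407
740,0.73843
742,0.85939
744,0.91445
746,0.93639
748,0.94437
750,0.94634
752,0.94437
754,0.93639
756,0.91445
758,0.85939
760,0.73843
762,0.53407
764,0.30478
766,0.14064
768,0.057082
770,0.021828
772,0.0081486
774,0.003014
776,0.001111
778,0.00040903
780,0.00015051
782,5.5377e-05
784,2.0373e-05
786,7.4948e-06
788,2.7572e-06
790,1.0143e-06
792,3.7315e-07
794,1.3727e-07
796,5.05e-08
798,1.8578e-08
800,6.8344e-09
802,2.5142e-09
804,9.2494e-10
806,3.4027e-10
808,1.2518e-10
810,4.605e-11
812,1.6941e-11
814,6.2322e-12
816,2.2927e-12
818,8.4344e-13
820,3.1028e-13
822,1.1415e-13
824,4.1992e-14
826,1.5448e-14
828,5.683e-15
830,2.0907e-15
832,7.6911e-16
834,2.8294e-16
836,1.0409e-16
838,3.8292e-17
840,1.4087e-17
842,5.1822e-18
844,1.9064e-18
846,7.0134e-19
848,2.5801e-19
850,9.4916e-20
852,3.4918e-20
854,1.2846e-20
856,4.7256e-21
858,1.7384e-21
860,6.3954e-22
862,2.3527e-22
864,8.6552e-23
866,3.1841e-23
868,1.1714e-23
870,4.3092e-24
872,1.5853e-24
874,5.8318e-25
876,2.1454e-25
878,7.8925e-26
880,2.9035e-26
882,1.0681e-26
884,3.9295e-27
886,1.4456e-27
888,5.318e-28
890,1.9564e-28
892,7.1971e-29
894,2.6477e-29
896,9.7402e-30
898,3.5832e-30
900,1.3182e-30
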