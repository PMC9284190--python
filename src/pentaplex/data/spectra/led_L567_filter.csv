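wavelength_nm,value
340,1.2335e-43
342,3.353e-43
344,9.1145e-43
346,2.4776e-42
348,6.7347e-42
350,1.8307e-41
352,4.9763e-41
354,1.3527e-40
356,3.677e-40
358,9.9953e-40
360,2.717e-39
362,7.3855e-39
364,2.0076e-38
366,5.4572e-38
368,1.4834e-37
370,4.0324e-37
372,1.0961e-36
374,2.9795e-36
376,8.0992e-36
378,2.2016e-35
380,5.9846e-35
382,1.6268e-34
384,4.422e-34
386,1.202e-33
388,3.2675e-33
390,8.8819e-33
392,2.4143e-32
394,6.5629e-32
396,1.784e-31
398,4.8493e-31
400,1.3182e-30
402,3.5832e-30
404,9.7402e-30
406,2.6477e-29
408,7.1971e-29
410,1.9564e-28
412,5.318e-28
414,1.4456e-27
416,3.9295e-27
418,1.0681e-26
420,2.9035e-26
422,7.8925e-26
424,2.1454e-25
426,5.8318e-25
428,1.5853e-24
430,4.3092e-24
432,1.1714e-23
434,3.1841e-23
436,8.6552e-23
438,2.3527e-22
440,6.3954e-22
442,1.7384e-21
444,4.7256e-21
446,1.2846e-20
448,3.4918e-20
450,9.4916e-20
452,2.5801e-19
454,7.0134e-19
456,1.9064e-18
458,5.1822e-18
460,1.4087e-17
462,3.8292e-17
464,1.0409e-16
466,2.8294e-16
468,7.6911e-16
470,2.0907e-15
472,5.683e-15
474,1.5448e-14
476,4.1992e-14
478,1.1415e-13
480,3.1028e-13
482,8.4344e-13
484,2.2927e-12
486,6.2322e-12
488,1.6941e-11
490,4.605e-11
492,1.2518e-10
494,3.4027e-10
496,9.2494e-10
498,2.5142e-09
500,6.8344e-09
502,1.8578e-08
504,5.05e-08
506,1.3727e-07
508,3.7315e-07
510,1.0143e-06
512,2.7572e-06
514,7.4948e-06
516,2.0373e-05
518,5.5377e-05
520,0.00015051
522,0.00040903
524,0.001111
526,0.003014
528,0.0081486
530,0.021828
532,0.057082
534,0.14064
536,0.30478
538,0.53407
540,0.73843
542,0.85939
544,0.91445
546,0.93639
548,0.94437
550,0.94634
552,0.94437
554,0.93639
556,0.91445
558,0.85939
560,0.73843
562,0.53407
564,0.30478
566,0.14064
568,0.057082
570,0.021828
572,0.0081486
574,0.003014
576,0.001111
578,0.00040903
580,0.00015051
582,5.5377e-05
584,2.0373e-05
586,7.4948e-06
588,2.7572e-06
590,1.0143e-06
592,3.7315e-07
594,1.3727e-07
596,5.05e-08
598,1.8578e-08
600,6.8344e-09
602,2.5142e-09
604,9.2494e-10
606,3.4027e-10
608,1.2518e-10
610,4.605e-11
612,1.6941e-11
614,6.2322e-12
616,2.2927e-12
618,8.4344e-13
620,3.1028e-13
622,1.1415e-13
624,4.1992e-14
626,1.5448e-14
628,5.683e-15
630,2.0907e-15
632,7.6911e-16
634,2.8294e-16
636,1.0409e-16
638,3.8292e-17
640,1.4087e-17
642,5.1822e-18
644,1.9064e-18
646,7.0134e-19
648,2.5801e-19
650,9.4916e-20
652,3.4918e-20
654,1.2846e-20
656,4.7256e-21
658,1.7384e-21
660,6.3954e-22
662,2.3527e-22
664,8.6552e-23
666,3.1841e-23
668,1.1714e-23
670,4.3092e-24
672,1.5853e-24
674,5.8318e-25
676,2.1454e-25
678,7.8925e-26
680,2.9035e-26
682,1.0681e-26
684,3.9295e-27
686,1.4456e-27
688,5.318e-28
690,1.9564e-28
692,7.1971e-29
694,2.6477e-29
696,9.7402e-30
698,3.5832e-30
700,1.3182e-30
702,4.8493e-31
704,1.784e-31
706,6.5629e-32
708,2.4143e-32
710,8.8819e-33
712,3.2675e-33
714,1.202e-33
716,4.422e-34
718,1.6268e-34
720,5.9846e-35
722,2.2016e-35
724,8.0992e-36
726,2.9795e-36
728,1.0961e-36
730,4.0324e-37
732,1.4834e-37
734,5.4572e-38
736,2.0076e-38
738,7.3855e-39
740,2.717e-39
742,9.9953e-40
744,3.677e-40
746,1.3527e-40
748,4.9763e-41
750,1.8307e-41
752,6.7347e-42
754,2.4776e-42
756,9.1145e-43
758,3.353e-43
760,1.2335e-43
762,4.5378e-44
764,1.6694e-44
766,6.1413e-45
768,2.2593e-45
770,8.3113e-46
772,3.0576e-46
774,1.1248e-46
776,4.138e-47
778,1.5223e-47
780,5.6001e-48
782,2.0602e-48
784,7.579e-49
786,2.7881e-49
788,1.0257e-49
790,3.7733e-50
792,1.3881e-50
794,5.1067e-51
796,1.8786e-51
798,6.9111e-52
800,2.5425e-52
802,9.3532e-53
804,3.4408e-53
806,1.2658e-53
808,4.6567e-54
810,1.7131e-54
812,6.3021e-55
814,2.3184e-55
816,8.529e-56
818,3.1376e-56
820,1.1543e-56
822,4.2463e-57
824,1.5621e-57
826,5.7468e-58
828,2.1141e-58
830,7.7774e-59
832,2.8612e-59
834,1.0526e-59
836,3.8722e-60
838,1.4245e-60
840,5.2404e-61
842,1.9278e-61
844,7.0921e-62
846,2.609e-62
848,9.5981e-63
850,3.531e-63
852,1.299e-63
854,4.7786e-64
856,1.758e-64
858,6.4672e-65
860,2.3791e-65
862,8.7524e-66
864,3.2198e-66
866,1.1845e-66
868,4.3575e-67
870,1.603e-67
872,5.8973e-68
874,2.1695e-68
876,7.9811e-69
878,2.9361e-69
880,1.0801e-69
882,3.9736e-70
884,1.4618e-70
886,5.3776e-71
888,1.9783e-71
890,7.2778e-72
892,2.6774e-72
894,9.8495e-73
896,3.6234e-73
898,1.333e-73
900,4.9038e-74
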