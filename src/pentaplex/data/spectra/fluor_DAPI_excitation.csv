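wavelength_nm,value
340,0.83527
342,0.86743
344,0.89683
346,0.92312
348,0.94596
350,0.96507
352,0.9802
354,0.99115
356,0.99778
358,1
360,0.99778
362,0.99115
364,0.9802
366,0.96507
368,0.94596
370,0.92312
372,0.89683
374,0.86743
376,0.83527
378,0.80074
380,0.76423
382,0.72615
384,0.68691
386,0.64691
388,0.60653
390,0.56615
392,0.52612
394,0.48675
396,0.44833
398,0.41111
400,0.37531
402,0.34111
404,0.30865
406,0.27804
408,0.24935
410,0.22263
412,0.1979
414,0.17513
416,0.1543
418,0.13534
420,0.11818
422,0.10274
424,0.088922
426,0.076621
428,0.065729
430,0.056135
432,0.047729
434,0.040401
436,0.034047
438,0.028566
440,0.02386
442,0.019841
444,0.016426
446,0.013538
448,0.011109
450,0.0090751
452,0.0073807
454,0.005976
456,0.0048172
458,0.0038659
460,0.0030887
462,0.0024568
464,0.0019455
466,0.0015338
468,0.0012039
470,0.0009407
472,0.0007318
474,0.00056677
476,0.00043701
478,0.00033546
480,0.00025637
482,0.00019506
484,0.00014775
486,0.00011142
488,8.3648e-05
490,6.2522e-05
492,4.6523e-05
494,3.4465e-05
496,2.5419e-05
498,1.8664e-05
500,1.3644e-05
502,9.9295e-06
504,7.1943e-06
506,5.1894e-06
508,3.7267e-06
510,2.6643e-06
512,1.8964e-06
514,1.3438e-06
516,9.4802e-07
518,6.6584e-07
520,4.6557e-07
522,3.241e-07
524,2.2461e-07
526,1.5498e-07
528,1.0645e-07
530,7.28e-08
532,4.9564e-08
534,3.3595e-08
536,2.267e-08
538,1.523e-08
540,1.0186e-08
542,6.7827e-09
544,4.4963e-09
546,2.9675e-09
548,1.9498e-09
550,1.2754e-09
552,8.3059e-10
554,5.3851e-10
556,3.4759e-10
558,2.2336e-10
560,1.429e-10
562,9.1015e-11
564,5.7712e-11
566,3.6433e-11
568,2.2897e-11
570,1.4327e-11
572,8.9245e-12
574,5.5346e-12
576,3.4171e-12
578,2.1004e-12
580,1.2853e-12
582,7.8307e-13
584,4.7496e-13
586,2.868e-13
588,1.7241e-13
590,1.0319e-13
592,6.1484e-14
594,3.6472e-14
596,2.1539e-14
598,1.2664e-14
600,7.4129e-15
602,4.3199e-15
604,2.5062e-15
606,1.4476e-15
608,8.324e-16
610,4.7653e-16
612,2.7159e-16
614,1.5411e-16
616,8.7054e-17
618,4.8959e-17
620,2.7412e-17
622,1.528e-17
624,8.4794e-18
626,4.6847e-18
628,2.5768e-18
630,1.411e-18
632,7.6924e-19
634,4.175e-19
636,2.2559e-19
638,1.2136e-19
640,6.4993e-20
642,3.4653e-20
644,1.8395e-20
646,9.721e-21
648,5.1144e-21
650,2.6789e-21
652,1.3969e-21
654,7.2523e-22
656,3.7484e-22
658,1.9287e-22
660,9.8806e-23
662,5.0391e-23
664,2.5586e-23
666,1.2933e-23
668,6.5088e-24
670,3.261e-24
672,1.6266e-24
674,8.0774e-25
676,3.9933e-25
678,1.9655e-25
680,9.631e-26
682,4.6984e-26
684,2.2819e-26
686,1.1033e-26
688,5.3111e-27
690,2.5453e-27
692,1.2144e-27
694,5.7683e-28
696,2.7278e-28
698,1.2842e-28
700,6.0193e-29
702,2.8088e-29
704,1.3048e-29
706,6.0349e-30
708,2.7787e-30
710,1.2738e-30
712,5.8132e-31
714,2.6412e-31
716,1.1947e-31
718,5.3802e-32
720,2.4121e-32
722,1.0766e-32
724,4.7841e-33
726,2.1165e-33
728,9.3216e-34
730,4.0873e-34
732,1.7843e-34
734,7.7544e-35
736,3.3551e-35
738,1.4452e-35
740,6.1977e-36
742,2.646e-36
744,1.1247e-36
746,4.7593e-37
748,2.005e-37
750,8.4094e-38
752,3.5114e-38
754,1.4597e-38
756,6.0412e-39
758,2.4891e-39
760,1.021e-39
762,4.1697e-40
764,1.6953e-40
766,6.8619e-41
768,2.7652e-41
770,1.1093e-41
772,4.4308e-42
774,1.7618e-42
776,6.9746e-43
778,2.7488e-43
780,1.0785e-43
782,4.2131e-44
784,1.6384e-44
786,6.3436e-45
788,2.4452e-45
790,9.3831e-46
792,3.5848e-46
794,1.3635e-46
796,5.1629e-47
798,1.9463e-47
800,7.3048e-48
802,2.7294e-48
804,1.0153e-48
806,3.7601e-49
808,1.3863e-49
810,5.0888e-50
812,1.8596e-50
814,6.7655e-51
816,2.4505e-51
818,8.8363e-52
820,3.1722e-52
822,1.1338e-52
824,4.0341e-53
826,1.4291e-53
828,5.0398e-54
830,1.7695e-54
832,6.1853e-55
834,2.1525e-55
836,7.4574e-56
838,2.5722e-56
840,8.8327e-57
842,3.0196e-57
844,1.0277e-57
846,3.4824e-58
848,1.1747e-58
850,3.9453e-59
852,1.3191e-59
854,4.391e-60
856,1.4551e-60
858,4.8009e-61
860,1.5769e-61
862,5.1566e-62
864,1.6788e-62
866,5.441e-63
868,1.7557e-63
870,5.64e-64
872,1.8038e-64
874,5.7433e-65
876,1.8206e-65
878,5.7454e-66
880,1.8051e-66
882,5.6462e-67
884,1.7582e-67
886,5.4509e-68
888,1.6824e-68
890,5.1697e-69
892,1.5815e-69
894,4.8166e-70
896,1.4604e-70
898,4.4085e-71
900,1.3249e-71
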