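wavelength_nm,value
340,1.3061e-07
342,2.1356e-07
344,3.4633e-07
346,5.5703e-07
348,8.8852e-07
350,1.4056e-06
352,2.2054e-06
354,3.4316e-06
356,5.2958e-06
358,8.1055e-06
360,1.2304e-05
362,1.8523e-05
364,2.7655e-05
366,4.0951e-05
368,6.014e-05
370,8.7594e-05
372,0.00012653
374,0.00018127
376,0.00025755
378,0.00036292
380,0.0005072
382,0.000703
384,0.00096636
386,0.0013174
388,0.0017813
390,0.0023887
392,0.0031768
394,0.0041901
396,0.0054812
398,0.0071111
400,0.0091497
402,0.011676
404,0.014777
406,0.018548
408,0.02309
410,0.028508
412,0.034908
414,0.042395
416,0.051065
418,0.061005
420,0.072287
422,0.084959
424,0.099046
426,0.11454
428,0.13142
430,0.1496
432,0.16898
434,0.18945
436,0.21085
438,0.23303
440,0.25586
442,0.2792
444,0.30297
446,0.32715
448,0.35178
450,0.37699
452,0.40299
454,0.43009
456,0.45865
458,0.48906
460,0.5217
462,0.55689
464,0.59483
466,0.63553
468,0.67873
470,0.7239
472,0.7702
474,0.81642
476,0.86112
478,0.90258
480,0.93897
482,0.96846
484,0.9893
486,1
488,0.99946
490,0.98703
492,0.96261
494,0.92665
496,0.88014
498,0.82455
500,0.76169
502,0.69366
504,0.62263
506,0.55076
508,0.48005
510,0.41225
512,0.34877
514,0.29066
516,0.23861
518,0.19294
520,0.15367
522,0.12055
524,0.093137
526,0.070875
528,0.053121
530,0.039216
532,0.028515
534,0.020423
536,0.014409
538,0.010014
540,0.006857
542,0.0046259
544,0.0030752
546,0.0020148
548,0.0013011
550,0.0008284
552,0.00052011
554,0.00032213
556,0.00019687
558,0.00011878
560,7.0783e-05
562,4.1687e-05
564,2.4281e-05
566,1.3999e-05
568,7.9956e-06
570,4.5292e-06
572,2.5474e-06
574,1.4244e-06
576,7.9283e-07
578,4.3984e-07
580,2.435e-07
582,1.3467e-07
584,7.4467e-08
586,4.1194e-08
588,2.2804e-08
590,1.2631e-08
592,6.9985e-09
594,3.8765e-09
596,2.1449e-09
598,1.1846e-09
600,6.5239e-10
602,3.5799e-10
604,1.9557e-10
606,1.0629e-10
608,5.7438e-11
610,3.0843e-11
612,1.6451e-11
614,8.7124e-12
616,4.5803e-12
618,2.3897e-12
620,1.2372e-12
622,6.3547e-13
624,3.238e-13
626,1.6367e-13
628,8.2059e-14
630,4.0807e-14
632,2.0127e-14
634,9.8464e-15
636,4.7774e-15
638,2.2989e-15
640,1.0972e-15
642,5.1932e-16
644,2.4379e-16
646,1.135e-16
648,5.2411e-17
650,2.4001e-17
652,1.0901e-17
654,4.9103e-18
656,2.1936e-18
658,9.719e-19
660,4.2707e-19
662,1.8611e-19
664,8.044e-20
666,3.4481e-20
668,1.4659e-20
670,6.1805e-21
672,2.5844e-21
674,1.0718e-21
676,4.4083e-22
678,1.7982e-22
680,7.2748e-23
682,2.9189e-23
684,1.1615e-23
686,4.5839e-24
688,1.7941e-24
690,6.9645e-25
692,2.6813e-25
694,1.0238e-25
696,3.8767e-26
698,1.4559e-26
700,5.4229e-27
702,2.0032e-27
704,7.3391e-28
706,2.6666e-28
708,9.6094e-29
710,3.4343e-29
712,1.2173e-29
714,4.2792e-30
716,1.4919e-30
718,5.1585e-31
720,1.769e-31
722,6.0163e-32
724,2.0293e-32
726,6.7885e-33
728,2.2522e-33
730,7.4108e-34
732,2.4184e-34
734,7.8271e-35
736,2.5124e-35
738,7.998e-36
740,2.5251e-36
742,7.9068e-37
744,2.4554e-37
746,7.5625e-38
748,2.31e-38
750,6.998e-39
752,2.1025e-39
754,6.265e-40
756,1.8515e-40
758,5.4264e-41
760,1.5774e-41
762,4.5473e-42
764,1.3001e-42
766,3.6867e-43
768,1.0368e-43
770,2.8917e-44
772,7.999e-45
774,2.1944e-45
776,5.9706e-46
778,1.6111e-46
780,4.3117e-47
782,1.1444e-47
784,3.0125e-48
786,7.8647e-49
788,2.0363e-49
790,5.229e-50
792,1.3317e-50
794,3.3636e-51
796,8.4257e-52
798,2.0933e-52
800,5.1577e-53
802,1.2604e-53
804,3.0545e-54
806,7.3419e-55
808,1.7502e-55
810,4.1377e-56
812,9.7018e-57
814,2.2561e-57
816,5.2032e-58
818,1.1901e-58
820,2.6998e-59
822,6.0741e-60
824,1.3553e-60
826,2.9992e-61
828,6.5825e-62
830,1.4328e-62
832,3.093e-63
834,6.6221e-64
836,1.4061e-64
838,2.9611e-65
840,6.1844e-66
842,1.281e-66
844,2.6316e-67
846,5.3616e-68
848,1.0834e-68
850,2.1711e-69
852,4.3151e-70
854,8.5057e-71
856,1.6628e-71
858,3.2239e-72
860,6.1992e-73
862,1.1822e-73
864,2.236e-74
866,4.1943e-75
868,7.8029e-76
870,1.4397e-76
872,2.6344e-77
874,4.7809e-78
876,8.6049e-79
878,1.536e-79
880,2.7193e-80
882,4.7745e-81
884,8.314e-82
886,1.4358e-82
888,2.4593e-83
890,4.1775e-84
892,7.0379e-85
894,1.1759e-85
896,1.9486e-86
898,3.2025e-87
900,5.2198e-88
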