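wavelength_nm,value
340,0.0025775
342,0.0031302
344,0.0037891
346,0.0045717
348,0.0054979
350,0.0065903
352,0.0078739
354,0.0093769
356,0.01113
358,0.013169
360,0.015529
362,0.018254
364,0.021386
366,0.024974
368,0.029069
370,0.033725
372,0.039
374,0.044952
376,0.051644
378,0.059139
380,0.0675
382,0.076793
384,0.08708
386,0.098423
388,0.11088
390,0.12451
392,0.13936
394,0.15546
396,0.17287
398,0.1916
400,0.21166
402,0.23306
404,0.25579
406,0.27983
408,0.30512
410,0.33161
412,0.35923
414,0.38788
416,0.41745
418,0.44781
420,0.47881
422,0.51029
424,0.54207
426,0.57395
428,0.60572
430,0.63716
432,0.66806
434,0.69816
436,0.72725
438,0.75508
440,0.78142
442,0.80604
444,0.82872
446,0.84927
448,0.86748
450,0.88321
452,0.89628
454,0.90658
456,0.91401
458,0.9185
460,0.92
462,0.9185
464,0.91401
466,0.90658
468,0.89628
470,0.88321
472,0.86748
474,0.84927
476,0.82872
478,0.80604
480,0.78142
482,0.75508
484,0.72725
486,0.69816
488,0.66806
490,0.63716
492,0.60572
494,0.57395
496,0.54207
498,0.51029
500,0.47881
502,0.44781
504,0.41745
506,0.38788
508,0.35923
510,0.33161
512,0.30512
514,0.27983
516,0.25579
518,0.23306
520,0.21166
522,0.1916
524,0.17287
526,0.15547
528,0.13936
530,0.12451
532,0.11088
534,0.098426
536,0.087083
538,0.076796
540,0.067504
542,0.059144
544,0.05165
546,0.044959
548,0.039008
550,0.033735
552,0.02908
554,0.024986
556,0.0214
558,0.01827
560,0.015548
562,0.01319
564,0.011155
566,0.0094051
568,0.0079062
570,0.0066272
572,0.0055401
574,0.0046198
576,0.0038439
578,0.0031926
580,0.0026484
582,0.002196
584,0.0018219
586,0.0015146
588,0.001264
590,0.0010615
592,0.00089972
594,0.00077246
596,0.00067444
598,0.00060126
600,0.00054925
602,0.00051541
604,0.0004973
606,0.00049296
608,0.00050083
610,0.00051974
612,0.0005488
614,0.00058742
616,0.00063519
618,0.00069192
620,0.00075761
622,0.00083237
624,0.00091647
626,0.0010103
628,0.0011142
630,0.0012289
632,0.001355
634,0.0014932
636,0.0016443
638,0.0018091
640,0.0019886
642,0.0021838
644,0.0023956
646,0.0026253
648,0.0028739
650,0.0031426
652,0.0034327
654,0.0037454
656,0.0040822
658,0.0044443
660,0.0048331
662,0.0052502
664,0.005697
666,0.0061749
668,0.0066854
670,0.0072302
672,0.0078106
674,0.0084283
676,0.0090847
678,0.0097814
680,0.01052
682,0.011301
684,0.012128
686,0.013
688,0.013919
690,0.014887
692,0.015904
694,0.016972
696,0.018092
698,0.019264
700,0.02049
702,0.021769
704,0.023102
706,0.02449
708,0.025932
710,0.027429
712,0.02898
714,0.030584
716,0.032242
718,0.033951
720,0.035712
722,0.037522
724,0.03938
726,0.041284
728,0.043232
730,0.045222
732,0.047251
734,0.049316
736,0.051415
738,0.053543
740,0.055697
742,0.057873
744,0.060068
746,0.062277
748,0.064495
750,0.066718
752,0.068941
754,0.07116
756,0.073367
758,0.07556
760,0.077731
762,0.079876
764,0.08199
766,0.084065
768,0.086097
770,0.088081
772,0.09001
774,0.09188
776,0.093684
778,0.095417
780,0.097075
782,0.098651
784,0.10014
786,0.10154
788,0.10285
790,0.10406
792,0.10516
794,0.10616
796,0.10705
798,0.10782
800,0.10848
802,0.10903
804,0.10945
806,0.10976
808,0.10994
810,0.11
812,0.10994
814,0.10976
816,0.10945
818,0.10903
820,0.10848
822,0.10782
824,0.10705
826,0.10616
828,0.10516
830,0.10406
832,0.10285
834,0.10154
836,0.10014
838,0.098651
840,0.097075
842,0.095417
844,0.093684
846,0.09188
848,0.09001
850,0.088081
852,0.086097
854,0.084065
856,0.08199
858,0.079876
860,0.077731
862,0.07556
864,0.073367
866,0.07116
868,0.068941
870,0.066718
872,0.064495
874,0.062277
876,0.060068
878,0.057873
880,0.055697
882,0.053543
884,0.051415
886,0.049316
888,0.047251
890,0.045222
892,0.043232
894,0.041284
896,0.03938
898,0.037522
900,0.035712
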