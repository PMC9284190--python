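wavelength_nm,value
340,6.2173e-06
342,7.9235e-06
344,1.0073e-05
346,1.2773e-05
348,1.6157e-05
350,2.0386e-05
352,2.5658e-05
354,3.2212e-05
356,4.034e-05
358,5.0392e-05
360,6.2793e-05
362,7.8049e-05
364,9.677e-05
366,0.00011968
368,0.00014765
370,0.0001817
372,0.00022304
374,0.0002731
376,0.00033356
378,0.0004064
380,0.0004939
382,0.00059875
384,0.00072403
386,0.00087335
388,0.0010508
390,0.0012612
392,0.00151
394,0.0018032
396,0.0021481
398,0.0025525
400,0.0030255
402,0.0035772
404,0.0042189
406,0.0049634
408,0.0058246
410,0.0068181
412,0.0079612
414,0.0092728
416,0.010773
418,0.012486
420,0.014434
422,0.016645
424,0.019146
426,0.021968
428,0.025143
430,0.028705
432,0.03269
434,0.037136
436,0.04208
438,0.047564
440,0.053629
442,0.060315
444,0.067666
446,0.075723
448,0.084528
450,0.094121
452,0.10454
454,0.11583
456,0.12801
458,0.14112
460,0.15518
462,0.17022
464,0.18625
466,0.20328
468,0.22131
470,0.24035
472,0.26036
474,0.28135
476,0.30326
478,0.32606
480,0.3497
482,0.37412
484,0.39925
486,0.425
488,0.45128
490,0.47799
492,0.50501
494,0.53223
496,0.55952
498,0.58674
500,0.61375
502,0.64039
504,0.66653
506,0.692
508,0.71665
510,0.74032
512,0.76287
514,0.78414
516,0.80399
518,0.82228
520,0.83889
522,0.8537
524,0.86661
526,0.87751
528,0.88633
530,0.893
532,0.89748
534,0.89972
536,0.89972
538,0.89748
540,0.893
542,0.88633
544,0.87751
546,0.86661
548,0.85371
550,0.8389
552,0.82229
554,0.804
556,0.78415
558,0.76289
560,0.74034
562,0.71667
564,0.69203
566,0.66656
568,0.64043
570,0.61379
572,0.58679
574,0.55958
576,0.5323
578,0.50509
580,0.47808
582,0.45138
584,0.42511
586,0.39938
588,0.37427
590,0.34987
592,0.32625
594,0.30347
596,0.28159
598,0.26064
600,0.24065
602,0.22166
604,0.20367
606,0.18668
608,0.1707
610,0.15572
612,0.14172
614,0.12868
616,0.11658
618,0.10538
620,0.095051
622,0.085561
624,0.076869
626,0.068936
628,0.061722
630,0.055184
632,0.049282
634,0.043976
636,0.039225
638,0.03499
640,0.031234
642,0.027921
644,0.025016
646,0.022486
648,0.020302
650,0.018433
652,0.016854
654,0.01554
656,0.014468
658,0.013617
660,0.012969
662,0.012507
664,0.012214
666,0.012078
668,0.012086
670,0.012228
672,0.012493
674,0.012875
676,0.013366
678,0.013959
680,0.01465
682,0.015434
684,0.016308
686,0.017269
688,0.018314
690,0.019441
692,0.020648
694,0.021935
696,0.0233
698,0.024741
700,0.02626
702,0.027853
704,0.029522
706,0.031266
708,0.033082
710,0.034972
712,0.036933
714,0.038966
716,0.041067
718,0.043236
720,0.045472
722,0.047771
724,0.050133
726,0.052554
728,0.055031
730,0.057562
732,0.060143
734,0.06277
736,0.06544
738,0.068148
740,0.070889
742,0.073658
744,0.076451
746,0.079262
748,0.082085
750,0.084915
752,0.087744
754,0.090567
756,0.093377
758,0.096167
760,0.098931
762,0.10166
764,0.10435
766,0.10699
768,0.10958
770,0.1121
772,0.11456
774,0.11694
776,0.11923
778,0.12144
780,0.12355
782,0.12556
784,0.12745
786,0.12924
788,0.1309
790,0.13243
792,0.13384
794,0.13511
796,0.13624
798,0.13723
800,0.13807
802,0.13876
804,0.1393
806,0.13969
808,0.13992
810,0.14
812,0.13992
814,0.13969
816,0.1393
818,0.13876
820,0.13807
822,0.13723
824,0.13624
826,0.13511
828,0.13384
830,0.13243
832,0.1309
834,0.12924
836,0.12745
838,0.12556
840,0.12355
842,0.12144
844,0.11923
846,0.11694
848,0.11456
850,0.1121
852,0.10958
854,0.10699
856,0.10435
858,0.10166
860,0.098931
862,0.096167
864,0.093377
866,0.090567
868,0.087744
870,0.084914
872,0.082085
874,0.079262
876,0.07645
878,0.073657
880,0.070887
882,0.068145
884,0.065437
886,0.062766
888,0.060138
890,0.057556
892,0.055023
894,0.052544
896,0.05012
898,0.047755
900,0.045451
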