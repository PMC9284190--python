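wavelength_nm,value
340,1.6391e-14
342,2.4119e-14
344,3.5401e-14
346,5.1831e-14
348,7.5697e-14
350,1.1028e-13
352,1.6025e-13
354,2.3229e-13
356,3.3587e-13
358,4.8444e-13
360,6.9697e-13
362,1.0002e-12
364,1.4319e-12
366,2.0447e-12
368,2.9124e-12
370,4.1381e-12
372,5.8649e-12
374,8.2915e-12
376,1.1693e-11
378,1.6448e-11
380,2.308e-11
382,3.2305e-11
384,4.5104e-11
386,6.2817e-11
388,8.7268e-11
390,1.2093e-10
392,1.6716e-10
394,2.305e-10
396,3.1702e-10
398,4.3495e-10
400,5.9525e-10
402,8.1259e-10
404,1.1065e-09
406,1.503e-09
408,2.0365e-09
410,2.7524e-09
412,3.7107e-09
414,4.9902e-09
416,6.6941e-09
418,8.9574e-09
420,1.1956e-08
422,1.5918e-08
424,2.1141e-08
426,2.8008e-08
428,3.7011e-08
430,4.8788e-08
432,6.415e-08
434,8.4139e-08
436,1.1008e-07
438,1.4366e-07
440,1.8702e-07
442,2.4286e-07
444,3.1458e-07
446,4.0646e-07
448,5.2386e-07
450,6.7349e-07
452,8.637e-07
454,1.1049e-06
456,1.4098e-06
458,1.7945e-06
460,2.2784e-06
462,2.8856e-06
464,3.6454e-06
466,4.5939e-06
468,5.7746e-06
470,7.2407e-06
472,9.0564e-06
474,1.1299e-05
476,1.4062e-05
478,1.7457e-05
480,2.1617e-05
482,2.6702e-05
484,3.29e-05
486,4.0436e-05
488,4.9574e-05
490,6.0626e-05
492,7.3956e-05
494,8.9992e-05
496,0.00010923
498,0.00013225
500,0.00015973
502,0.00019243
504,0.00023124
506,0.00027719
508,0.00033145
510,0.00039533
512,0.00047035
514,0.0005582
516,0.00066081
518,0.00078034
520,0.00091918
522,0.00108
524,0.0012659
526,0.00148
528,0.0017261
530,0.0020082
532,0.0023308
534,0.0026989
536,0.0031182
538,0.0035953
540,0.0041383
542,0.0047569
544,0.0054645
546,0.0062789
548,0.0072258
550,0.0083428
552,0.0096845
554,0.011332
556,0.013401
558,0.016058
560,0.019536
562,0.024152
564,0.030322
566,0.038583
568,0.049599
570,0.06416
572,0.083164
574,0.10758
576,0.13839
578,0.17648
580,0.22255
582,0.27698
584,0.33969
586,0.41002
588,0.48668
590,0.56766
592,0.65031
594,0.73146
596,0.80758
598,0.87507
600,0.93053
602,0.97107
604,0.9946
606,1
608,0.98724
610,0.9574
612,0.91253
614,0.85546
616,0.78956
618,0.71838
620,0.6454
622,0.57377
624,0.50608
626,0.44431
628,0.38973
630,0.34295
632,0.30403
634,0.27257
636,0.24784
638,0.22894
640,0.21486
642,0.20464
644,0.19736
646,0.19223
648,0.18858
650,0.18588
652,0.18372
654,0.1818
656,0.17989
658,0.17784
660,0.17556
662,0.173
664,0.17011
666,0.1669
668,0.16336
670,0.15951
672,0.15536
674,0.15096
676,0.14631
678,0.14145
680,0.13642
682,0.13123
684,0.12593
686,0.12054
688,0.11509
690,0.10961
692,0.10414
694,0.098688
696,0.09329
698,0.087967
700,0.082741
702,0.077631
704,0.072654
706,0.067827
708,0.063163
710,0.058672
712,0.054365
714,0.050248
716,0.046327
718,0.042605
720,0.039084
722,0.035765
724,0.032646
726,0.029724
728,0.026997
730,0.024458
732,0.022103
734,0.019925
736,0.017916
738,0.01607
740,0.014378
742,0.012832
744,0.011424
746,0.010145
748,0.0089864
750,0.0079404
752,0.0069986
754,0.0061532
756,0.0053963
758,0.0047207
760,0.0041194
762,0.0035857
764,0.0031134
766,0.0026965
768,0.0023296
770,0.0020076
772,0.0017258
774,0.0014799
776,0.0012658
778,0.00108
780,0.00091917
782,0.00078033
784,0.00066081
786,0.0005582
788,0.00047035
790,0.00039533
792,0.00033145
794,0.00027719
796,0.00023124
798,0.00019243
800,0.00015973
802,0.00013225
804,0.00010923
806,8.9992e-05
808,7.3956e-05
810,6.0626e-05
812,4.9574e-05
814,4.0436e-05
816,3.29e-05
818,2.6702e-05
820,2.1617e-05
822,1.7457e-05
824,1.4062e-05
826,1.1299e-05
828,9.0564e-06
830,7.2407e-06
832,5.7746e-06
834,4.5939e-06
836,3.6454e-06
838,2.8856e-06
840,2.2784e-06
842,1.7945e-06
844,1.4098e-06
846,1.1049e-06
848,8.637e-07
850,6.7349e-07
852,5.2386e-07
854,4.0646e-07
856,3.1458e-07
858,2.4286e-07
860,1.8702e-07
862,1.4366e-07
864,1.1008e-07
866,8.4139e-08
868,6.415e-08
870,4.8788e-08
872,3.7011e-08
874,2.8008e-08
876,2.1141e-08
878,1.5918e-08
880,1.1956e-08
882,8.9574e-09
884,6.6941e-09
886,4.9902e-09
888,3.7107e-09
890,2.7524e-09
892,2.0365e-09
894,1.503e-09
896,1.1065e-09
898,8.1259e-10
900,5.9525e-10
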