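wavelength_nm,value
340,2.5738e-11
342,3.5515e-11
344,4.8895e-11
346,6.7164e-11
348,9.205e-11
350,1.2587e-10
352,1.7173e-10
354,2.3376e-10
356,3.1748e-10
358,4.3021e-10
360,5.8165e-10
362,7.8461e-10
364,1.056e-09
366,1.418e-09
368,1.8999e-09
370,2.5397e-09
372,3.3872e-09
374,4.5075e-09
376,5.9845e-09
378,7.9277e-09
380,1.0478e-08
382,1.3817e-08
384,1.8179e-08
386,2.3865e-08
388,3.1257e-08
390,4.0846e-08
392,5.3256e-08
394,6.928e-08
396,8.9921e-08
398,1.1645e-07
400,1.5046e-07
402,1.9396e-07
404,2.4947e-07
406,3.2014e-07
408,4.0991e-07
410,5.2366e-07
412,6.6745e-07
414,8.488e-07
416,1.077e-06
418,1.3634e-06
420,1.7221e-06
422,2.1703e-06
424,2.7288e-06
426,3.4234e-06
428,4.285e-06
430,5.3513e-06
432,6.6678e-06
434,8.2894e-06
436,1.0282e-05
438,1.2725e-05
440,1.5712e-05
442,1.9357e-05
444,2.3793e-05
446,2.918e-05
448,3.5705e-05
450,4.3591e-05
452,5.3097e-05
454,6.453e-05
456,7.8248e-05
458,9.4666e-05
460,0.00011427
462,0.00013762
464,0.00016537
466,0.00019826
468,0.00023716
470,0.00028304
472,0.00033704
474,0.00040043
476,0.00047466
478,0.00056138
480,0.00066244
482,0.00077993
484,0.00091617
486,0.0010738
488,0.0012556
490,0.001465
492,0.0017053
494,0.0019806
496,0.0022952
498,0.0026537
500,0.0030612
502,0.0035233
504,0.0040459
506,0.0046356
508,0.0052993
510,0.0060444
512,0.0068789
514,0.0078113
516,0.0088511
518,0.010009
520,0.011296
522,0.012728
524,0.014322
526,0.016105
528,0.018114
530,0.020401
532,0.023049
534,0.026177
536,0.029963
538,0.034662
540,0.040629
542,0.04835
544,0.058454
546,0.071738
548,0.089152
550,0.11178
552,0.14077
554,0.17726
556,0.22219
558,0.27621
560,0.33944
562,0.41133
564,0.49049
566,0.57469
568,0.66086
570,0.74524
572,0.82363
574,0.8918
576,0.94584
578,0.98259
580,1
582,0.99733
584,0.97525
586,0.93577
588,0.88197
590,0.81771
592,0.74716
594,0.67446
596,0.60331
598,0.53673
600,0.47693
602,0.42521
604,0.38211
606,0.34744
608,0.32056
610,0.30045
612,0.28598
614,0.27596
616,0.2693
618,0.26503
620,0.26234
622,0.26061
624,0.25934
626,0.25819
628,0.25692
630,0.25535
632,0.25338
634,0.25096
636,0.24806
638,0.24467
640,0.2408
642,0.23646
644,0.23168
646,0.22648
648,0.2209
650,0.21497
652,0.20872
654,0.2022
656,0.19544
658,0.18848
660,0.18135
662,0.1741
664,0.16675
666,0.15936
668,0.15195
670,0.14456
672,0.13721
674,0.12994
676,0.12278
678,0.11575
680,0.10888
682,0.10218
684,0.095676
686,0.089384
688,0.083317
690,0.077485
692,0.071898
694,0.066564
696,0.061485
698,0.056665
700,0.052105
702,0.047803
704,0.043757
706,0.039963
708,0.036415
710,0.033107
712,0.030031
714,0.02718
716,0.024543
718,0.022112
720,0.019877
722,0.017827
724,0.015952
726,0.014242
728,0.012687
730,0.011276
732,0.0099988
734,0.0088465
736,0.0078092
738,0.0068779
740,0.006044
742,0.0052991
744,0.0046356
746,0.0040459
748,0.0035232
750,0.0030612
752,0.0026536
754,0.0022952
756,0.0019806
758,0.0017053
760,0.001465
762,0.0012556
764,0.0010738
766,0.00091617
768,0.00077993
770,0.00066244
772,0.00056138
774,0.00047466
776,0.00040043
778,0.00033704
780,0.00028304
782,0.00023716
784,0.00019826
786,0.00016537
788,0.00013762
790,0.00011427
792,9.4666e-05
794,7.8248e-05
796,6.453e-05
798,5.3097e-05
800,4.3591e-05
802,3.5705e-05
804,2.918e-05
806,2.3793e-05
808,1.9357e-05
810,1.5712e-05
812,1.2725e-05
814,1.0282e-05
816,8.2894e-06
818,6.6678e-06
820,5.3513e-06
822,4.285e-06
824,3.4234e-06
826,2.7288e-06
828,2.1703e-06
830,1.7221e-06
832,1.3634e-06
834,1.077e-06
836,8.488e-07
838,6.6745e-07
840,5.2366e-07
842,4.0991e-07
844,3.2014e-07
846,2.4947e-07
848,1.9396e-07
850,1.5046e-07
852,1.1645e-07
854,8.9921e-08
856,6.928e-08
858,5.3256e-08
860,4.0846e-08
862,3.1257e-08
864,2.3865e-08
866,1.8179e-08
868,1.3817e-08
870,1.0478e-08
872,7.9277e-09
874,5.9845e-09
876,4.5075e-09
878,3.3872e-09
880,2.5397e-09
882,1.8999e-09
884,1.418e-09
886,1.056e-09
888,7.8461e-10
890,5.8165e-10
892,4.3021e-10
894,3.1748e-10
896,2.3376e-10
898,1.7173e-10
900,1.2587e-10
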