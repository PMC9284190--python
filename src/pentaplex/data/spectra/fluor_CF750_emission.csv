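wavelength_nm,value
340,4.8137e-23
342,7.2956e-23
344,1.1038e-22
346,1.6671e-22
348,2.5135e-22
350,3.783e-22
352,5.6839e-22
354,8.5251e-22
356,1.2764e-21
358,1.9079e-21
360,2.8467e-21
362,4.2401e-21
364,6.3047e-21
366,9.3583e-21
368,1.3867e-20
370,2.0512e-20
372,3.0288e-20
374,4.4646e-20
376,6.5697e-20
378,9.6505e-20
380,1.4152e-19
382,2.0716e-19
384,3.0273e-19
386,4.4161e-19
388,6.431e-19
390,9.3489e-19
392,1.3567e-18
394,1.9655e-18
396,2.8424e-18
398,4.1035e-18
400,5.9138e-18
402,8.508e-18
404,1.2219e-17
406,1.7518e-17
408,2.5072e-17
410,3.582e-17
412,5.1088e-17
414,7.2736e-17
416,1.0338e-16
418,1.4668e-16
420,2.0775e-16
422,2.9373e-16
424,4.1459e-16
426,5.8416e-16
428,8.2166e-16
430,1.1537e-15
432,1.6171e-15
434,2.2628e-15
436,3.1607e-15
438,4.4073e-15
440,6.1348e-15
442,8.5248e-15
444,1.1825e-14
446,1.6375e-14
448,2.2636e-14
450,3.1236e-14
452,4.303e-14
454,5.9174e-14
456,8.1233e-14
458,1.1132e-13
460,1.5229e-13
462,2.0798e-13
464,2.8353e-13
466,3.8586e-13
468,5.2421e-13
470,7.1094e-13
472,9.625e-13
474,1.3008e-12
476,1.755e-12
478,2.3637e-12
480,3.1779e-12
482,4.2652e-12
484,5.7146e-12
486,7.6433e-12
488,1.0205e-11
490,1.3602e-11
492,1.8098e-11
494,2.4039e-11
496,3.1874e-11
498,4.2189e-11
500,5.5746e-11
502,7.3532e-11
504,9.6824e-11
506,1.2727e-10
508,1.6701e-10
510,2.1876e-10
512,2.8607e-10
514,3.7343e-10
516,4.8662e-10
518,6.3302e-10
520,8.2203e-10
522,1.0656e-09
524,1.379e-09
526,1.7815e-09
528,2.2975e-09
530,2.9577e-09
532,3.8011e-09
534,4.8764e-09
536,6.2452e-09
538,7.9842e-09
540,1.019e-08
542,1.2982e-08
544,1.6511e-08
546,2.0963e-08
548,2.6568e-08
550,3.3615e-08
552,4.2456e-08
554,5.353e-08
556,6.7375e-08
558,8.4654e-08
560,1.0618e-07
562,1.3295e-07
564,1.6618e-07
566,2.0735e-07
568,2.5828e-07
570,3.2115e-07
572,3.9864e-07
574,4.9397e-07
576,6.1103e-07
578,7.5452e-07
580,9.3009e-07
582,1.1445e-06
584,1.406e-06
586,1.7241e-06
588,2.1106e-06
590,2.5792e-06
592,3.1464e-06
594,3.8317e-06
596,4.6582e-06
598,5.6531e-06
600,6.8486e-06
602,8.2826e-06
604,9.9994e-06
606,1.2051e-05
608,1.4499e-05
610,1.7413e-05
612,2.0877e-05
614,2.4986e-05
616,2.9853e-05
618,3.5605e-05
620,4.2392e-05
622,5.0386e-05
624,5.9783e-05
626,7.0809e-05
628,8.3724e-05
630,9.8822e-05
632,0.00011644
634,0.00013696
636,0.00016082
638,0.00018851
640,0.00022058
642,0.00025766
644,0.00030046
646,0.00034975
648,0.00040642
650,0.00047145
652,0.00054595
654,0.00063111
656,0.0007283
658,0.000839
660,0.00096484
662,0.0011076
664,0.0012694
666,0.0014522
668,0.0016584
670,0.0018907
672,0.0021518
674,0.0024446
676,0.0027725
678,0.003139
680,0.0035477
682,0.0040026
684,0.0045081
686,0.0050686
688,0.0056889
690,0.006374
692,0.0071293
694,0.0079602
696,0.0088726
698,0.0098724
700,0.010966
702,0.012159
704,0.01346
706,0.014874
708,0.016409
710,0.018072
712,0.019874
714,0.021822
716,0.023931
718,0.026216
720,0.028701
722,0.031419
724,0.034419
726,0.037773
728,0.041584
730,0.046002
732,0.051238
734,0.057576
736,0.065396
738,0.075185
740,0.087547
742,0.1032
744,0.12297
746,0.14773
748,0.17838
750,0.21572
752,0.2604
754,0.31275
756,0.37269
758,0.4396
760,0.51228
762,0.58887
764,0.66694
766,0.74353
768,0.81541
770,0.87924
772,0.9319
774,0.97072
776,0.99376
778,1
780,0.9894
782,0.96296
784,0.92256
786,0.87082
788,0.81083
790,0.74586
792,0.67913
794,0.61354
796,0.55148
798,0.49478
800,0.4446
802,0.40154
804,0.36564
806,0.33654
808,0.31358
810,0.29593
812,0.28269
814,0.27295
816,0.26589
818,0.26078
820,0.25702
822,0.25411
824,0.25168
826,0.24945
828,0.24723
830,0.24486
832,0.24227
834,0.23939
836,0.23621
838,0.23269
840,0.22886
842,0.22471
844,0.22026
846,0.21553
848,0.21053
850,0.2053
852,0.19985
854,0.1942
856,0.18839
858,0.18244
860,0.17636
862,0.1702
864,0.16396
866,0.15768
868,0.15138
870,0.14507
872,0.13879
874,0.13255
876,0.12637
878,0.12027
880,0.11426
882,0.10837
884,0.1026
886,0.096975
888,0.091496
890,0.086177
892,0.081026
894,0.076051
896,0.071257
898,0.06665
900,0.062233
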