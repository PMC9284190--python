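wavelength_nm,value
340,3.5663e-18
342,5.4189e-18
344,8.2153e-18
346,1.2426e-17
348,1.8754e-17
350,2.8239e-17
352,4.2424e-17
354,6.3592e-17
356,9.5105e-17
358,1.4191e-16
360,2.1128e-16
362,3.1383e-16
364,4.6511e-16
366,6.8776e-16
368,1.0147e-15
370,1.4936e-15
372,2.1936e-15
374,3.2144e-15
376,4.6995e-15
378,6.8551e-15
380,9.977e-15
382,1.4488e-14
384,2.099e-14
386,3.0342e-14
388,4.3761e-14
390,6.2972e-14
392,9.0411e-14
394,1.2951e-13
396,1.851e-13
398,2.6396e-13
400,3.7555e-13
402,5.3312e-13
404,7.5507e-13
406,1.067e-12
408,1.5044e-12
410,2.1163e-12
412,2.9703e-12
414,4.1596e-12
416,5.8117e-12
418,8.1017e-12
420,1.1268e-11
422,1.5637e-11
424,2.1651e-11
426,2.991e-11
428,4.1226e-11
430,5.6693e-11
432,7.7787e-11
434,1.0649e-10
436,1.4545e-10
438,1.9822e-10
440,2.6951e-10
442,3.6562e-10
444,4.9488e-10
446,6.6832e-10
448,9.0051e-10
450,1.2106e-09
452,1.6238e-09
454,2.1731e-09
456,2.9016e-09
458,3.8656e-09
460,5.1382e-09
462,6.8142e-09
464,9.0165e-09
466,1.1904e-08
468,1.5679e-08
470,2.0606e-08
472,2.702e-08
474,3.5349e-08
476,4.6141e-08
478,6.0092e-08
480,7.8084e-08
482,1.0123e-07
484,1.3095e-07
486,1.69e-07
488,2.1762e-07
490,2.7958e-07
492,3.5838e-07
494,4.5835e-07
496,5.8487e-07
498,7.4463e-07
500,9.4588e-07
502,1.1988e-06
504,1.5159e-06
506,1.9126e-06
508,2.4075e-06
510,3.0237e-06
512,3.7891e-06
514,4.7373e-06
516,5.9095e-06
518,7.355e-06
520,9.1334e-06
522,1.1316e-05
524,1.3989e-05
526,1.7253e-05
528,2.1231e-05
530,2.6068e-05
532,3.1933e-05
534,3.903e-05
536,4.7595e-05
538,5.7909e-05
540,7.0299e-05
542,8.5146e-05
544,0.00010289
546,0.00012406
548,0.00014924
550,0.00017913
552,0.00021452
554,0.00025631
556,0.00030556
558,0.00036344
560,0.0004313
562,0.00051068
564,0.0006033
566,0.0007111
568,0.00083626
570,0.00098123
572,0.0011487
574,0.0013418
576,0.0015637
578,0.0018182
580,0.0021093
582,0.0024415
584,0.0028196
586,0.003249
588,0.0037352
590,0.0042844
592,0.0049032
594,0.0055988
596,0.0063785
598,0.0072504
600,0.0082228
602,0.0093046
604,0.010505
606,0.011834
608,0.013301
610,0.014919
612,0.016699
614,0.018656
616,0.020811
618,0.02319
620,0.025835
622,0.028809
624,0.032213
626,0.036201
628,0.041011
630,0.046992
632,0.054645
634,0.064656
636,0.077924
638,0.095567
640,0.1189
642,0.14935
644,0.18834
646,0.23708
648,0.29634
650,0.36616
652,0.44564
654,0.53273
656,0.62422
658,0.7158
660,0.80243
662,0.87874
664,0.93966
666,0.98101
668,1
670,0.99566
672,0.9689
674,0.92242
676,0.86037
678,0.78774
680,0.70982
682,0.63163
684,0.55738
686,0.49026
688,0.43224
690,0.3842
692,0.34605
694,0.31696
696,0.29571
698,0.28084
700,0.27089
702,0.26454
704,0.26064
706,0.25829
708,0.2568
710,0.25567
712,0.25455
714,0.25321
716,0.25152
718,0.2494
720,0.24679
722,0.2437
724,0.24012
726,0.23606
728,0.23155
730,0.22661
732,0.22128
734,0.21558
736,0.20956
738,0.20324
740,0.19667
742,0.18987
744,0.1829
746,0.17579
748,0.16856
750,0.16127
752,0.15395
754,0.14662
756,0.13933
758,0.1321
760,0.12496
762,0.11794
764,0.11106
766,0.10435
768,0.097817
770,0.091487
772,0.085374
774,0.079488
776,0.073841
778,0.06844
780,0.06329
782,0.058394
784,0.053756
786,0.049374
788,0.045246
790,0.04137
792,0.03774
794,0.03435
796,0.031194
798,0.028264
800,0.025551
802,0.023047
804,0.02074
806,0.018622
808,0.016683
810,0.014912
812,0.013298
814,0.011832
816,0.010504
818,0.0093044
820,0.0082227
822,0.0072504
824,0.0063785
826,0.0055988
828,0.0049032
830,0.0042844
832,0.0037352
834,0.003249
836,0.0028196
838,0.0024415
840,0.0021093
842,0.0018182
844,0.0015637
846,0.0013418
848,0.0011487
850,0.00098123
852,0.00083626
854,0.0007111
856,0.0006033
858,0.00051068
860,0.0004313
862,0.00036344
864,0.00030556
866,0.00025631
868,0.00021452
870,0.00017913
872,0.00014924
874,0.00012406
876,0.00010289
878,8.5146e-05
880,7.0299e-05
882,5.7909e-05
884,4.7595e-05
886,3.903e-05
888,3.1933e-05
890,2.6068e-05
892,2.1231e-05
894,1.7253e-05
896,1.3989e-05
898,1.1316e-05
900,9.1334e-06
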