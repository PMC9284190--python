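wavelength_nm,value
340,2.9811e-06
342,3.7267e-06
344,4.6494e-06
346,5.7893e-06
348,7.1943e-06
350,8.9227e-06
352,1.1044e-05
354,1.3644e-05
356,1.6822e-05
358,2.0699e-05
360,2.5419e-05
362,3.1155e-05
364,3.8109e-05
366,4.6523e-05
368,5.6684e-05
370,6.8927e-05
372,8.3648e-05
374,0.00010131
376,0.00012247
378,0.00014775
380,0.00017789
382,0.00021377
384,0.00025637
386,0.00030685
388,0.00036656
390,0.00043701
392,0.00051998
394,0.00061747
396,0.0007318
398,0.00086559
400,0.0010218
402,0.0012039
404,0.0014155
406,0.0016611
408,0.0019455
410,0.0022741
412,0.0026529
414,0.0030887
416,0.003589
418,0.0041621
420,0.0048172
422,0.0055644
424,0.0064149
426,0.0073807
428,0.0084751
430,0.0097127
432,0.011109
434,0.012681
436,0.014447
438,0.016426
440,0.01864
442,0.02111
444,0.02386
446,0.026915
448,0.030302
450,0.034047
452,0.03818
454,0.042731
456,0.047729
458,0.053206
460,0.059195
462,0.065729
464,0.072839
466,0.080559
468,0.088922
470,0.097959
472,0.1077
474,0.11818
476,0.12942
478,0.14145
480,0.1543
482,0.16797
484,0.1825
486,0.1979
488,0.21417
490,0.23132
492,0.24935
494,0.26826
496,0.28803
498,0.30865
500,0.33009
502,0.35232
504,0.37531
506,0.39901
508,0.42337
510,0.44833
512,0.47383
514,0.49978
516,0.52612
518,0.55276
520,0.57959
522,0.60653
524,0.63347
526,0.6603
528,0.68691
530,0.71318
532,0.73899
534,0.76423
536,0.78877
538,0.81249
540,0.83527
542,0.857
544,0.87755
546,0.89683
548,0.91472
550,0.93113
552,0.94596
554,0.95913
556,0.97057
558,0.9802
560,0.98797
562,0.99385
564,0.99778
566,0.99975
568,0.99975
570,0.99778
572,0.99385
574,0.98797
576,0.9802
578,0.97057
580,0.95913
582,0.94596
584,0.93113
586,0.91472
588,0.89683
590,0.87755
592,0.857
594,0.83527
596,0.81249
598,0.78877
600,0.76423
602,0.73899
604,0.71318
606,0.68691
608,0.6603
610,0.63347
612,0.60653
614,0.57959
616,0.55276
618,0.52612
620,0.49978
622,0.47383
624,0.44833
626,0.42337
628,0.39901
630,0.37531
632,0.35232
634,0.33009
636,0.30865
638,0.28803
640,0.26826
642,0.24935
644,0.23132
646,0.21417
648,0.1979
650,0.1825
652,0.16797
654,0.1543
656,0.14145
658,0.12942
660,0.11818
662,0.1077
664,0.097959
666,0.088922
668,0.080559
670,0.072839
672,0.065729
674,0.059195
676,0.053206
678,0.047729
680,0.042731
682,0.03818
684,0.034047
686,0.030302
688,0.026915
690,0.02386
692,0.02111
694,0.01864
696,0.016426
698,0.014447
700,0.012681
702,0.011109
704,0.0097127
706,0.0084751
708,0.0073807
710,0.0064149
712,0.0055644
714,0.0048172
716,0.0041621
718,0.003589
720,0.0030887
722,0.0026529
724,0.0022741
726,0.0019455
728,0.0016611
730,0.0014155
732,0.0012039
734,0.0010218
736,0.00086559
738,0.0007318
740,0.00061747
742,0.00051998
744,0.00043701
746,0.00036656
748,0.00030685
750,0.00025637
752,0.00021377
754,0.00017789
756,0.00014775
758,0.00012247
760,0.00010131
762,8.3648e-05
764,6.8927e-05
766,5.6684e-05
768,4.6523e-05
770,3.8109e-05
772,3.1155e-05
774,2.5419e-05
776,2.0699e-05
778,1.6822e-05
780,1.3644e-05
782,1.1044e-05
784,8.9227e-06
786,7.1943e-06
788,5.7893e-06
790,4.6494e-06
792,3.7267e-06
794,2.9811e-06
796,2.38e-06
798,1.8964e-06
800,1.5081e-06
802,1.1969e-06
804,9.4802e-07
806,7.4943e-07
808,5.9127e-07
810,4.6557e-07
812,3.6587e-07
814,2.8695e-07
816,2.2461e-07
818,1.7547e-07
820,1.3681e-07
822,1.0645e-07
824,8.2671e-08
826,6.4075e-08
828,4.9564e-08
830,3.8264e-08
832,2.9481e-08
834,2.267e-08
836,1.7398e-08
838,1.3326e-08
840,1.0186e-08
842,7.7712e-09
844,5.917e-09
846,4.4963e-09
848,3.41e-09
850,2.5811e-09
852,1.9498e-09
854,1.47e-09
856,1.1061e-09
858,8.3059e-10
860,6.225e-10
862,4.6562e-10
864,3.4759e-10
866,2.5897e-10
868,1.9256e-10
870,1.429e-10
872,1.0584e-10
874,7.8231e-11
876,5.7712e-11
878,4.2491e-11
880,3.1223e-11
882,2.2897e-11
884,1.6759e-11
886,1.2242e-11
888,8.9245e-12
890,6.4933e-12
892,4.7151e-12
894,3.4171e-12
896,2.4716e-12
898,1.7841e-12
900,1.2853e-12
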