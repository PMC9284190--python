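wavelength_nm,value
340,2.8919e-09
342,3.9713e-09
344,5.4385e-09
346,7.4271e-09
348,1.0115e-08
350,1.3737e-08
352,1.8605e-08
354,2.5128e-08
356,3.3844e-08
358,4.5457e-08
360,6.0886e-08
362,8.1328e-08
364,1.0833e-07
366,1.439e-07
368,1.9062e-07
370,2.5181e-07
372,3.3172e-07
374,4.3579e-07
376,5.7091e-07
378,7.4587e-07
380,9.7175e-07
382,1.2625e-06
384,1.6358e-06
386,2.1135e-06
388,2.7232e-06
390,3.4991e-06
392,4.4836e-06
394,5.7292e-06
396,7.3006e-06
398,9.2773e-06
400,1.1757e-05
402,1.4857e-05
404,1.8724e-05
406,2.3531e-05
408,2.9491e-05
410,3.6858e-05
412,4.5938e-05
414,5.7097e-05
416,7.0769e-05
418,8.7474e-05
420,0.00010782
422,0.00013254
424,0.00016246
426,0.0001986
428,0.0002421
430,0.00029431
432,0.00035679
434,0.00043134
436,0.00052003
438,0.00062522
440,0.0007496
442,0.00089624
444,0.0010686
446,0.0012706
448,0.0015066
450,0.0017815
452,0.0021008
454,0.0024705
456,0.0028974
458,0.003389
460,0.0039537
462,0.0046011
464,0.0053425
466,0.0061914
468,0.0071652
470,0.008287
472,0.0095892
474,0.011119
476,0.012946
478,0.015174
480,0.017956
482,0.021511
484,0.026153
486,0.032311
488,0.040554
490,0.051612
492,0.066382
494,0.08591
496,0.11135
498,0.14388
500,0.18458
502,0.23431
504,0.29346
506,0.36186
508,0.43853
510,0.52166
512,0.60854
514,0.69566
516,0.77897
518,0.85412
520,0.91694
522,0.96377
524,0.99194
526,1
528,0.98791
530,0.95706
532,0.91004
534,0.85044
536,0.78237
538,0.7101
540,0.63763
542,0.5684
544,0.50506
546,0.44937
548,0.40224
550,0.36382
552,0.33364
554,0.31083
556,0.29427
558,0.28274
560,0.27506
562,0.27018
564,0.26718
566,0.26533
568,0.26405
570,0.26293
572,0.26166
574,0.26003
576,0.25792
578,0.25525
580,0.25199
582,0.24813
584,0.24368
586,0.23865
588,0.23309
590,0.22703
592,0.22052
594,0.21361
596,0.20634
598,0.19876
600,0.19094
602,0.18291
604,0.17474
606,0.16647
608,0.15816
610,0.14984
612,0.14157
614,0.13338
616,0.12532
618,0.11742
620,0.10972
622,0.10224
624,0.095001
626,0.088033
628,0.08135
630,0.074967
632,0.068893
634,0.063137
636,0.057701
638,0.052587
640,0.047794
642,0.043318
644,0.039152
646,0.035289
648,0.03172
650,0.028432
652,0.025415
654,0.022655
656,0.020139
658,0.017852
660,0.015782
662,0.013913
664,0.012232
666,0.010724
668,0.0093755
670,0.0081742
672,0.0071071
674,0.0061622
676,0.0053281
678,0.0045942
680,0.0039505
682,0.0033875
684,0.0028967
686,0.0024702
688,0.0021007
690,0.0017815
692,0.0015066
694,0.0012706
696,0.0010686
698,0.00089624
700,0.0007496
702,0.00062522
704,0.00052003
706,0.00043134
708,0.00035679
710,0.00029431
712,0.0002421
714,0.0001986
716,0.00016246
718,0.00013254
720,0.00010782
722,8.7474e-05
724,7.0769e-05
726,5.7097e-05
728,4.5938e-05
730,3.6858e-05
732,2.9491e-05
734,2.3531e-05
736,1.8724e-05
738,1.4857e-05
740,1.1757e-05
742,9.2773e-06
744,7.3006e-06
746,5.7292e-06
748,4.4836e-06
750,3.4991e-06
752,2.7232e-06
754,2.1135e-06
756,1.6358e-06
758,1.2625e-06
760,9.7175e-07
762,7.4587e-07
764,5.7091e-07
766,4.3579e-07
768,3.3172e-07
770,2.5181e-07
772,1.9062e-07
774,1.439e-07
776,1.0833e-07
778,8.1328e-08
780,6.0886e-08
782,4.5457e-08
784,3.3844e-08
786,2.5128e-08
788,1.8605e-08
790,1.3737e-08
792,1.0115e-08
794,7.4271e-09
796,5.4385e-09
798,3.9713e-09
800,2.8919e-09
802,2.1001e-09
804,1.5208e-09
806,1.0983e-09
808,7.9098e-10
810,5.6807e-10
812,4.0685e-10
814,2.9058e-10
816,2.0697e-10
818,1.47e-10
820,1.0412e-10
822,7.3547e-11
824,5.1806e-11
826,3.6391e-11
828,2.5492e-11
830,1.7808e-11
832,1.2406e-11
834,8.6183e-12
836,5.9706e-12
838,4.1249e-12
840,2.8419e-12
842,1.9525e-12
844,1.3378e-12
846,9.1404e-13
848,6.2279e-13
850,4.2318e-13
852,2.8674e-13
854,1.9376e-13
856,1.3057e-13
858,8.774e-14
860,5.8798e-14
862,3.9293e-14
864,2.6186e-14
866,1.7403e-14
868,1.1534e-14
870,7.623e-15
872,5.0242e-15
874,3.3023e-15
876,2.1645e-15
878,1.4148e-15
880,9.2218e-16
882,5.9944e-16
884,3.8857e-16
886,2.5118e-16
888,1.6192e-16
890,1.0409e-16
892,6.6733e-17
894,4.2663e-17
896,2.7199e-17
898,1.7293e-17
900,1.0964e-17
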