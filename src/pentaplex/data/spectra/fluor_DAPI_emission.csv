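wavelength_nm,value
340,0.00065288
342,0.00075754
344,0.00088077
346,0.0010264
348,0.0011991
350,0.0014045
352,0.0016497
354,0.0019431
356,0.002295
358,0.0027177
360,0.0032263
362,0.0038386
364,0.0045759
366,0.0054635
368,0.0065309
370,0.007813
372,0.0093501
374,0.011189
376,0.013382
378,0.015991
380,0.019084
382,0.022737
384,0.027035
386,0.03207
388,0.037943
390,0.044762
392,0.052642
394,0.061703
396,0.07207
398,0.083868
400,0.097222
402,0.11225
404,0.12908
406,0.14781
408,0.16853
410,0.19132
412,0.21622
414,0.24327
416,0.27245
418,0.30374
420,0.33705
422,0.37227
424,0.40923
426,0.44774
428,0.48756
430,0.52839
432,0.5699
434,0.61174
436,0.65351
438,0.69478
440,0.73513
442,0.77409
444,0.81123
446,0.84609
448,0.87825
450,0.90732
452,0.93292
454,0.95475
456,0.97253
458,0.98605
460,0.99518
462,0.99983
464,1
466,0.99574
468,0.98719
470,0.97453
472,0.95801
474,0.93793
476,0.91465
478,0.88853
480,0.86
482,0.82947
484,0.79739
486,0.76418
488,0.73027
490,0.69606
492,0.66194
494,0.62825
496,0.59532
498,0.5634
500,0.53274
502,0.50352
504,0.4759
506,0.44998
508,0.42583
510,0.40348
512,0.38293
514,0.36413
516,0.34705
518,0.33159
520,0.31767
522,0.30517
524,0.29398
526,0.28398
528,0.27504
530,0.26704
532,0.25986
534,0.25338
536,0.24749
538,0.24209
540,0.23709
542,0.2324
544,0.22795
546,0.22368
548,0.21952
550,0.21542
552,0.21136
554,0.20728
556,0.20317
558,0.19901
560,0.19478
562,0.19048
564,0.18609
566,0.18162
568,0.17706
570,0.17242
572,0.16771
574,0.16293
576,0.1581
578,0.15322
580,0.1483
582,0.14336
584,0.1384
586,0.13345
588,0.1285
590,0.12358
592,0.11869
594,0.11384
596,0.10905
598,0.10432
600,0.09967
602,0.095098
604,0.090617
606,0.086232
608,0.081952
610,0.077781
612,0.073725
614,0.069788
616,0.065974
618,0.062286
620,0.058727
622,0.055298
624,0.052
626,0.048834
628,0.045801
630,0.042899
632,0.040128
634,0.037486
636,0.034972
638,0.032584
640,0.030318
642,0.028173
644,0.026145
646,0.02423
648,0.022427
650,0.02073
652,0.019136
654,0.017641
656,0.016242
658,0.014934
660,0.013713
662,0.012575
664,0.011517
666,0.010533
668,0.0096212
670,0.0087765
672,0.0079953
674,0.007274
676,0.006609
678,0.0059969
680,0.0054343
682,0.004918
684,0.0044448
686,0.0040119
688,0.0036163
690,0.0032555
692,0.0029267
694,0.0026277
696,0.0023562
698,0.0021099
700,0.0018868
702,0.0016851
704,0.001503
706,0.0013388
708,0.0011909
710,0.001058
712,0.00093866
714,0.00083169
716,0.00073594
718,0.00065035
720,0.00057396
722,0.00050587
724,0.00044527
726,0.00039141
728,0.00034361
730,0.00030125
732,0.00026376
734,0.00023063
736,0.0002014
738,0.00017564
740,0.00015297
742,0.00013305
744,0.00011557
746,0.00010026
748,8.6859e-05
750,7.5151e-05
752,6.4935e-05
754,5.6033e-05
756,4.8288e-05
758,4.1558e-05
760,3.5719e-05
762,3.066e-05
764,2.6283e-05
766,2.2501e-05
768,1.9237e-05
770,1.6426e-05
772,1.4006e-05
774,1.1927e-05
776,1.0144e-05
778,8.6154e-06
780,7.3076e-06
782,6.1902e-06
784,5.2367e-06
786,4.4242e-06
788,3.7329e-06
790,3.1454e-06
792,2.6469e-06
794,2.2244e-06
796,1.8669e-06
798,1.5648e-06
800,1.3098e-06
802,1.095e-06
804,9.1415e-07
806,7.6218e-07
808,6.3463e-07
810,5.2772e-07
812,4.3825e-07
814,3.6346e-07
816,3.0104e-07
818,2.4901e-07
820,2.057e-07
822,1.697e-07
824,1.3981e-07
826,1.1504e-07
828,9.4529e-08
830,7.7573e-08
832,6.3574e-08
834,5.2033e-08
836,4.2531e-08
838,3.4718e-08
840,2.8303e-08
842,2.3042e-08
844,1.8735e-08
846,1.5213e-08
848,1.2336e-08
850,9.9905e-09
852,8.0801e-09
854,6.5263e-09
856,5.2644e-09
858,4.2409e-09
860,3.4118e-09
862,2.7412e-09
864,2.1995e-09
866,1.7625e-09
868,1.4105e-09
870,1.1273e-09
872,8.9975e-10
874,7.1719e-10
876,5.7091e-10
878,4.5387e-10
880,3.6035e-10
882,2.8572e-10
884,2.2625e-10
886,1.7891e-10
888,1.413e-10
890,1.1144e-10
892,8.7781e-11
894,6.9051e-11
896,5.4245e-11
898,4.2558e-11
900,3.3345e-11
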