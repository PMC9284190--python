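wavelength_nm,value
340,2.6292e-16
342,3.9055e-16
344,5.7882e-16
346,8.5589e-16
348,1.2627e-15
350,1.8587e-15
352,2.7299e-15
354,4.0002e-15
356,5.8483e-15
358,8.531e-15
360,1.2416e-14
362,1.8029e-14
364,2.6121e-14
366,3.7759e-14
368,5.4459e-14
370,7.8366e-14
372,1.1251e-13
374,1.6117e-13
376,2.3036e-13
378,3.2849e-13
380,4.6736e-13
382,6.6345e-13
384,9.3966e-13
386,1.3279e-12
388,1.8722e-12
390,2.6337e-12
392,3.6965e-12
394,5.1764e-12
396,7.2325e-12
398,1.0082e-11
400,1.4023e-11
402,1.946e-11
404,2.6944e-11
406,3.7222e-11
408,5.1304e-11
410,7.0553e-11
412,9.6804e-11
414,1.3252e-10
416,1.8101e-10
418,2.4667e-10
420,3.354e-10
422,4.55e-10
424,6.1586e-10
426,8.3171e-10
428,1.1207e-09
430,1.5066e-09
432,2.0208e-09
434,2.7043e-09
436,3.611e-09
438,4.8106e-09
440,6.3943e-09
442,8.4801e-09
444,1.1221e-08
446,1.4814e-08
448,1.9512e-08
450,2.5644e-08
452,3.3625e-08
454,4.3991e-08
456,5.7421e-08
458,7.4783e-08
460,9.7173e-08
462,1.2598e-07
464,1.6296e-07
466,2.1031e-07
468,2.7082e-07
470,3.4793e-07
472,4.4599e-07
474,5.704e-07
476,7.2785e-07
478,9.2667e-07
480,1.1771e-06
482,1.4919e-06
484,1.8865e-06
486,2.3801e-06
488,2.9961e-06
490,3.7629e-06
492,4.7154e-06
494,5.8955e-06
496,7.3542e-06
498,9.1531e-06
500,1.1366e-05
502,1.4082e-05
504,1.7408e-05
506,2.1471e-05
508,2.6422e-05
510,3.244e-05
512,3.9739e-05
514,4.8571e-05
516,5.9231e-05
518,7.2066e-05
520,8.7484e-05
522,0.00010596
524,0.00012805
526,0.00015439
528,0.00018573
530,0.00022292
532,0.00026696
534,0.00031897
536,0.00038026
538,0.00045229
540,0.00053674
542,0.00063553
544,0.00075079
546,0.00088494
548,0.0010407
550,0.0012211
552,0.0014295
554,0.0016698
556,0.0019459
558,0.0022627
560,0.002625
562,0.0030384
564,0.0035089
566,0.0040432
568,0.0046483
570,0.0053318
572,0.0061019
574,0.0069675
576,0.0079378
578,0.0090228
580,0.010233
582,0.011579
584,0.013072
586,0.014725
588,0.016549
590,0.018557
592,0.020761
594,0.023175
596,0.02581
598,0.028681
600,0.031798
602,0.035174
604,0.03882
606,0.042748
608,0.046966
610,0.051483
612,0.056307
614,0.061444
616,0.066897
618,0.07267
620,0.078762
622,0.085171
624,0.091893
626,0.098921
628,0.10624
630,0.11385
632,0.12173
634,0.12986
636,0.13821
638,0.14677
640,0.15551
642,0.16439
644,0.17339
646,0.18247
648,0.19158
650,0.2007
652,0.20977
654,0.21876
656,0.22761
658,0.23629
660,0.24474
662,0.25293
664,0.26079
666,0.26829
668,0.27538
670,0.28202
672,0.28817
674,0.29379
676,0.29885
678,0.30333
680,0.30719
682,0.31043
684,0.31304
686,0.31502
688,0.31639
690,0.31719
692,0.31748
694,0.31733
696,0.31685
698,0.31618
700,0.31551
702,0.31506
704,0.3151
706,0.31595
708,0.318
710,0.32166
712,0.3274
714,0.33571
716,0.34709
718,0.36205
720,0.38102
722,0.40439
724,0.43243
726,0.46524
728,0.50276
730,0.54469
732,0.59051
734,0.63942
736,0.69039
738,0.74215
740,0.79324
742,0.84206
744,0.88696
746,0.92628
748,0.95847
750,0.98217
752,0.99627
754,1
756,0.99297
758,0.97519
760,0.94708
762,0.90941
764,0.86333
766,0.8102
768,0.7516
770,0.68921
772,0.62472
774,0.55975
776,0.49577
778,0.4341
780,0.37579
782,0.32167
784,0.27229
786,0.22799
788,0.18887
790,0.15484
792,0.12567
794,0.10103
796,0.080496
798,0.063605
800,0.049885
802,0.038873
804,0.030133
806,0.023269
808,0.017927
810,0.013805
812,0.010645
814,0.0082354
816,0.0064036
818,0.0050125
820,0.0039548
822,0.0031475
824,0.0025275
826,0.0020473
828,0.0016716
830,0.0013744
832,0.0011366
834,0.00094419
836,0.00078694
838,0.00065732
840,0.00054972
842,0.00045992
844,0.00038469
846,0.00032152
848,0.0002684
850,0.00022373
852,0.00018618
854,0.00015463
856,0.00012818
858,0.00010603
860,8.7521e-05
862,7.2085e-05
864,5.924e-05
866,4.8576e-05
868,3.9742e-05
870,3.2441e-05
872,2.6422e-05
874,2.1471e-05
876,1.7408e-05
878,1.4083e-05
880,1.1366e-05
882,9.1531e-06
884,7.3542e-06
886,5.8955e-06
888,4.7154e-06
890,3.7629e-06
892,2.9961e-06
894,2.3801e-06
896,1.8865e-06
898,1.4919e-06
900,1.1771e-06
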