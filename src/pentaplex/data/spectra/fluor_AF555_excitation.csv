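wavelength_nm,value
340,1.0397e-15
342,2.1784e-15
344,4.5266e-15
346,9.3289e-15
348,1.9068e-14
350,3.8652e-14
352,7.7708e-14
354,1.5494e-13
356,3.0639e-13
358,6.0089e-13
360,1.1688e-12
362,2.2546e-12
364,4.3134e-12
366,8.1844e-12
368,1.5401e-11
370,2.8744e-11
372,5.3204e-11
374,9.7667e-11
376,1.7781e-10
378,3.2107e-10
380,5.7495e-10
382,1.0211e-09
384,1.7986e-09
386,3.1421e-09
388,5.4438e-09
390,9.3539e-09
392,1.594e-08
394,2.6941e-08
396,4.5158e-08
398,7.5071e-08
400,1.2377e-07
402,2.0238e-07
404,3.2821e-07
406,5.2787e-07
408,8.4201e-07
410,1.332e-06
412,2.0899e-06
414,3.252e-06
416,5.0186e-06
418,7.6812e-06
420,1.166e-05
422,1.7553e-05
424,2.6208e-05
426,3.8808e-05
428,5.6992e-05
430,8.3009e-05
432,0.00011991
434,0.00017178
436,0.00024407
438,0.00034393
440,0.00048065
442,0.0006662
444,0.00091578
446,0.0012485
448,0.0016881
450,0.0022636
452,0.0030105
454,0.0039708
456,0.0051943
458,0.0067388
460,0.0086707
462,0.011065
464,0.014003
466,0.017577
468,0.02188
470,0.027013
472,0.033076
474,0.040166
476,0.048375
478,0.057782
480,0.068451
482,0.080423
484,0.093714
486,0.10831
488,0.12414
490,0.14114
492,0.15915
494,0.17802
496,0.19753
498,0.21745
500,0.23753
502,0.2575
504,0.27714
506,0.29622
508,0.31463
510,0.33228
512,0.34925
514,0.36571
516,0.382
518,0.39861
520,0.41617
522,0.43542
524,0.45718
526,0.48226
528,0.51141
530,0.54517
532,0.58384
534,0.62729
536,0.675
538,0.7259
540,0.77844
542,0.83061
544,0.88005
546,0.92418
548,0.96042
550,0.98636
552,1
554,0.99989
556,0.98531
558,0.95631
560,0.91375
562,0.85918
564,0.79476
566,0.72307
568,0.64689
570,0.569
572,0.49202
574,0.4182
576,0.34938
578,0.28687
580,0.23149
582,0.18358
584,0.14307
586,0.10957
588,0.08247
590,0.060998
592,0.044338
594,0.031673
596,0.022237
598,0.015344
600,0.010408
602,0.0069392
604,0.0045487
606,0.0029318
608,0.0018584
610,0.0011588
612,0.00071092
614,0.00042932
616,0.0002553
618,0.00014958
620,8.6407e-05
622,4.9254e-05
624,2.7733e-05
626,1.5444e-05
628,8.5187e-06
630,4.6621e-06
632,2.5366e-06
634,1.375e-06
636,7.4424e-07
638,4.031e-07
640,2.189e-07
642,1.1936e-07
644,6.5416e-08
646,3.6043e-08
648,1.9958e-08
650,1.1096e-08
652,6.186e-09
654,3.4527e-09
656,1.9263e-09
658,1.0727e-09
660,5.9542e-10
662,3.2904e-10
664,1.8087e-10
666,9.8816e-11
668,5.3628e-11
670,2.8898e-11
672,1.5456e-11
674,8.2036e-12
676,4.32e-12
678,2.2568e-12
680,1.1695e-12
682,6.0113e-13
684,3.0647e-13
686,1.5496e-13
688,7.7715e-14
690,3.8655e-14
692,1.9068e-14
694,9.3291e-15
696,4.5267e-15
698,2.1784e-15
700,1.0397e-15
702,4.9212e-16
704,2.3103e-16
706,1.0756e-16
708,4.9667e-17
710,2.2745e-17
712,1.033e-17
714,4.6533e-18
716,2.0788e-18
718,9.2103e-19
720,4.0471e-19
722,1.7637e-19
724,7.623e-20
726,3.2676e-20
728,1.3891e-20
730,5.857e-21
732,2.4491e-21
734,1.0157e-21
736,4.1776e-22
738,1.7041e-22
740,6.8941e-23
742,2.7661e-23
744,1.1007e-23
746,4.3439e-24
748,1.7002e-24
750,6.6e-25
752,2.5409e-25
754,9.7017e-26
756,3.6738e-26
758,1.3797e-26
760,5.1391e-27
762,1.8984e-27
764,6.9549e-28
766,2.5271e-28
768,9.1064e-29
770,3.2546e-29
772,1.1536e-29
774,4.0552e-30
776,1.4138e-30
778,4.8885e-31
780,1.6764e-31
782,5.7014e-32
784,1.9231e-32
786,6.4332e-33
788,2.1344e-33
790,7.0229e-34
792,2.2918e-34
794,7.4174e-35
796,2.3809e-35
798,7.5793e-36
800,2.393e-36
802,7.4929e-37
804,2.3269e-37
806,7.1666e-38
808,2.1891e-38
810,6.6317e-39
812,1.9925e-39
814,5.9371e-40
816,1.7545e-40
818,5.1424e-41
820,1.4948e-41
822,4.3093e-42
824,1.2321e-42
826,3.4937e-43
828,9.8252e-44
830,2.7404e-44
832,7.5803e-45
834,2.0796e-45
836,5.6581e-46
838,1.5268e-46
840,4.086e-47
842,1.0845e-47
844,2.8548e-48
846,7.453e-49
848,1.9297e-49
850,4.9553e-50
852,1.262e-50
854,3.1875e-51
856,7.9847e-52
858,1.9837e-52
860,4.8877e-53
862,1.1944e-53
864,2.8947e-54
866,6.9576e-55
868,1.6586e-55
870,3.9211e-56
872,9.194e-57
874,2.138e-57
876,4.9309e-58
878,1.1278e-58
880,2.5585e-59
882,5.7562e-60
884,1.2844e-60
886,2.8423e-61
888,6.238e-62
890,1.3578e-62
892,2.9311e-63
894,6.2755e-64
896,1.3325e-64
898,2.8061e-65
900,5.8607e-66
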