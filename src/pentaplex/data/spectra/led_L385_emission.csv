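wavelength_nm,value
340,3.9116e-11
342,3.1399e-10
344,2.2928e-09
346,1.523e-08
348,9.2027e-08
350,5.0584e-07
352,2.5293e-06
354,1.1504e-05
356,4.7601e-05
358,0.00017916
360,0.00061343
362,0.0019106
364,0.0054131
366,0.013951
368,0.032709
370,0.069758
372,0.13534
374,0.23884
376,0.38344
378,0.55996
380,0.74389
382,0.89897
384,0.98824
386,0.98824
388,0.89897
390,0.74389
392,0.55996
394,0.38344
396,0.23884
398,0.13534
400,0.069758
402,0.032709
404,0.013951
406,0.0054131
408,0.0019106
410,0.00061343
412,0.00017916
414,4.7601e-05
416,1.1504e-05
418,2.5293e-06
420,5.0584e-07
422,9.2027e-08
424,1.523e-08
426,2.2928e-09
428,3.1399e-10
430,3.9116e-11
432,4.4327e-12
434,4.5695e-13
436,4.285e-14
438,3.6553e-15
440,2.8364e-16
442,2.0022e-17
444,1.2857e-18
446,7.5097e-20
448,3.9903e-21
450,1.9287e-22
452,8.4806e-24
454,3.392e-25
456,1.2342e-26
458,4.0849e-28
460,1.2299e-29
462,3.3685e-31
464,8.3923e-33
466,1.902e-34
468,3.9214e-36
470,7.3542e-38
472,1.2546e-39
474,1.9471e-41
476,2.7488e-43
478,3.53e-45
480,4.1238e-47
482,4.3822e-49
484,4.2362e-51
486,3.7252e-53
488,2.9799e-55
490,2.1684e-57
492,1.4353e-59
494,8.6428e-62
496,4.7341e-64
498,2.3589e-66
500,1.0692e-68
502,4.4085e-71
504,1.6535e-73
506,5.6418e-76
508,1.7511e-78
510,4.9439e-81
512,1.2698e-83
514,2.9666e-86
516,6.3048e-89
518,1.2189e-91
520,2.1437e-94
522,3.4295e-97
524,4.9909e-100
526,6.6072e-103
528,7.9567e-106
530,8.7164e-109
532,8.6861e-112
534,7.8739e-115
536,6.493e-118
538,4.8706e-121
540,3.3235e-124
542,2.063e-127
544,1.1649e-130
546,5.9835e-134
548,2.7958e-137
550,1.1883e-140
552,4.5948e-144
554,1.6161e-147
556,5.1707e-151
558,1.5049e-154
560,3.9845e-158
562,9.5964e-162
564,2.1025e-165
566,4.1902e-169
568,7.5966e-173
570,1.2528e-176
572,1.8795e-180
574,2.5649e-184
576,3.1842e-188
578,3.5958e-192
580,3.6939e-196
582,3.4519e-200
584,2.9343e-204
586,2.269e-208
588,1.5961e-212
590,1.0213e-216
592,5.945e-221
594,3.1479e-225
596,1.5163e-229
598,6.6437e-234
600,2.6481e-238
602,9.6014e-243
604,3.1668e-247
606,9.5014e-252
608,2.5932e-256
610,6.4384e-261
612,1.4541e-265
614,2.9875e-270
616,5.5833e-275
618,9.492e-280
620,1.468e-284
622,2.0651e-289
624,2.6428e-294
626,3.0766e-299
628,3.2581e-304
630,3.1386e-309
632,2.7503e-314
634,2.1924e-319
636,0
638,0
640,0
642,0
644,0
646,0
648,0
650,0
652,0
654,0
656,0
658,0
660,0
662,0
664,0
666,0
668,0
670,0
672,0
674,0
676,0
678,0
680,0
682,0
684,0
686,0
688,0
690,0
692,0
694,0
696,0
698,0
700,0
702,0
704,0
706,0
708,0
710,0
712,0
714,0
716,0
718,0
720,0
722,0
724,0
726,0
728,0
730,0
732,0
734,0
736,0
738,0
740,0
742,0
744,0
746,0
748,0
750,0
752,0
754,0
756,0
758,0
760,0
762,0
764,0
766,0
768,0
770,0
772,0
774,0
776,0
778,0
780,0
782,0
784,0
786,0
788,0
790,0
792,0
794,0
796,0
798,0
800,0
802,0
804,0
806,0
808,0
810,0
812,0
814,0
816,0
818,0
820,0
822,0
824,0
826,0
828,0
830,0
832,0
834,0
836,0
838,0
840,0
842,0
844,0
846,0
848,0
850,0
852,0
854,0
856,0
858,0
860,0
862,0
864,0
866,0
868,0
870,0
872,0
874,0
876,0
878,0
880,0
882,0
884,0
886,0
888,0
890,0
892,0
894,0
896,0
898,0
900,0
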