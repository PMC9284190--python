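wavelength_nm,value
340,1.1874e-32
342,3.5348e-32
344,1.0436e-31
346,3.056e-31
348,8.8748e-31
350,2.5561e-30
352,7.3014e-30
354,2.0685e-29
356,5.8116e-29
358,1.6194e-28
360,4.4754e-28
362,1.2266e-27
364,3.3343e-27
366,8.9891e-27
368,2.4034e-26
370,6.3732e-26
372,1.6761e-25
374,4.3716e-25
376,1.1308e-24
378,2.9012e-24
380,7.3817e-24
382,1.8627e-23
384,4.6617e-23
386,1.1571e-22
388,2.8483e-22
390,6.9538e-22
392,1.6837e-21
394,4.0432e-21
396,9.6292e-21
398,2.2744e-20
400,5.3279e-20
402,1.2378e-19
404,2.8521e-19
406,6.5176e-19
408,1.4771e-18
410,3.3202e-18
412,7.4014e-18
414,1.6364e-17
416,3.588e-17
418,7.8026e-17
420,1.6828e-16
422,3.5995e-16
424,7.6359e-16
426,1.6065e-15
428,3.3522e-15
430,6.9371e-15
432,1.4238e-14
434,2.8981e-14
436,5.8506e-14
438,1.1714e-13
440,2.3259e-13
442,4.5805e-13
444,8.9462e-13
446,1.7329e-12
448,3.3291e-12
450,6.3428e-12
452,1.1985e-11
454,2.2461e-11
456,4.1746e-11
458,7.6952e-11
460,1.4068e-10
462,2.5507e-10
464,4.5866e-10
466,8.1797e-10
468,1.4467e-09
470,2.5378e-09
472,4.415e-09
474,7.6177e-09
476,1.3035e-08
478,2.2122e-08
480,3.7235e-08
482,6.2156e-08
484,1.029e-07
486,1.6896e-07
488,2.7513e-07
490,4.4434e-07
492,7.117e-07
494,1.1306e-06
496,1.7812e-06
498,2.783e-06
500,4.3127e-06
502,6.6281e-06
504,1.0103e-05
506,1.5272e-05
508,2.2896e-05
510,3.4045e-05
512,5.0204e-05
514,7.3425e-05
516,0.0001065
518,0.00015321
520,0.00021859
522,0.00030929
524,0.00043404
526,0.00060408
528,0.00083382
530,0.0011415
532,0.0015498
534,0.0020868
536,0.0027868
538,0.0036909
540,0.0048481
542,0.0063158
544,0.0081601
546,0.010456
548,0.013288
550,0.016748
552,0.020935
554,0.025953
556,0.031909
558,0.03891
560,0.047055
562,0.056438
564,0.067134
566,0.079201
568,0.092667
570,0.10753
572,0.12375
574,0.14125
576,0.15989
578,0.1795
580,0.19986
582,0.2207
584,0.24171
586,0.26255
588,0.28284
590,0.30222
592,0.32029
594,0.33671
596,0.35114
598,0.36333
600,0.37308
602,0.38032
604,0.3851
606,0.38761
608,0.38824
610,0.38755
612,0.38631
614,0.38551
616,0.38632
618,0.39003
620,0.39805
622,0.41176
624,0.4324
626,0.46094
628,0.49793
630,0.54334
632,0.59647
634,0.65585
636,0.71924
638,0.78373
640,0.84591
642,0.90207
644,0.94853
646,0.98197
648,0.99971
650,1
652,0.98218
654,0.94674
656,0.89528
658,0.83033
660,0.75512
662,0.67327
664,0.58845
666,0.50412
668,0.42329
670,0.34833
672,0.28093
674,0.22203
676,0.17196
678,0.13052
680,0.097073
682,0.070751
684,0.050532
686,0.035367
688,0.024257
690,0.016304
692,0.010739
694,0.0069328
696,0.0043863
698,0.00272
700,0.0016534
702,0.00098522
704,0.00057561
706,0.00032978
708,0.00018532
710,0.00010218
712,5.5303e-05
714,2.9395e-05
716,1.5357e-05
718,7.8924e-06
720,3.9956e-06
722,1.996e-06
724,9.8599e-07
726,4.8298e-07
728,2.3539e-07
730,1.146e-07
732,5.5975e-08
734,2.7549e-08
736,1.3714e-08
738,6.9242e-09
740,3.5497e-09
742,1.8466e-09
744,9.7275e-10
746,5.1737e-10
748,2.7689e-10
750,1.4863e-10
752,7.9787e-11
754,4.2737e-11
756,2.28e-11
758,1.2099e-11
760,6.3802e-12
762,3.3411e-12
764,1.7367e-12
766,8.9579e-13
768,4.584e-13
770,2.327e-13
772,1.1717e-13
774,5.8514e-14
776,2.8984e-14
778,1.4238e-14
780,6.9373e-15
782,3.3523e-15
784,1.6065e-15
786,7.636e-16
788,3.5995e-16
790,1.6828e-16
792,7.8026e-17
794,3.588e-17
796,1.6364e-17
798,7.4014e-18
800,3.3202e-18
802,1.4771e-18
804,6.5176e-19
806,2.8521e-19
808,1.2378e-19
810,5.3279e-20
812,2.2744e-20
814,9.6292e-21
816,4.0432e-21
818,1.6837e-21
820,6.9538e-22
822,2.8483e-22
824,1.1571e-22
826,4.6617e-23
828,1.8627e-23
830,7.3817e-24
832,2.9012e-24
834,1.1308e-24
836,4.3716e-25
838,1.6761e-25
840,6.3732e-26
842,2.4034e-26
844,8.9891e-27
846,3.3343e-27
848,1.2266e-27
850,4.4754e-28
852,1.6194e-28
854,5.8116e-29
856,2.0685e-29
858,7.3014e-30
860,2.5561e-30
862,8.8748e-31
864,3.056e-31
866,1.0436e-31
868,3.5348e-32
870,1.1874e-32
872,3.9557e-33
874,1.307e-33
876,4.2828e-34
878,1.3919e-34
880,4.4861e-35
882,1.434e-35
884,4.5463e-36
886,1.4295e-36
888,4.4575e-37
890,1.3786e-37
892,4.2283e-38
894,1.2862e-38
896,3.8805e-39
898,1.1611e-39
900,3.4455e-40
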