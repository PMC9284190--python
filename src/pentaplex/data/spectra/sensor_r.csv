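wavelength_nm,value
340,5.3599e-08
342,6.9219e-08
344,8.9215e-08
346,1.1476e-07
348,1.4733e-07
350,1.8877e-07
352,2.4139e-07
354,3.0808e-07
356,3.924e-07
358,4.9883e-07
360,6.3286e-07
362,8.0133e-07
364,1.0127e-06
366,1.2772e-06
368,1.6076e-06
370,2.0196e-06
372,2.5321e-06
374,3.1684e-06
376,3.9567e-06
378,4.9316e-06
380,6.1344e-06
382,7.6156e-06
384,9.4358e-06
386,1.1668e-05
388,1.44e-05
390,1.7736e-05
392,2.1802e-05
394,2.6747e-05
396,3.275e-05
398,4.002e-05
400,4.8808e-05
402,5.9408e-05
404,7.2168e-05
406,8.7495e-05
408,0.00010587
410,0.00012785
412,0.00015408
414,0.00018534
416,0.00022249
418,0.00026657
420,0.00031874
422,0.00038038
424,0.00045304
426,0.00053852
428,0.00063886
430,0.0007564
432,0.0008938
434,0.0010541
436,0.0012406
438,0.0014573
440,0.0017085
442,0.001999
444,0.0023343
446,0.0027205
448,0.0031643
450,0.0036732
452,0.0042555
454,0.0049204
456,0.0056781
458,0.0065394
460,0.0075165
462,0.0086226
464,0.009872
466,0.01128
468,0.012863
470,0.01464
472,0.01663
474,0.018852
476,0.021329
478,0.024084
480,0.027142
482,0.030527
484,0.034266
486,0.038388
488,0.042921
490,0.047894
492,0.053338
494,0.059284
496,0.065762
498,0.072804
500,0.080442
502,0.088705
504,0.097624
506,0.10723
508,0.11754
510,0.1286
512,0.14042
514,0.15302
516,0.16642
518,0.18064
520,0.19568
522,0.21157
524,0.22829
526,0.24584
528,0.26423
530,0.28342
532,0.30342
534,0.32418
536,0.34568
538,0.36788
540,0.39073
542,0.41419
544,0.43819
546,0.46266
548,0.48754
550,0.51274
552,0.53818
554,0.56378
556,0.58942
558,0.61502
560,0.64047
562,0.66565
564,0.69047
566,0.71479
568,0.73852
570,0.76154
572,0.78373
574,0.80498
576,0.82518
578,0.84423
580,0.86202
582,0.87845
584,0.89344
586,0.90691
588,0.91878
590,0.92898
592,0.93746
594,0.94416
596,0.94906
598,0.95212
600,0.95333
602,0.95269
604,0.9502
606,0.94589
608,0.93977
610,0.93189
612,0.92231
614,0.91107
616,0.89825
618,0.88393
620,0.8682
622,0.85113
624,0.83285
626,0.81344
628,0.79302
630,0.7717
632,0.74959
634,0.72682
636,0.7035
638,0.67975
640,0.65567
642,0.6314
644,0.60703
646,0.58269
648,0.55846
650,0.53445
652,0.51075
654,0.48746
656,0.46464
658,0.44239
660,0.42076
662,0.39982
664,0.37962
666,0.36021
668,0.34163
670,0.32392
672,0.30711
674,0.2912
676,0.27623
678,0.2622
680,0.24911
682,0.23696
684,0.22574
686,0.21545
688,0.20608
690,0.19759
692,0.18997
694,0.1832
696,0.17725
698,0.1721
700,0.1677
702,0.16404
704,0.16107
706,0.15877
708,0.1571
710,0.15602
712,0.15551
714,0.15552
716,0.15603
718,0.157
720,0.15841
722,0.16021
724,0.16237
726,0.16487
728,0.16768
730,0.17077
732,0.17411
734,0.17768
736,0.18144
738,0.18538
740,0.18947
742,0.1937
744,0.19802
746,0.20244
748,0.20692
750,0.21144
752,0.216
754,0.22056
756,0.22512
758,0.22966
760,0.23416
762,0.2386
764,0.24298
766,0.24728
768,0.25147
770,0.25557
772,0.25954
774,0.26338
776,0.26707
778,0.27062
780,0.27399
782,0.2772
784,0.28023
786,0.28306
788,0.2857
790,0.28813
792,0.29035
794,0.29235
796,0.29413
798,0.29568
800,0.297
802,0.29809
804,0.29893
806,0.29954
808,0.2999
810,0.30002
812,0.29989
814,0.29952
816,0.29891
818,0.29805
820,0.29696
822,0.29563
824,0.29406
826,0.29227
828,0.29025
830,0.288
832,0.28555
834,0.28288
836,0.28
838,0.27694
840,0.27368
842,0.27024
844,0.26662
846,0.26284
848,0.2589
850,0.25481
852,0.25058
854,0.24622
856,0.24174
858,0.23715
860,0.23245
862,0.22766
864,0.22279
866,0.21784
868,0.21284
870,0.20777
872,0.20266
874,0.19752
876,0.19235
878,0.18716
880,0.18196
882,0.17676
884,0.17157
886,0.1664
888,0.16125
890,0.15614
892,0.15106
894,0.14603
896,0.14105
898,0.13613
900,0.13127
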