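wavelength_nm,value
340,4.69e-31
342,3.9554e-30
344,3.2274e-29
346,2.5477e-28
348,1.9458e-27
350,1.4378e-26
352,1.0278e-25
354,7.1087e-25
356,4.7567e-24
358,3.0794e-23
360,1.9287e-22
362,1.1688e-21
364,6.852e-21
366,3.8864e-20
368,2.1327e-19
370,1.1323e-18
372,5.8158e-18
374,2.8901e-17
376,1.3895e-16
378,6.4634e-16
380,2.9087e-15
382,1.2664e-14
384,5.3346e-14
386,2.174e-13
388,8.5718e-13
390,3.2698e-12
392,1.2068e-11
394,4.3088e-11
396,1.4885e-10
398,4.9747e-10
400,1.6085e-09
402,5.0321e-09
404,1.523e-08
406,4.4596e-08
408,1.2634e-07
410,3.4627e-07
412,9.1822e-07
414,2.3557e-06
416,5.847e-06
418,1.4041e-05
420,3.262e-05
422,7.3321e-05
424,0.00015945
426,0.00033546
428,0.00068284
430,0.0013447
432,0.0025621
434,0.0047227
436,0.0084224
438,0.014532
440,0.024258
442,0.039177
444,0.061213
446,0.092535
448,0.13534
450,0.1915
452,0.26215
454,0.3472
456,0.44489
458,0.55154
460,0.66151
462,0.76762
464,0.86178
466,0.93602
468,0.98361
470,1
472,0.98361
474,0.93602
476,0.86178
478,0.76762
480,0.66151
482,0.55154
484,0.44489
486,0.3472
488,0.26215
490,0.1915
492,0.13534
494,0.092535
496,0.061213
498,0.039177
500,0.024258
502,0.014532
504,0.0084224
506,0.0047227
508,0.0025621
510,0.0013447
512,0.00068284
514,0.00033546
516,0.00015945
518,7.3321e-05
520,3.262e-05
522,1.4041e-05
524,5.847e-06
526,2.3557e-06
528,9.1822e-07
530,3.4627e-07
532,1.2634e-07
534,4.4596e-08
536,1.523e-08
538,5.0321e-09
540,1.6085e-09
542,4.9747e-10
544,1.4885e-10
546,4.3088e-11
548,1.2068e-11
550,3.2698e-12
552,8.5718e-13
554,2.174e-13
556,5.3346e-14
558,1.2664e-14
560,2.9087e-15
562,6.4634e-16
564,1.3895e-16
566,2.8901e-17
568,5.8158e-18
570,1.1323e-18
572,2.1327e-19
574,3.8864e-20
576,6.852e-21
578,1.1688e-21
580,1.9287e-22
582,3.0794e-23
584,4.7567e-24
586,7.1087e-25
588,1.0278e-25
590,1.4378e-26
592,1.9458e-27
594,2.5477e-28
596,3.2274e-29
598,3.9554e-30
600,4.69e-31
602,5.3802e-32
604,5.9713e-33
606,6.4118e-34
608,6.661e-35
610,6.6948e-36
612,6.51e-37
614,6.1244e-38
616,5.5743e-39
618,4.9087e-40
620,4.182e-41
622,3.447e-42
624,2.7488e-43
626,2.1207e-44
628,1.583e-45
630,1.1432e-46
632,7.9869e-48
634,5.3988e-49
636,3.5307e-50
638,2.2339e-51
640,1.3674e-52
642,8.0984e-54
644,4.6401e-55
646,2.5722e-56
648,1.3795e-57
650,7.1579e-59
652,3.5933e-60
654,1.7452e-61
656,8.2004e-63
658,3.728e-64
660,1.6396e-65
662,6.977e-67
664,2.8723e-68
666,1.144e-69
668,4.4085e-71
670,1.6436e-72
672,5.9282e-74
674,2.0687e-75
676,6.9844e-77
678,2.2814e-78
680,7.2095e-80
682,2.2042e-81
684,6.5201e-83
686,1.8659e-84
688,5.1663e-86
690,1.3839e-87
692,3.5865e-89
694,8.9926e-91
696,2.1814e-92
698,5.1196e-94
700,1.1625e-95
702,2.5537e-97
704,5.4274e-99
706,1.116e-100
708,2.2201e-102
710,4.273e-104
712,7.9567e-106
714,1.4334e-107
716,2.4984e-109
718,4.213e-111
720,6.8734e-113
722,1.0849e-114
724,1.6567e-116
726,2.4476e-118
728,3.4986e-120
730,4.8382e-122
732,6.4731e-124
734,8.3789e-126
736,1.0493e-127
738,1.2714e-129
740,1.4903e-131
742,1.6901e-133
744,1.8544e-135
746,1.9686e-137
748,2.0217e-139
750,2.0088e-141
752,1.9311e-143
754,1.796e-145
756,1.6161e-147
758,1.4069e-149
760,1.1849e-151
762,9.6555e-154
764,7.612e-156
766,5.8058e-158
768,4.2842e-160
770,3.0586e-162
772,2.1126e-164
774,1.4117e-166
776,9.1272e-169
778,5.709e-171
780,3.4549e-173
782,2.0227e-175
784,1.1458e-177
786,6.279e-180
788,3.3292e-182
790,1.7077e-184
792,8.4751e-187
794,4.0692e-189
796,1.8903e-191
798,8.4954e-194
800,3.6939e-196
802,1.5539e-198
804,6.3243e-201
806,2.4902e-203
808,9.4866e-206
810,3.4965e-208
812,1.2468e-210
814,4.3012e-213
816,1.4356e-215
818,4.6358e-218
820,1.4483e-220
822,4.3775e-223
824,1.2801e-225
826,3.6216e-228
828,9.913e-231
830,2.6251e-233
832,6.7258e-236
834,1.6672e-238
836,3.9981e-241
838,9.2762e-244
840,2.0823e-246
842,4.5221e-249
844,9.5014e-252
846,1.9314e-254
848,3.7985e-257
850,7.2276e-260
852,1.3305e-262
854,2.3696e-265
856,4.0831e-268
858,6.8068e-271
860,1.0978e-273
862,1.7131e-276
864,2.5861e-279
866,3.7772e-282
868,5.3376e-285
870,7.2971e-288
872,9.6517e-291
874,1.2351e-293
876,1.5291e-296
878,1.8316e-299
880,2.1225e-302
882,2.3797e-305
884,2.5813e-308
886,2.7089e-311
888,2.7503e-314
890,2.7016e-317
892,2.5677e-320
894,2.4703e-323
896,0
898,0
900,0
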