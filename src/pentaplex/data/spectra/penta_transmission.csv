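wavelength_nm,value
340,7.9357e-17
342,2.1572e-16
344,5.8638e-16
346,1.5939e-15
348,4.3328e-15
350,1.1778e-14
352,3.2015e-14
354,8.7026e-14
356,2.3656e-13
358,6.4304e-13
360,1.748e-12
362,4.7515e-12
364,1.2916e-11
366,3.5109e-11
368,9.5435e-11
370,2.5942e-10
372,7.0518e-10
374,1.9169e-09
376,5.2106e-09
378,1.4164e-08
380,3.8501e-08
382,1.0466e-07
384,2.8449e-07
386,7.7332e-07
388,2.1021e-06
390,5.7141e-06
392,1.5532e-05
394,4.222e-05
396,0.00011476
398,0.00031188
400,0.00084728
402,0.0022995
404,0.0062244
406,0.016727
408,0.044106
410,0.11086
412,0.25012
414,0.465
416,0.67988
418,0.81914
420,0.88589
422,0.91327
424,0.92377
426,0.92769
428,0.92914
430,0.92965
432,0.92977
434,0.92965
436,0.92914
438,0.92769
440,0.92377
442,0.91327
444,0.88589
446,0.81914
448,0.67988
450,0.465
452,0.25012
454,0.11086
456,0.044106
458,0.016727
460,0.0062244
462,0.0022995
464,0.00084729
466,0.0003119
468,0.00011482
470,4.2393e-05
472,1.6001e-05
474,6.9891e-06
476,5.5679e-06
478,1.0194e-05
480,2.5893e-05
482,6.9712e-05
484,0.00018923
486,0.0005141
488,0.0013961
490,0.0037852
492,0.010218
494,0.02726
496,0.070548
498,0.16966
500,0.35111
502,0.57889
504,0.76034
506,0.85944
508,0.90271
510,0.91971
512,0.92603
514,0.92809
516,0.92809
518,0.92603
520,0.91971
522,0.90271
524,0.85944
526,0.76034
528,0.57889
530,0.35111
532,0.16966
534,0.070548
536,0.02726
538,0.010218
540,0.0037852
542,0.0013961
544,0.0005141
546,0.00018923
548,6.9712e-05
550,2.5893e-05
552,1.0194e-05
554,5.5679e-06
556,6.9891e-06
558,1.6001e-05
560,4.2393e-05
562,0.00011482
564,0.0003119
566,0.00084729
568,0.0022995
570,0.0062244
572,0.016727
574,0.044106
576,0.11086
578,0.25012
580,0.465
582,0.67988
584,0.81914
586,0.88589
588,0.91326
590,0.92373
592,0.92759
594,0.92884
596,0.92884
598,0.92759
600,0.92373
602,0.91326
604,0.88589
606,0.81914
608,0.67988
610,0.465
612,0.25012
614,0.11086
616,0.044106
618,0.016727
620,0.0062244
622,0.0022995
624,0.00084729
626,0.0003119
628,0.00011482
630,4.2393e-05
632,1.6001e-05
634,6.9891e-06
636,5.5679e-06
638,1.0194e-05
640,2.5893e-05
642,6.9712e-05
644,0.00018923
646,0.0005141
648,0.0013961
650,0.0037852
652,0.010218
654,0.02726
656,0.070548
658,0.16966
660,0.35111
662,0.57889
664,0.76034
666,0.85945
668,0.90274
670,0.91978
672,0.92621
674,0.9286
676,0.92948
678,0.9298
680,0.9299
682,0.9299
684,0.9298
686,0.92948
688,0.9286
690,0.92621
692,0.91978
694,0.90274
696,0.85945
698,0.76034
700,0.57889
702,0.35111
704,0.16966
706,0.070548
708,0.02726
710,0.010218
712,0.0037852
714,0.0013961
716,0.00051408
718,0.00018919
720,6.9607e-05
722,2.5608e-05
724,9.421e-06
726,3.4662e-06
728,1.2762e-06
730,4.722e-07
732,1.8114e-07
734,8.683e-08
736,8.683e-08
738,1.8114e-07
740,4.722e-07
742,1.2762e-06
744,3.4662e-06
746,9.421e-06
748,2.5608e-05
750,6.9607e-05
752,0.00018919
754,0.00051408
756,0.0013961
758,0.0037852
760,0.010218
762,0.02726
764,0.070548
766,0.16966
768,0.35111
770,0.57889
772,0.76034
774,0.85945
776,0.90274
778,0.91978
780,0.92621
782,0.9286
784,0.92949
786,0.92981
788,0.92993
790,0.92997
792,0.92999
794,0.93
796,0.93
798,0.93
800,0.93
802,0.93
804,0.93
806,0.93
808,0.93
810,0.93
812,0.93
814,0.93
816,0.93
818,0.93
820,0.93
822,0.93
824,0.93
826,0.92999
828,0.92997
830,0.92993
832,0.92981
834,0.92949
836,0.9286
838,0.92621
840,0.91978
842,0.90274
844,0.85945
846,0.76034
848,0.57889
850,0.35111
852,0.16966
854,0.070548
856,0.02726
858,0.010218
860,0.0037852
862,0.0013961
864,0.00051408
866,0.00018919
868,6.9607e-05
870,2.5608e-05
872,9.4209e-06
874,3.4658e-06
876,1.275e-06
878,4.6904e-07
880,1.7255e-07
882,6.3478e-08
884,2.3352e-08
886,8.5908e-09
888,3.1604e-09
890,1.1626e-09
892,4.2771e-10
894,1.5735e-10
896,5.7885e-11
898,2.1295e-11
900,7.8338e-12
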