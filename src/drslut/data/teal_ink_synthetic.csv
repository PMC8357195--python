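wavelength_nm,mua_stock
450.0,3.708376
451.0,3.708872
452.0,3.709417
453.0,3.710016
454.0,3.710674
455.0,3.711397
456.0,3.712189
457.0,3.713058
458.0,3.714011
459.0,3.715054
460.0,3.716195
461.0,3.717444
462.0,3.718809
463.0,3.7203
464.0,3.721929
465.0,3.723707
466.0,3.725645
467.0,3.727758
468.0,3.73006
469.0,3.732566
470.0,3.735293
471.0,3.738258
472.0,3.741481
473.0,3.744981
474.0,3.748781
475.0,3.752903
476.0,3.757372
477.0,3.762214
478.0,3.767458
479.0,3.773134
480.0,3.779272
481.0,3.785908
482.0,3.793077
483.0,3.800816
484.0,3.809168
485.0,3.818174
486.0,3.82788
487.0,3.838335
488.0,3.849588
489.0,3.861695
490.0,3.874711
491.0,3.888697
492.0,3.903715
493.0,3.919832
494.0,3.937119
495.0,3.955648
496.0,3.975496
497.0,3.996746
498.0,4.019482
499.0,4.043792
500.0,4.069771
501.0,4.097515
502.0,4.127127
503.0,4.158713
504.0,4.192383
505.0,4.228253
506.0,4.266443
507.0,4.307079
508.0,4.35029
509.0,4.39621
510.0,4.44498
511.0,4.496743
512.0,4.55165
513.0,4.609855
514.0,4.671517
515.0,4.736802
516.0,4.805877
517.0,4.878918
518.0,4.956104
519.0,5.037618
520.0,5.123648
521.0,5.214387
522.0,5.310032
523.0,5.410783
524.0,5.516847
525.0,5.628431
526.0,5.745747
527.0,5.86901
528.0,5.998439
529.0,6.134254
530.0,6.276677
531.0,6.425932
532.0,6.582246
533.0,6.745846
534.0,6.916958
535.0,7.095809
536.0,7.282627
537.0,7.477636
538.0,7.681061
539.0,7.893122
540.0,8.11404
541.0,8.344028
542.0,8.583297
543.0,8.832055
544.0,9.0905
545.0,9.358827
546.0,9.637223
547.0,9.925866
548.0,10.224927
549.0,10.534566
550.0,10.854932
551.0,11.186166
552.0,11.528394
553.0,11.88173
554.0,12.246274
555.0,12.622112
556.0,13.009314
557.0,13.407935
558.0,13.81801
559.0,14.239559
560.0,14.672581
561.0,15.117059
562.0,15.572952
563.0,16.040199
564.0,16.518719
565.0,17.008406
566.0,17.509133
567.0,18.02075
568.0,18.54308
569.0,19.075923
570.0,19.619056
571.0,20.172227
572.0,20.735159
573.0,21.307552
574.0,21.889075
575.0,22.479375
576.0,23.07807
577.0,23.684751
578.0,24.298985
579.0,24.92031
580.0,25.54824
581.0,26.182264
582.0,26.821842
583.0,27.466413
584.0,28.11539
585.0,28.768162
586.0,29.424097
587.0,30.082538
588.0,30.74281
589.0,31.404214
590.0,32.066037
591.0,32.727543
592.0,33.387981
593.0,34.046586
594.0,34.702577
595.0,35.355161
596.0,36.003534
597.0,36.646881
598.0,37.284382
599.0,37.915208
600.0,38.538526
601.0,39.1535
602.0,39.759296
603.0,40.355075
604.0,40.940007
605.0,41.513263
606.0,42.074021
607.0,42.62147
608.0,43.154805
609.0,43.673238
610.0,44.175993
611.0,44.66231
612.0,45.13145
613.0,45.58269
614.0,46.015333
615.0,46.428702
616.0,46.822148
617.0,47.195049
618.0,47.546811
619.0,47.876871
620.0,48.184696
621.0,48.46979
622.0,48.731689
623.0,48.969965
624.0,49.184228
625.0,49.374125
626.0,49.539344
627.0,49.679612
628.0,49.794695
629.0,49.884404
630.0,49.948588
631.0,49.987142
632.0,50.0
633.0,49.987142
634.0,49.948588
635.0,49.884404
636.0,49.794695
637.0,49.679612
638.0,49.539344
639.0,49.374125
640.0,49.184228
641.0,48.969965
642.0,48.731689
643.0,48.46979
644.0,48.184696
645.0,47.876871
646.0,47.546811
647.0,47.195049
648.0,46.822148
649.0,46.428702
650.0,46.015333
651.0,45.58269
652.0,45.13145
653.0,44.66231
654.0,44.175993
655.0,43.673238
656.0,43.154805
657.0,42.62147
658.0,42.074021
659.0,41.513263
660.0,40.940007
661.0,40.355075
662.0,39.759296
663.0,39.1535
664.0,38.538526
665.0,37.915208
666.0,37.284382
667.0,36.646881
668.0,36.003534
669.0,35.355161
670.0,34.702577
671.0,34.046586
672.0,33.387981
673.0,32.727543
674.0,32.066037
675.0,31.404214
676.0,30.74281
677.0,30.082538
678.0,29.424097
679.0,28.768162
680.0,28.11539
681.0,27.466413
682.0,26.821842
683.0,26.182264
684.0,25.54824
685.0,24.92031
686.0,24.298985
687.0,23.684751
688.0,23.07807
689.0,22.479375
690.0,21.889075
691.0,21.307552
692.0,20.735159
693.0,20.172227
694.0,19.619056
695.0,19.075923
696.0,18.54308
697.0,18.02075
698.0,17.509133
699.0,17.008406
700.0,16.518719
701.0,16.040199
702.0,15.572952
703.0,15.117059
704.0,14.672581
705.0,14.239559
706.0,13.81801
707.0,13.407935
708.0,13.009314
709.0,12.622112
710.0,12.246274
711.0,11.88173
712.0,11.528394
713.0,11.186166
714.0,10.854932
715.0,10.534566
716.0,10.224927
717.0,9.925866
718.0,9.637223
719.0,9.358827
720.0,9.0905
721.0,8.832055
722.0,8.583297
723.0,8.344028
724.0,8.11404
725.0,7.893122
726.0,7.681061
727.0,7.477636
728.0,7.282627
729.0,7.095809
730.0,6.916958
731.0,6.745846
732.0,6.582246
733.0,6.425932
734.0,6.276677
735.0,6.134254
736.0,5.998439
737.0,5.86901
738.0,5.745747
739.0,5.628431
740.0,5.516847
741.0,5.410783
742.0,5.310032
743.0,5.214387
744.0,5.123648
745.0,5.037618
746.0,4.956104
747.0,4.878918
748.0,4.805877
749.0,4.736802
750.0,4.671517
751.0,4.609855
752.0,4.55165
753.0,4.496743
754.0,4.44498
755.0,4.39621
756.0,4.35029
757.0,4.307079
758.0,4.266443
759.0,4.228253
760.0,4.192383
761.0,4.158713
762.0,4.127127
763.0,4.097515
764.0,4.069771
765.0,4.043792
766.0,4.019482
767.0,3.996746
768.0,3.975496
769.0,3.955648
770.0,3.937119
771.0,3.919832
772.0,3.903715
773.0,3.888697
774.0,3.874711
775.0,3.861695
776.0,3.849588
777.0,3.838335
778.0,3.82788
779.0,3.818174
780.0,3.809168
781.0,3.800816
782.0,3.793077
783.0,3.785908
784.0,3.779272
785.0,3.773134
786.0,3.767458
787.0,3.762214
788.0,3.757372
789.0,3.752903
790.0,3.748781
791.0,3.744981
792.0,3.741481
793.0,3.738258
794.0,3.735293
795.0,3.732566
796.0,3.73006
797.0,3.727758
798.0,3.725645
799.0,3.723707
800.0,3.721929
801.0,3.7203
802.0,3.718809
803.0,3.717444
804.0,3.716195
805.0,3.715054
806.0,3.714011
807.0,3.713058
808.0,3.712189
809.0,3.711397
810.0,3.710674
811.0,3.710016
812.0,3.709417
813.0,3.708872
814.0,3.708376
815.0,3.707926
816.0,3.707517
817.0,3.707145
818.0,3.706808
819.0,3.706503
820.0,3.706226
821.0,3.705975
822.0,3.705748
823.0,3.705543
824.0,3.705357
825.0,3.705189
826.0,3.705038
827.0,3.704901
828.0,3.704778
829.0,3.704667
830.0,3.704567
831.0,3.704477
832.0,3.704396
833.0,3.704323
834.0,3.704257
835.0,3.704198
836.0,3.704145
837.0,3.704098
838.0,3.704055
839.0,3.704017
840.0,3.703983
841.0,3.703953
842.0,3.703925
843.0,3.703901
844.0,3.703879
845.0,3.703859
846.0,3.703842
847.0,3.703826
848.0,3.703813
849.0,3.7038
850.0,3.703789
851.0,3.70378
852.0,3.703771
853.0,3.703763
854.0,3.703756
855.0,3.70375
856.0,3.703745
857.0,3.70374
858.0,3.703736
859.0,3.703732
860.0,3.703728
861.0,3.703726
862.0,3.703723
863.0,3.703721
864.0,3.703719
865.0,3.703717
866.0,3.703715
867.0,3.703714
868.0,3.703713
869.0,3.703711
870.0,3.70371
871.0,3.70371
872.0,3.703709
873.0,3.703708
874.0,3.703708
875.0,3.703707
876.0,3.703707
877.0,3.703706
878.0,3.703706
879.0,3.703706
880.0,3.703705
881.0,3.703705
882.0,3.703705
883.0,3.703705
884.0,3.703705
885.0,3.703705
886.0,3.703704
887.0,3.703704
888.0,3.703704
889.0,3.703704
890.0,3.703704
891.0,3.703704
892.0,3.703704
893.0,3.703704
894.0,3.703704
895.0,3.703704
896.0,3.703704
897.0,3.703704
898.0,3.703704
899.0,3.703704
900.0,3.703704
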