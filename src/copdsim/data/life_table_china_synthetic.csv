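sex,age,annual_mortality_probability
male,35,0.001333
male,36,0.001456
male,37,0.001590
male,38,0.001736
male,39,0.001895
male,40,0.002069
male,41,0.002260
male,42,0.002467
male,43,0.002694
male,44,0.002941
male,45,0.003211
male,46,0.003506
male,47,0.003828
male,48,0.004180
male,49,0.004563
male,50,0.004982
male,51,0.005439
male,52,0.005938
male,53,0.006482
male,54,0.007076
male,55,0.007725
male,56,0.008432
male,57,0.009205
male,58,0.010047
male,59,0.010966
male,60,0.011969
male,61,0.013063
male,62,0.014256
male,63,0.015557
male,64,0.016976
male,65,0.018523
male,66,0.020209
male,67,0.022047
male,68,0.024051
male,69,0.026234
male,70,0.028613
male,71,0.031203
male,72,0.034024
male,73,0.037095
male,74,0.040437
male,75,0.044074
male,76,0.048029
male,77,0.052330
male,78,0.057004
male,79,0.062082
male,80,0.067595
male,81,0.073579
male,82,0.080069
male,83,0.087104
male,84,0.094725
male,85,0.102974
male,86,0.111897
male,87,0.121539
male,88,0.131948
male,89,0.143174
male,90,0.155266
male,91,0.168277
male,92,0.182255
male,93,0.197251
male,94,0.213313
male,95,0.230485
male,96,0.248809
male,97,0.268320
male,98,0.289048
male,99,0.311013
male,100,0.334223
female,35,0.000653
female,36,0.000717
female,37,0.000787
female,38,0.000865
female,39,0.000950
female,40,0.001044
female,41,0.001147
female,42,0.001260
female,43,0.001384
female,44,0.001520
female,45,0.001670
female,46,0.001834
female,47,0.002015
female,48,0.002213
female,49,0.002431
female,50,0.002670
female,51,0.002933
female,52,0.003222
female,53,0.003538
female,54,0.003887
female,55,0.004269
female,56,0.004689
female,57,0.005149
female,58,0.005656
female,59,0.006211
female,60,0.006821
female,61,0.007491
female,62,0.008226
female,63,0.009033
female,64,0.009919
female,65,0.010892
female,66,0.011959
female,67,0.013130
female,68,0.014414
female,69,0.015824
female,70,0.017370
female,71,0.019065
female,72,0.020924
female,73,0.022963
female,74,0.025197
female,75,0.027646
female,76,0.030329
female,77,0.033268
female,78,0.036486
female,79,0.040010
female,80,0.043865
female,81,0.048083
female,82,0.052695
female,83,0.057736
female,84,0.063243
female,85,0.069255
female,86,0.075816
female,87,0.082970
female,88,0.090765
female,89,0.099252
female,90,0.108484
female,91,0.118517
female,92,0.129409
female,93,0.141219
female,94,0.154009
female,95,0.167840
female,96,0.182773
female,97,0.198870
female,98,0.216188
female,99,0.234781
female,100,0.254699
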