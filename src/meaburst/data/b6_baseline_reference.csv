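electrode,source,n_bursts,mean_duration_s,mean_spikes_per_burst,mean_burst_isi_s
B6_11,r_pipeline,141,0.154547,26.049645,0.007170579
B6_11,axion,141,0.154627,26.049645,0.007177
B6_12,r_pipeline,70,0.1212651,11.2,0.012609743
B6_12,axion,70,0.121345,11.2,0.012619
B6_13,r_pipeline,1,0.09216,17,0.00576
B6_13,axion,1,0.09224,17,0.005765
B6_14,r_pipeline,189,0.1930743,41.910053,0.004879648
B6_14,axion,189,0.193154,41.910053,0.004884
B6_21,r_pipeline,1,0.08424,22,0.004011429
B6_21,axion,1,0.08432,22,0.004015
B6_22,r_pipeline,46,0.1168209,7.173913,0.018208933
B6_22,axion,46,0.116901,7.173913,0.018223
B6_23,r_pipeline,181,0.1468888,26.524862,0.006349683
B6_23,axion,181,0.147533,26.541436,0.00637
B6_24,r_pipeline,17,0.1649647,7.529412,0.028800437
B6_24,axion,17,0.165045,7.529412,0.028814
B6_31,r_pipeline,1,0.08328,22,0.003965714
B6_31,axion,1,0.08336,22,0.00397
B6_32,r_pipeline,1,0.11192,24,0.004866087
B6_32,axion,1,0.112,24,0.00487
B6_33,r_pipeline,201,0.1455781,30.427861,0.005327455
B6_33,axion,201,0.145659,30.427861,0.005334
B6_34,r_pipeline,185,0.1440069,26.313514,0.006119163
B6_34,axion,185,0.144087,26.313514,0.006126
B6_41,r_pipeline,1,0.1028,19,0.005711111
B6_41,axion,1,0.10288,19,0.005716
B6_42,r_pipeline,4,0.09752,9.75,0.018117636
B6_42,axion,4,0.0976,9.75,0.018133
B6_43,r_pipeline,87,0.1481968,11.298851,0.014456641
B6_43,axion,87,0.148277,11.298851,0.014467
B6_44,r_pipeline,211,0.1491685,29.753555,0.005202875
B6_44,axion,211,0.149249,29.753555,0.005208
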