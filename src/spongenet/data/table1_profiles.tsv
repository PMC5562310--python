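group	mirna	mean	sd
sepsis	miR-146	0.4956	1.2388
sepsis	miR-150	0.14136	0.6691
sepsis	miR-155	0.03478	0.1839
sepsis	miR-486	0.66113	1.44524
sepsis	miR-16	11.5914	28.3203
sepsis	miR-21	0.48337	0.93555
sepsis	miR-29a	0.13165	0.27103
sepsis	miR-182	0.00421	0.0085
sepsis	miR-223	2.95182	6.31515
sepsis	miR-23	0.01366	0.03249
sepsis	miR-26a	1.41987	3.39754
sepsis	miR-26b	0.9474	2.24152
sepsis	miR-93	0.62634	1.20462
sepsis	miR-342	0.04754	0.09653
sepsis	KSHV-miR-k12-10b	0.00898	0.01759
sepsis	KSHV-miR-k12-12*	0.00105	0.00237
control	miR-146	0.4045	0.5935
control	miR-150	0.03767	0.03843
control	miR-155	0.009113	0.01409
control	miR-486	0.3059	0.2537
control	miR-16	3.350	3.300
control	miR-21	0.1780	0.2058
control	miR-29a	0.01086	0.008120
control	miR-182	0.001466	0.002985
control	miR-223	1.267	2.284
control	miR-23	0.004970	0.007263
control	miR-26a	0.6085	0.9975
control	miR-26b	0.2568	0.3975
control	miR-93	0.1770	0.1930
control	miR-342	0.02378	0.03320
control	KSHV-miR-k12-10b	0.0001075	0.0001311
control	KSHV-miR-k12-12*	0.0000073	0.0001190
pre_surgery	miR-146	0.03176	0.03171
pre_surgery	miR-150	0.01693	0.006835
pre_surgery	miR-155	0.0004117	0.0002813
pre_surgery	miR-486	0.09814	0.1091
pre_surgery	miR-16	0.7989	0.9298
pre_surgery	miR-21	0.02005	0.01575
pre_surgery	miR-29a	0.6451	0.4109
pre_surgery	miR-182	0.0000032	0.0000026
pre_surgery	miR-223	0.1020	0.1733
pre_surgery	miR-23	0.0001189	0.0001869
pre_surgery	miR-26a	0.006481	0.006750
pre_surgery	miR-26b	0.006006	0.006811
pre_surgery	miR-93	0.02736	0.02943
pre_surgery	miR-342	0.0006272	0.0004870
pre_surgery	KSHV-miR-k12-10b	0.0001944	0.0001925
pre_surgery	KSHV-miR-k12-12*	0.0000036	0.0000032
post_surgery	miR-146	0.01627	0.009304
post_surgery	miR-150	0.01382	0.007288
post_surgery	miR-155	0.00153	0.004051
post_surgery	miR-486	0.1002	0.1371
post_surgery	miR-16	0.7834	1.404
post_surgery	miR-21	0.01652	0.01209
post_surgery	miR-29a	0.6485	0.2313
post_surgery	miR-182	0.0000017	0.0000017
post_surgery	miR-223	0.05056	0.04559
post_surgery	miR-23	0.0000065	0.0000087
post_surgery	miR-26a	0.005517	0.003665
post_surgery	miR-26b	0.005034	0.005601
post_surgery	miR-93	0.02156	0.03142
post_surgery	miR-342	0.0004092	0.0003300
post_surgery	KSHV-miR-k12-10b	0.000235	0.0002743
post_surgery	KSHV-miR-k12-12*	0.0000051	0.0000044
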