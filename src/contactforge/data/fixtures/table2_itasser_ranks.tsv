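protein	cd	any_heavy	cbeta	centroid
1abv_	100	221	366	320
1af7__	13	492	101	101
1ah9_	392	450	212	152
1aoy_	147	397	474	445
1b4bA	3	322	52	6
1b72A	392	486	512	534
1bm8_	3	208	10	40
1bq9A	8	389	298	7
1cewI	137	438	359	243
1cqkA	2	282	23	76
1csp_	220	305	195	255
1cy5A	48	274	227	249
1dcjA_	72	2	289	69
1di2A_	226	17	225	198
1dtjA_	18	284	90	282
1egxA	83	156	20	13
1fadA	95	391	337	430
1fo5A	145	289	235	334
1g1cA	32	290	135	35
1gjxA	32	474	283	256
1gnuA	10	467	441	238
1gpt_	56	383	316	343
1gyvA	12	229	5	60
1hbkA	172	265	234	178
1itpA	376	473	445	250
1jnuA	6	236	11	161
1kjs_	240	270	176	339
1kviA	455	475	298	540
1mkyA3	87	267	234	151
1mla_2	17	103	194	125
1mn8A	196	392	373	503
1n0uA4	171	269	266	277
1ne3A	76	498	537	503
1no5A	2	36	2	84
1npsA	214	385	363	365
1o2fB_	4	248	246	19
1of9A	1	507	432	31
1ogwA_	240	333	243	192
1orgA	3	65	4	1
1pgx_	379	157	452	349
1r69_	17	2	208	110
1sfp_	61	309	7	211
1shfA	67	502	335	362
1sro_	85	476	6	86
1ten_	11	258	256	219
1tfi_	264	234	94	103
1thx_	4	228	40	6
1tif_	12	422	367	486
1tig_	201	478	466	397
1vcc_	9	550	414	398
256bA	335	445	336	335
2a0b_	219	234	221	218
2cr7A	102	257	101	101
2f3nA	274	455	442	274
2pcy_	249	324	249	354
2reb_2	45	91	309	337
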