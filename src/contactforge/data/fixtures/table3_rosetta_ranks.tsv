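protein	cd	any_heavy	cbeta	centroid
1a19	8	26	14	22
1a32	50	101	92	27
1a68	63	101	35	12
1acf	1	35	10	10
1ail	4	20	3	16
1aiu	61	101	67	64
1b3a	16	80	48	38
1bgf	35	76	15	11
1bk2	13	74	13	3
1bkr	8	39	12	1
1bm8	1	34	10	1
1bq9	18	37	10	9
1c8c	15	49	34	13
1c9o	53	99	36	45
1cc8	29	35	8	17
1cei	40	12	17	5
1cg5	29	59	6	15
1ctf	53	1	14	4
1dhn	1	54	6	1
1e6i	7	96	1	17
1elw	16	1	70	87
1enh	67	93	51	62
1ew4	1	22	2	4
1eyv	2	17	10	9
1fkb	1	14	4	1
1fna	19	33	27	14
1gvp	6	76	41	15
1hz6	16	32	10	11
1ig5	21	27	1	90
1iib	23	94	27	14
1kpe	13	48	10	1
1lis	63	100	15	14
1lou	12	87	27	32
1nps	4	12	11	17
1opd	2	6	6	22
1pgx	5	1	69	19
1ptq	7	101	60	10
1r69	38	1	54	37
1rnb	1	18	1	22
1scj	35	30	59	20
1shf	25	68	22	38
1ten	1	1	1	1
1tig	5	48	2	25
1tul	7	14	10	1
1ubi	61	84	48	41
1ugh	4	46	33	57
1urn	2	50	20	2
1utg	100	101	101	100
1vcc	6	94	20	9
1vie	25	40	36	62
1vls	65	62	13	60
1who	1	10	1	1
256b	62	1	28	76
2acy	1	13	1	5
2chf	23	87	36	72
2ci2	8	100	37	73
2tif	1	1	1	1
4ubp	1	33	1	1
5cro	74	55	43	13
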