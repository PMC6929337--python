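pdb	length	best	spicker_original	spicker_reranked	calibur_original	calibur_reranked	durandal_original	durandal_reranked
1abv_	103	4.81	13.93	8.08	13.17	13.17	13.57	12.31
1af7__	72	2.92	5.73	5.73	4.45	4.45	10.28	3.99
1ah9_	63	1.88	4.66	4.66	3.31	2.81	3.02	3.02
1b4bA	71	4.20	7.18	5.08	5.57	5.57	5.54	5.54
1b72A	49	2.36	4.07	5.08	3.23	3.73	3.23	3.23
1bm8_	99	6.67	7.18	7.18	7.07	7.07	7.48	7.48
1bq9A	53	3.98	7.39	5.04	8.18	6.42	8.36	8.36
1cewI	108	3.20	3.92	3.92	12.49	4.28	3.75	3.75
1cqkA	101	1.40	2.78	2.78	1.69	1.95	2.37	2.37
1dcjA_	73	9.31	11.66	10.45	12.18	11.66	11.97	9.96
1di2A_	69	1.32	2.49	2.49	2.62	2.19	2.49	2.49
1dtjA_	74	1.58	2.54	3.22	2.83	1.88	1.88	1.88
1egxA	115	1.93	2.31	2.31	2.59	2.95	2.59	2.59
1g1cA	98	2.16	2.97	2.97	2.65	2.59	2.49	2.49
1gjxA	77	5.01	7.30	5.58	14.09	13.23	8.09	8.09
1gnuA	117	4.06	7.09	6.78	9.15	7.74	9.54	9.54
1gpt_	47	2.79	5.52	5.53	6.29	4.64	3.68	3.68
1gyvA	117	2.69	3.78	3.78	3.41	3.63	3.39	3.39
1hbkA	89	2.69	3.57	3.57	3.48	3.52	3.48	3.48
1itpA	68	4.10	11.23	8.04	10.92	8.07	11.48	11.48
1jnuA	104	2.30	3.45	3.45	2.68	3.21	2.76	2.76
1kjs_	74	4.65	8.67	5.88	8.44	5.89	8.75	5.92
1mkyA3	81	3.68	5.16	5.16	5.54	5.33	5.49	5.49
1mla_2	70	2.04	3.18	3.18	2.82	2.98	3.38	3.38
1mn8A	84	5.14	6.69	6.69	7.45	7.45	10.38	10.38
1n0uA4	69	3.14	4.59	4.59	4.62	4.37	4.28	4.28
1ne3A	56	3.16	5.12	6.63	6.09	4.05	5.96	5.96
1no5A	93	6.12	10.82	10.56	10.69	10.54	11	11
1npsA	88	1.81	3.07	3.07	2.28	2.74	6.07	8.29
1o2fB_	77	4.08	7.41	7.12	9.03	6.80	3.91	3.91
1ogwA_	77	0.96	1.81	1.81	1.29	1.34	2.43	3.00
1pgx_	59	2.79	3.42	3.42	3.26	4.19	3.26	3.26
1r69_	61	1.30	2.28	2.28	1.97	2.14	1.99	1.99
1shfA	59	1.18	2.86	2.86	1.49	2.75	1.29	1.29
1sro_	71	2.59	3.54	3.00	3.54	3.89	3.54	3.54
1tfi_	47	2.49	4.61	5.72	5.08	5.08	4.48	4.48
1thx_	108	1.71	2.67	2.67	2.26	2.27	2.10	2.10
1tif_	59	6.47	7.45	7.45	7.57	7.57	7.62	9.44
1tig_	88	3.00	9.12	6.11	3.58	3.58	4.25	4.25
1vcc_	76	4.52	6.53	6.53	8.13	6.43	7.46	7.46
256bA	106	2.75	3.20	3.20	5.93	6.23	3.73	2.78
2pcy_	99	3.87	5.46	5.46	1.94	2.12	4.71	4.71
2a0b_	118	2.05	2.20	2.20	3.48	2.98	2.75	2.75
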