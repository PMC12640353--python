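breed	region	n_farms_2024	delta_farms	pct_farms	n_animals_2024	delta_animals	pct_animals	growth_rate	ne	delta_f_pct	risk	recognized_after_2010
Bergamasca	North-western	70	-15	-17.6	17063	1083	6.8	1.09	579	0.09	NR	0
Biellese	North-western	16	-14	-46.7	306	-1402	-82.1	0.91	68	0.74	C	0
Brianzola	North-western	25	-12	-32.4	1518	471	45	1.04	353	0.14	E	0
Brigasca	North-western	8	-7	-46.7	1179	37	3.2	1.1	113	0.44	E	0
Delle Langhe	North-western	27	-58	-68.2	1840	-1190	-39.3	0.97	225	0.22	E	0
Frabosana	North-western	43	-17	-28.3	4267	1846	76.2	1.05	560	0.09	V	0
Garessina	North-western	0	-3	-100	0	-92	-100	0.92	0	NA	Ex	0
Pecora Ciuta	North-western	19	18	1800	545	544	54400	2.42	264	0.19	E	1
Pecora di Corteno	North-western	12	-2	-14.3	326	101	44.9	1.04	106	0.47	C	0
Rosset	North-western	40	-7	-14.9	214	124	137.8	1.61	210	0.24	C	0
Saltasassi	North-western	0	-2	-100	0	-24	-100	1.05	0	NA	Ex	0
Sambucana	North-western	56	3	5.7	3445	1871	118.9	1.06	523	0.1	V	0
Savoiarda	North-western	8	2	33.3	263	182	224.7	1.1	67	0.75	C	0
Tacola	North-western	107	58	118.4	13720	10765	364.3	1.13	2182	0.02	NR	0
Alpagota	North-eastern	42	-9	-17.6	1459	209	16.7	1.02	345	0.15	E	0
Brogne	North-eastern	32	7	28	1220	204	20.1	1.03	426	0.12	E	0
Cornella Bianca	North-eastern	8	3	60	299	192	179.4	1.19	95	0.53	C	0
Corniglio	North-eastern	13	-3	-18.8	1297	590	83.5	1.05	413	0.12	E	0
Istriana-Carsolina	North-eastern	6	0	0	423	-8	-1.9	1.01	69	0.73	E	0
Juraschaf-Giurassica	North-eastern	26	-16	-38.1	5	-267	-98.2	0.85	0	NA	Ex	0
Lamon	North-eastern	19	10	111.1	257	143	125.4	1.11	127	0.39	C	0
Plezzana	North-eastern	3	-1	-25	336	242	257.4	1.11	135	0.37	C	0
Schnalserschaf	North-eastern	27	-9	-25	35	-315	-90	0.89	0	NA	Ex	0
Schwarz Braunes Bergschaf	North-eastern	51	-129	-71.7	36	-1725	-98	1.13	11	4.55	C	0
Schwarznasenschaf	North-eastern	31	27	675	282	269	2069.2	1.4	206	0.24	C	0
Tiroler Bergschaf	North-eastern	83	-324	-79.6	33	-4813	-99.3	0.71	8	6.65	C	0
Tiroler Steinschaf	North-eastern	3	2	200	0	-6	-100	1.34	0	NA	Ex	1
Vicentina-Foza	North-eastern	14	11	366.7	186	88	89.8	1.05	128	0.39	C	0
Villnoesser Schaf-Fiemmese	North-eastern	67	-45	-40.2	579	-639	-52.5	0.97	142	0.35	E	0
Appenninica	Central	113	-27	-19.3	5147	-4390	-46	0.96	969	0.05	V	0
Dell'Amiata	Central	46	42	1050	3061	2983	3824.4	1.72	476	0.11	E	0
Fabrianese	Central	29	-25	-46.3	1525	-1754	-53.5	0.95	317	0.16	E	0
Garfagnina Bianca	Central	29	16	123.1	1391	1168	523.8	1.18	182	0.28	E	0
Massese	Central	65	-9	-12.2	6121	-3108	-33.7	0.98	778	0.06	V	0
Merinizzata Italiana	Central	113	-79	-41.1	7821	-19187	-71	0.92	1424	0.04	NR	0
Nostrana	Central	0	-1	-100	0	-1	-100	1	0	NA	Ex	1
Pomarancina	Central	31	4	14.8	1334	654	96.2	1.06	236	0.21	E	0
Quadricorna	Central	2	0	0	52	0	0	NA	50	1	C	1
Sopravissana	Central	60	10	20	5449	-245	-4.3	1	797	0.06	V	0
Altamurana	Southern	6	1	20	317	-74	-18.9	1.01	149	0.34	C	0
Bagnolese	Southern	144	30	26.3	12983	1404	12.1	1.02	2059	0.02	NR	0
Di Benevento-Quadrella	Southern	1	0	0	10	0	0	1.03	4	13.89	C	1
Gentile di Puglia	Southern	40	11	37.9	3999	244	6.5	1.02	983	0.05	V	0
Laticauda	Southern	68	9	15.3	2955	-58	-1.9	1	562	0.09	E	0
Moscia Leccese	Southern	21	5	31.2	690	-751	-52.1	0.96	115	0.44	E	0
Trimeticcia di Segezia	Southern	1	0	0	18	18	Inf	0.94	10	5	C	1
Sciara-Moscia Calabrese	Southern	1	0	0	10	9	900	1.36	6	7.81	C	0
Turchessa	Southern	10	6	150	2222	2156	3266.7	1.34	275	0.18	E	0
Zerasca	Southern	17	-11	-39.3	851	181	27	1.21	156	0.32	E	0
Barbaresca	Isles	18	-12	-40	594	-1270	-68.1	0.94	280	0.18	E	0
Comisana	Isles	31	-550	-94.7	1755	-50174	-96.6	0.79	345	0.14	E	0
Nera di Arbus	Isles	88	29	49.2	7141	4764	200.4	1.09	1013	0.05	NR	0
Noticiana	Isles	1	0	0	312	310	15500	1.99	35	1.43	E	0
Pinzirita	Isles	8	-253	-96.9	0	-24280	-100	0.6	0	NA	Ex	0
Sarda	Isles	452	-831	-64.8	119614	-314165	-72.4	0.92	25739	0	NR	0
Valle del Belice	Isles	180	-1027	-85.1	15036	-191182	-92.7	1.09	20	2.5	C	0
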