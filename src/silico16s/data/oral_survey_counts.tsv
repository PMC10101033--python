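domain	pair_id	detected_genomes	detected_species	ma_species	total_genomes	total_species
bacteria	KP_F048-OP_R043	508	180	22	518	186
bacteria	OP_F098-OP_R119	493	177	28	518	186
bacteria	OP_F066-KP_R040	455	165	77	518	186
bacteria	OP_F009-OP_R030	504	181	29	518	186
bacteria	KP_F061-KP_R074	468	169	39	518	186
bacteria	OP_F101-OP_R030	460	167	39	518	186
bacteria	OP_F053-KP_R020	506	179	6	518	186
bacteria	KP_F048-KP_R031	507	180	9	518	186
bacteria	KP_F048-OP_R073	498	178	6	518	186
bacteria	KP_F051-KP_R041	456	166	20	518	186
bacteria	KP_F051-OP_R030	508	184	19	518	186
bacteria	OP_F116-KP_R060	516	185	31	518	186
bacteria	KP_F048-OP_R030	507	180	6	518	186
bacteria	KP_F048-KP_R060	507	180	6	518	186
bacteria	KP_F056-KP_R077	495	180	10	518	186
bacteria	OP_F114-KP_R002	485	172	22	518	186
bacteria	KP_F020-KP_R032	488	176	28	518	186
bacteria	OP_F066-OP_R073	502	182	85	518	186
bacteria	OP_F114-KP_R031	507	180	9	518	186
bacteria	OP_F114-OP_R073	498	178	6	518	186
bacteria	KP_F020-OP_R073	488	176	22	518	186
bacteria	OP_F114-OP_R121	507	180	6	518	186
bacteria	KP_F020-OP_R121	489	177	10	518	186
bacteria	OP_F066-OP_R121	516	185	16	518	186
bacteria	KP_F078-OP_R010	488	176	28	518	186
bacteria	KP_F031-KP_R021	347	138	2	518	186
bacteria	KP_F047-KP_R035	500	177	9	518	186
bacteria	OP_F009-OP_R029	469	164	24	518	186
bacteria	KP_F034-KP_R065	440	155	2	518	186
archaea	KP_F018-KP_R002	185	129	29	191	135
archaea	OP_F066-KP_R013	184	129	35	191	135
archaea	KP_F018-KP_R032	186	130	20	191	135
archaea	KP_F018-OP_R073	177	122	18	191	135
archaea	KP_F020-KP_R013	183	128	20	191	135
archaea	KP_F022-KP_R063	180	124	8	191	135
archaea	OP_F114-KP_R013	184	129	16	191	135
archaea	KP_F018-KP_R063	183	127	6	191	135
archaea	OP_F066-OP_R016	180	124	8	191	135
archaea	OP_F114-KP_R002	190	134	29	191	135
archaea	KP_F020-KP_R032	190	134	30	191	135
archaea	OP_F066-OP_R073	181	126	49	191	135
archaea	OP_F114-KP_R031	190	134	20	191	135
archaea	OP_F114-OP_R073	181	126	18	191	135
archaea	KP_F020-OP_R073	180	125	26	191	135
archaea	OP_F114-OP_R121	185	129	6	191	135
archaea	KP_F020-OP_R121	185	129	6	191	135
archaea	OP_F066-OP_R121	186	130	8	191	135
archaea	KP_F078-OP_R010	123	86	20	191	135
archaea	KP_F014-KP_R011	44	41	5	191	135
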