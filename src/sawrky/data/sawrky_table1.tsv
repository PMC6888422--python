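gene	orf_aa	motif_string	zinc_labels	subcellular	group
SaWRKY5	549	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY8	273	WRKYGQK	C-X4-C-X22-HXH	Golgi	I
SaWRKY12	764	WRKYGQK/WRKYGQK	C-X5-C-X23-HXT/C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY18	700	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY20	507	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY25	342	WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH/C-X7-C-X23-HXL	Nucleus	I
SaWRKY30	427	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY31	443	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY34	580	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY36	440	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY38	511	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY39	521	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY41	621	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X5-C-X23-HXH	Nucleus	I
SaWRKY44	627	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY55	577	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	Nucleus	I
SaWRKY1	333	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIa
SaWRKY3	320	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIa
SaWRKY49	369	WRKYGQK	C-X5-C-X23-HXH	Chloroplast	IIa
SaWRKY10	555	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIb
SaWRKY11	331	WRKYGQK	C-X6-C-X23-HXH	Nucleus	IIb
SaWRKY17	639	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIb
SaWRKY24	545	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIb
SaWRKY35	435	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIb
SaWRKY40	631	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIb
SaWRKY2	179	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY4	329	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY13	295	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY15	306	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY16	199	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY19	296	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY23	234	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY27	266	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY29	181	WRKYGKK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY32	311	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY33	343	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY37	294	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY45	121	WRKYGHK	C-X4-C-X23-HXY	cytoplasm	IIc
SaWRKY46	177	WRKYGQK	C-X4-C-X23-HXH	peroxisome	IIc
SaWRKY54	589	WRKYGKK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY62	341	WRKYGQK	C-X4-C-X23-HXH	Nucleus	IIc
SaWRKY22	356	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY42	335	WRKYGQK	C-X4-C-X22-HXV/C-X5-C-X23-HXH	Nucleus	IId
SaWRKY43	310	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY50	375	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY52	347	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY59	314	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY60	314	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY61	315	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY64	336	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IId
SaWRKY6	394	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY14	282	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY21	316	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY26	300	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY48	242	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY51	369	WRKYGQK	C-X3-C-X22-HXL/C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY56	422	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY58	319	WRKYGQK	C-X5-C-X22-HXS	Nucleus	IIe
SaWRKY63	334	WRKYGQK	C-X5-C-X23-HXH	Nucleus	IIe
SaWRKY7	367	WRKYGQK	C-X7-C-X23-HXC	Nucleus	III
SaWRKY9	357	WRKYGQK	C-X7-C-X23-HXC	Nucleus	III
SaWRKY28	366	WRKYGQK	C-X7-C-X23-HXC	Nucleus	III
SaWRKY47	290	WRKYGQK	C-X7-C-X23-HXC	Nucleus	III
SaWRKY53	362	WRKYGQK	C-X7-C-X22-HXT	Nucleus	III
SaWRKY57	330	WRKYGQK	C-X7-C-X23-HXC	Nucleus	III
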