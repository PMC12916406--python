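name	domain	segment	start	end
N-terminus	none	terminus	1	126
DI-S1	DI	S1	127	145
DI-S1/S2	DI	loop	146	152
DI-S2	DI	S2	153	172
DI-S2/S3	DI	loop	173	186
DI-S3	DI	S3	187	205
DI-S3/S4	DI	loop	206	212
DI-S4	DI	S4	213	231
DI-S4/S5	DI	loop	232	245
DI-S5	DI	S5	246	270
DI-pore	DI	loop	271	399
DI-S6	DI	S6	400	424
DI-DII-linker	none	linker	425	751
DII-S1	DII	S1	752	771
DII-S1/S2	DII	loop	772	780
DII-S2	DII	S2	781	800
DII-S2/S3	DII	loop	801	807
DII-S3	DII	S3	808	827
DII-S3/S4	DII	loop	828	832
DII-S4	DII	S4	833	851
DII-S4/S5	DII	loop	852	866
DII-S5	DII	S5	867	887
DII-pore	DII	loop	888	945
DII-S6	DII	S6	946	970
DII-DIII-linker	none	linker	971	1199
DIII-S1	DIII	S1	1200	1219
DIII-S1/S2	DIII	loop	1220	1230
DIII-S2	DIII	S2	1231	1250
DIII-S2/S3	DIII	loop	1251	1257
DIII-S3	DIII	S3	1258	1277
DIII-S3/S4	DIII	loop	1278	1284
DIII-S4	DIII	S4	1285	1303
DIII-S4/S5	DIII	loop	1304	1319
DIII-S5	DIII	S5	1320	1340
DIII-pore	DIII	loop	1341	1420
DIII-S6	DIII	S6	1421	1445
DIII-DIV-linker	none	linker	1446	1522
DIV-S1	DIV	S1	1523	1542
DIV-S1/S2	DIV	loop	1543	1553
DIV-S2	DIV	S2	1554	1573
DIV-S2/S3	DIV	loop	1574	1580
DIV-S3	DIV	S3	1581	1600
DIV-S3/S4	DIV	loop	1601	1605
DIV-S4	DIV	S4	1606	1626
DIV-S4/S5	DIV	loop	1627	1641
DIV-S5	DIV	S5	1642	1662
DIV-pore	DIV	loop	1663	1740
DIV-S6	DIV	S6	1741	1770
C-terminus	none	terminus	1771	2000
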