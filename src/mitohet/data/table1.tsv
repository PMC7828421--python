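pair	sample	relationship	deletion_mb	palate	cardiac
1	DG18	child	3.0	VPI/BU	TA
1	DG213	mother	3.0	normal	MVP
2	DG33	child	3.0	VPI	normal
2	DG34	mother	3.0	VPI	normal
3	DG250	child	3.0	VPI	IIA
3	DG60	mother	3.0	VPI/BU	normal
4	DG233	child	3.0	VPI	ASD
4	DG76	mother	3.0	normal	normal
5	DG132	child	3.0	VPI	VSD
5	DG133	mother	3.0	normal	normal
6	DG139	child	1.5	VPI	TOF
6	DG161	mother	1.5	normal	normal
7	DG179	child	3.0	normal	TA
7	DG180	mother	3.0	normal	normal
8	DG185	child	3.0	VPI	VSD
8	DG184	mother	3.0	normal	normal
9	DG193	child	3.0	VPI	ASD
9	DG184	mother	3.0	normal	normal
10	DG221	child	3.0	VPI	normal
10	DG220	mother	3.0	normal	normal
11	DG222	child	3.0	VPI	normal
11	DG220	mother	3.0	normal	normal
12	DG224	child	3.0	normal	normal
12	DG225	mother	3.0	normal	normal
13	DG231	child	3.0	SMCP	TOF
13	DG232	mother	3.0	VPI	Murmur
14	DG236	child	1.5	normal	TA
14	DG237	mother	3.0	normal	VSD
15	DG242	child	3.0	VPI	TA
15	DG243	mother	3.0	VPI	normal
16	DG246	child	3.0	VPI	VSD
16	DG247	mother	3.0	CP	normal
17	DG249	child	3.0	normal	TA
17	DG248	mother	3.0	CP	normal
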