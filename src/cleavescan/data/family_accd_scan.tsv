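position	ref	A65	A67	A68	A69	det_A65	det_A67	det_A68	det_A69
56	C	T	T	T	T	-	-	-	-
63	A	A	A	G	G	NP	NP	-	-
73	G	G	G	A	G	NP	NP	+	NP
74	T	C	C	C	C	-	-	-	-
81	T	T	T	G	G	NP	NP	-	-
86	G	A	G	G	G	+	NP	NP	NP
87	A	C	A	A	A	+	NP	NP	NP
88	T	A	T	T	T	+	NP	NP	NP
100	G	T	G	G	G	+	NP	NP	NP
109	G	G	G	A	A	NP	NP	-	-
119	A	G	G	G	G	+	+	+	+
127	A	G	A	A	A	+	NP	NP	NP
134	C	A	C	C	C	+	NP	NP	NP
135	G	T	G	G	G	+	NP	NP	NP
144	C	A	C	A	A	+	NP	+	+
151	A	C	A	A	A	+	NP	NP	NP
152	C	T	C	C	C	+	NP	NP	NP
187	G	T	G	G	G	+	NP	NP	NP
191	A	G	A	A	A	+	NP	NP	NP
207	A	A	A	G	G	NP	NP	+	+
225	C	C	C	G	G	NP	NP	+	+
227	A	A	A	A	G	NP	NP	NP	+
250	G	G	G	C	C	NP	NP	+	+
251	T	T	T	C	C	NP	NP	+	+
260	A	G	G	G	G	+	+	+	+
266	C	T	C	T	T	-	NP	-	-
283	C	G	C	C	C	+	NP	NP	NP
305	T	C	T	T	T	+	NP	NP	NP
339	C	A	C	C	C	+	NP	NP	NP
345	A	C	A	A	A	+	NP	NP	NP
346	A	G	G	G	G	+	+	+	+
354	C	A	C	C	T	-	NP	NP	-
365	C	A	T	G	G	-	-	-	-
368	T	T	T	C	C	NP	NP	-	-
372	G	G	G	A	A	NP	NP	+	+
380	G	T	T	T	T	-	-	-	-
388	C	T	C	A	A	+	NP	+	+
389	T	G	G	G	G	+	+	+	+
395	A	A	A	G	G	NP	NP	-	-
408	G	G	G	A	A	NP	NP	-	-
416	A	C	A	A	A	+	NP	NP	NP
449	C	C	C	T	T	NP	NP	-	-
450	C	A	C	C	C	-	NP	NP	NP
468	C	A	A	C	C	+	+	NP	NP
469	G	A	A	A	A	+	+	+	+
470	G	T	G	G	G	+	NP	NP	NP
474	A	C	T	A	A	+	+	NP	NP
522	A	G	A	A	A	-	NP	NP	NP
543	T	C	C	T	T	+	+	NP	NP
704	A	G	G	G	G	+	+	+	+
707	G	G	C	G	G	NP	-	NP	NP
713	T	T	T	A	A	NP	NP	+	+
746	C	C	T	C	C	NP	-	NP	NP
755	T	T	T	T	C	NP	NP	NP	+
781	G	T	G	G	G	+	NP	NP	NP
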