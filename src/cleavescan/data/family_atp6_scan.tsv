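position	ref	A67	A76	A83	A90	det_A67	det_A76	det_A83	det_A90
134	G	T	T	G	G	+	+	NP	NP
240	G	C	C	C	G	+	+	+	NP
296	T	T	T	C	T	NP	NP	+	NP
305	T	C	C	T	T	+	+	NP	NP
314	T	G	G	G	T	+	+	+	NP
338	A	A	A	A	G	NP	NP	NP	+
351	C	G	G	G	C	+	+	+	NP
512	T	T	T	T	C	NP	NP	NP	+
533	T	T	T	T	C	NP	NP	NP	+
625	T	C	C	C	C	+	+	+	+
637	G	G	G	G	A	NP	NP	NP	+
647	A	A	A	A	T	NP	NP	NP	+
653	C	A	A	A	C	+	+	+	NP
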