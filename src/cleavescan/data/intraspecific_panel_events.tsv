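sample	gene	position	kind	ref	alt
B14	accD	216	substitution	G	T
B60	accD	216	substitution	G	T
B90	accD	216	substitution	G	T
B94	accD	335	substitution	T	A
B95	accD	335	substitution	T	A
B96	accD	335	substitution	T	A
B11	accD	560	deletion	AAAGTG	
B14	accD	560	deletion	AAAGTG	
B25	accD	560	deletion	AAAGTG	
B27	accD	560	deletion	AAAGTG	
B29	accD	560	deletion	AAAGTG	
B45	accD	560	deletion	AAAGTG	
B51	accD	560	deletion	AAAGTG	
B60	accD	560	deletion	AAAGTG	
B90	accD	560	deletion	AAAGTG	
B91	accD	560	deletion	AAAGTG	
B92	accD	560	deletion	AAAGTG	
B93	accD	560	deletion	AAAGTG	
B11	accD	644	substitution	A	C
B12	accD	644	substitution	A	C
B14	accD	644	substitution	A	C
B25	accD	644	substitution	A	C
B27	accD	644	substitution	A	C
B29	accD	644	substitution	A	C
B32	accD	644	substitution	A	C
B45	accD	644	substitution	A	C
B51	accD	644	substitution	A	C
B60	accD	644	substitution	A	C
B64	accD	644	substitution	A	C
B65	accD	644	substitution	A	C
B66	accD	644	substitution	A	C
B69	accD	644	substitution	A	C
B73	accD	644	substitution	A	C
B74	accD	644	substitution	A	C
B76	accD	644	substitution	A	C
B79	accD	644	substitution	A	C
B81	accD	644	substitution	A	C
B90	accD	644	substitution	A	C
B91	accD	644	substitution	A	C
B92	accD	644	substitution	A	C
B93	accD	644	substitution	A	C
B94	accD	797	substitution	C	T
B95	accD	797	substitution	C	T
B96	accD	797	substitution	C	T
B94	accD	858	substitution	G	A
B95	accD	858	substitution	G	A
B96	accD	858	substitution	G	A
B94	accD	1058	substitution	G	A
B95	accD	1058	substitution	G	A
B96	accD	1058	substitution	G	A
B94	accD	1177	substitution	T	G
B95	accD	1177	substitution	T	G
B96	accD	1177	substitution	T	G
B94	accD	1275	substitution	T	C
B95	accD	1275	substitution	T	C
B96	accD	1275	substitution	T	C
B94	matK	201	substitution	A	G
B95	matK	201	substitution	A	G
B96	matK	201	substitution	A	G
B11	matK	822	substitution	T	A
B12	matK	822	substitution	T	A
B14	matK	822	substitution	T	A
B27	matK	822	substitution	T	A
B29	matK	822	substitution	T	A
B32	matK	822	substitution	T	A
B45	matK	822	substitution	T	A
B51	matK	822	substitution	T	A
B60	matK	822	substitution	T	A
B64	matK	822	substitution	T	A
B65	matK	822	substitution	T	A
B66	matK	822	substitution	T	A
B68	matK	822	substitution	T	A
B69	matK	822	substitution	T	A
B73	matK	822	substitution	T	A
B74	matK	822	substitution	T	A
B76	matK	822	substitution	T	A
B79	matK	822	substitution	T	A
B81	matK	822	substitution	T	A
B90	matK	822	substitution	T	A
B91	matK	822	substitution	T	A
B92	matK	822	substitution	T	A
B93	matK	822	substitution	T	A
B94	matK	822	substitution	T	A
B95	matK	822	substitution	T	A
B96	matK	822	substitution	T	A
B11	matK	889	substitution	T	G
B12	matK	889	substitution	T	G
B14	matK	889	substitution	T	G
B27	matK	889	substitution	T	G
B29	matK	889	substitution	T	G
B32	matK	889	substitution	T	G
B45	matK	889	substitution	T	G
B51	matK	889	substitution	T	G
B60	matK	889	substitution	T	G
B64	matK	889	substitution	T	G
B65	matK	889	substitution	T	G
B66	matK	889	substitution	T	G
B68	matK	889	substitution	T	G
B69	matK	889	substitution	T	G
B73	matK	889	substitution	T	G
B74	matK	889	substitution	T	G
B76	matK	889	substitution	T	G
B79	matK	889	substitution	T	G
B81	matK	889	substitution	T	G
B90	matK	889	substitution	T	G
B91	matK	889	substitution	T	G
B92	matK	889	substitution	T	G
B93	matK	889	substitution	T	G
B14	matK	934	substitution	G	A
B29	matK	934	substitution	G	A
B60	matK	934	substitution	G	A
B90	matK	934	substitution	G	A
B94	matK	1031	substitution	TT	AA
B95	matK	1031	substitution	TT	AA
B96	matK	1031	substitution	TT	AA
B11	matK	1132	substitution	G	T
B12	matK	1132	substitution	G	T
B14	matK	1132	substitution	G	T
B25	matK	1132	substitution	G	T
B27	matK	1132	substitution	G	T
B29	matK	1132	substitution	G	T
B32	matK	1132	substitution	G	T
B45	matK	1132	substitution	G	T
B51	matK	1132	substitution	G	T
B60	matK	1132	substitution	G	T
B64	matK	1132	substitution	G	T
B65	matK	1132	substitution	G	T
B66	matK	1132	substitution	G	T
B68	matK	1132	substitution	G	T
B69	matK	1132	substitution	G	T
B73	matK	1132	substitution	G	T
B74	matK	1132	substitution	G	T
B76	matK	1132	substitution	G	T
B79	matK	1132	substitution	G	T
B81	matK	1132	substitution	G	T
B90	matK	1132	substitution	G	T
B91	matK	1132	substitution	G	T
B92	matK	1132	substitution	G	T
B93	matK	1132	substitution	G	T
B94	matK	1132	substitution	G	T
B95	matK	1132	substitution	G	T
B96	matK	1132	substitution	G	T
B11	rbcL	66	substitution	G	A
B12	rbcL	66	substitution	G	A
B14	rbcL	66	substitution	G	A
B27	rbcL	66	substitution	G	A
B32	rbcL	66	substitution	G	A
B51	rbcL	66	substitution	G	A
B60	rbcL	66	substitution	G	A
B64	rbcL	66	substitution	G	A
B65	rbcL	66	substitution	G	A
B66	rbcL	66	substitution	G	A
B68	rbcL	66	substitution	G	A
B73	rbcL	66	substitution	G	A
B74	rbcL	66	substitution	G	A
B76	rbcL	66	substitution	G	A
B81	rbcL	66	substitution	G	A
B90	rbcL	66	substitution	G	A
B91	rbcL	66	substitution	G	A
B92	rbcL	66	substitution	G	A
B93	rbcL	66	substitution	G	A
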