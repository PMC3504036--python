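site_no	size_700	size_800	product_bp	samples
1	73	754	827	A68
2	86	741	827	A65
3	87	740	827	A65
4	88	739	827	A65
5	100	727	827	A65
6	119	708	827	A65,A67,A68,A69
7	127	700	827	A65
8	134	693	827	A65
9	135	692	827	A65
10	144	683	827	A65,A68,A69
11	151	676	827	A65
12	152	675	827	A65
13	187	640	827	A65
14	191	636	827	A65
15	207	620	827	A68,A69
16	225	602	827	A68,A69
17	227	600	827	A69
18	250	577	827	A68,A69
19	251	576	827	A68,A69
20	260	567	827	A65,A67,A68,A69
21	283	544	827	A65
22	305	522	827	A65
23	339	488	827	A65
24	345	482	827	A65
25	346	481	827	A65,A67,A68,A69
26	372	455	827	A68,A69
27	388	439	827	A65
28	388	439	827	A68,A69
29	389	438	827	A65,A67,A68,A69
30	416	411	827	A65
31	468	359	827	A65,A67
32	469	358	827	A65,A67,A68,A69
33	470	357	827	A65
34	474	353	827	A65
35	474	353	827	A67
36	543	284	827	A65,A67
37	704	123	827	A65,A67,A68,A69
38	713	114	827	A68,A69
39	755	72	827	A69
40	781	46	827	A65
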