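sample	age	sex	location	size_cm	bethesda	calcitonin_ng_l	tnm
1	43	Female	Right	2.9	IV	NA	T1bNXMX
2	66	Female	Right	1.5	V	NA	T1bN0MX
3	49	Female	Right	1.0	III	1200	NA
4	18	Female	Left	1.7	V	18	T1bN0MX
5	78	Female	Right	4.0	III	10702	T2N0MX
6	35	Female	Left	2.5	III	1095	T2N1bMX
7	52	Female	Right	2.1	V	6912	T2N1bMX
8	52	Male	Left	5.1	V	6149	T3aN1bMX
9	62	Female	Left	1.5	III	122	T1bNXMX
10	55	Male	Right	5.3	IV	6866	T3aN0MX
11	73	Female	Right	4.0	III	NA	NA
12	44	Male	Right	0.7	IV	8	T1aN1aMX
13	35	Female	Right	1.0	V	34	T1aN1MX
14	69	Female	Right	1.6	IV	111	T1bNXMX
15	58	Female	Right	NA	III	495	T1bN0MX
16	25	Female	Left	2.1	V	158	T2NXMX
17	49	Female	Left	1.2	III	61	T1aN0MX
18	48	Female	Right	1.7	III	4000	T2N1MX
19	71	Female	Left	0.8	IV	NA	T1aNXMX
20	50	Male	Left	1.0	IV	92	T1aNXMX
21	65	Female	Left	1.4	V	157	T1bN0MX
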