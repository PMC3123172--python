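# 64-state backbone structural alphabet (index, phi_deg, psi_deg)
# derived by k-means on a synthetic Ramachandran basin mixture with canonical anchors; see tmdscan.alphabet.derive_alphabet
0	-161.359	152.611
1	-160.547	119.133
2	-153.750	-35.909
3	-153.435	81.893
4	-151.287	-91.683
5	-141.381	138.809
6	-138.654	-166.272
7	-136.726	21.066
8	-136.304	109.278
9	-132.278	164.190
10	-129.000	123.000
11	-123.397	128.081
12	-118.807	84.764
13	-115.655	145.823
14	-112.371	110.851
15	-107.452	-124.534
16	-102.782	164.820
17	-98.074	127.785
18	-89.779	148.400
19	-89.345	97.455
20	-83.917	-31.346
21	-78.708	-169.946
22	-78.265	-57.330
23	-78.138	135.660
24	-78.130	161.690
25	-75.000	145.000
26	-72.767	-42.461
27	-68.524	-15.013
28	-64.094	-31.142
29	-63.939	116.872
30	-63.924	50.427
31	-62.297	-120.719
32	-60.436	144.546
33	-60.058	-46.225
34	-59.512	164.945
35	-58.795	-61.432
36	-57.000	-47.000
37	-49.000	-26.000
38	-48.973	-34.142
39	-48.596	-16.382
40	-43.026	-49.997
41	-24.038	146.503
42	-9.861	-160.634
43	-5.917	-109.750
44	-4.862	8.187
45	-3.377	76.642
46	26.700	-53.405
47	38.932	139.681
48	46.909	52.490
49	51.785	-136.046
50	57.000	47.000
51	58.402	-12.395
52	61.728	35.749
53	74.767	59.299
54	91.331	-66.759
55	97.114	139.917
56	105.038	-142.382
57	137.051	-5.555
58	151.994	102.509
59	152.755	49.258
60	153.927	-146.694
61	157.978	-78.154
62	158.065	152.471
63	180.000	180.000
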