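roi_id	name	hemisphere
0	lh_caudalanteriorcingulate	left
1	lh_caudalmiddlefrontal	left
2	lh_cuneus	left
3	lh_entorhinal	left
4	lh_fusiform	left
5	lh_inferiorparietal	left
6	lh_inferiortemporal	left
7	lh_isthmuscingulate	left
8	lh_lateraloccipital	left
9	lh_lateralorbitofrontal	left
10	lh_lingual	left
11	lh_medialorbitofrontal	left
12	lh_middletemporal	left
13	lh_parahippocampal	left
14	lh_paracentral	left
15	lh_parsopercularis	left
16	lh_parsorbitalis	left
17	lh_parstriangularis	left
18	lh_pericalcarine	left
19	lh_postcentral	left
20	lh_posteriorcingulate	left
21	lh_precentral	left
22	lh_precuneus	left
23	lh_rostralanteriorcingulate	left
24	lh_rostralmiddlefrontal	left
25	lh_superiorfrontal	left
26	lh_superiorparietal	left
27	lh_superiortemporal	left
28	lh_supramarginal	left
29	lh_transversetemporal	left
30	lh_insula	left
31	rh_caudalanteriorcingulate	right
32	rh_caudalmiddlefrontal	right
33	rh_cuneus	right
34	rh_entorhinal	right
35	rh_fusiform	right
36	rh_inferiorparietal	right
37	rh_inferiortemporal	right
38	rh_isthmuscingulate	right
39	rh_lateraloccipital	right
40	rh_lateralorbitofrontal	right
41	rh_lingual	right
42	rh_medialorbitofrontal	right
43	rh_middletemporal	right
44	rh_parahippocampal	right
45	rh_paracentral	right
46	rh_parsopercularis	right
47	rh_parsorbitalis	right
48	rh_parstriangularis	right
49	rh_pericalcarine	right
50	rh_postcentral	right
51	rh_posteriorcingulate	right
52	rh_precentral	right
53	rh_precuneus	right
54	rh_rostralanteriorcingulate	right
55	rh_rostralmiddlefrontal	right
56	rh_superiorfrontal	right
57	rh_superiorparietal	right
58	rh_superiortemporal	right
59	rh_supramarginal	right
60	rh_transversetemporal	right
61	rh_insula	right
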