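id	name	lobe_group
1	Precentral	frontal
2	Superior frontal	frontal
3	Orbital superior frontal (lateral)	frontal
4	Middle frontal	frontal
5	Orbital frontal	frontal
6	Opercular Inferior frontal	frontal
7	Triangular Inferior frontal	frontal
8	Orbital Inferior frontal	frontal
9	Rolandic operculum	frontal
10	Supplementary motor area	frontal
11	Olfactory cortex	frontal
12	Medial superior frontal	frontal
13	Orbital superior frontal (medial)	frontal
14	Gyrus rectus	frontal
15	Paracentral	frontal
16	Hippocampus	temporal
17	Parahippocampus	temporal
18	Amygdala	temporal
19	Fusiform gyrus	temporal
20	Heschl gyrus	temporal
21	Superior temporal	temporal
22	Temporal pole	temporal
23	Middle temporal	temporal
24	Inferior temporal	temporal
25	Postcentral	parietal
26	Superior parietal	parietal
27	Inferior parietal	parietal
28	Supramarginal	parietal
29	Angular	parietal
30	Precuneus	parietal
31	Calcarine	occipital
32	Cuneus	occipital
33	Lingual	occipital
34	Superior occipital	occipital
35	Middle occipital	occipital
36	Inferior occipital	occipital
37	Insula	insula_cingulate
38	Anterior cingulate	insula_cingulate
39	Middle cingulate	insula_cingulate
40	Posterior cingulate	insula_cingulate
41	Caudate	central
42	Putamen	central
43	Thalamus	central
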