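region	T0	T2	T4	SEM	fixed_effect	p_value
Precentral	0.057	0.054	0.054	0.001	-0.0006	0.077
Superior frontal	0.057	0.053	0.053	0.002	-0.0006	0.084
Orbital superior frontal (lateral)	0.052	0.050	0.053	0.001	-0.0003	0.921
Middle frontal	0.061	0.057	0.056	0.002	-0.0006	0.134
Orbital frontal	0.058	0.054	0.056	0.002	-0.0003	0.492
Opercular Inferior frontal	0.056	0.053	0.054	0.002	-0.0004	0.179
Triangular Inferior frontal	0.058	0.055	0.055	0.002	-0.0005	0.164
Orbital Inferior frontal	0.054	0.050	0.051	0.002	-0.0005	0.162
Rolandic operculum	0.049	0.049	0.049	0.001	-0.0002	0.510
Supplementary motor area	0.054	0.050	0.050	0.001	-0.0006	0.065
Olfactory cortex	0.036	0.035	0.034	0.001	-0.0003	0.216
Medial superior frontal	0.054	0.050	0.049	0.001	-0.0006	0.062
Orbital superior frontal (medial)	0.053	0.049	0.048	0.001	-0.0007	0.031
Gyrus rectus	0.049	0.046	0.047	0.001	-0.0003	0.274
Paracentral	0.049	0.048	0.048	0.001	-0.0003	0.316
Hippocampus	0.027	0.026	0.025	0.001	-0.0003	0.050
Parahippocampus	0.033	0.032	0.031	0.001	-0.0004	0.048
Amygdala	0.027	0.025	0.024	0.001	-0.0004	0.011
Fusiform gyrus	0.042	0.040	0.039	0.001	-0.0004	0.127
Heschl gyrus	0.061	0.058	0.058	0.002	-0.0005	0.144
Superior temporal	0.050	0.047	0.047	0.002	-0.0005	0.117
Temporal pole	0.041	0.037	0.036	0.001	-0.0007	0.016
Middle temporal	0.050	0.047	0.046	0.002	-0.0005	0.109
Inferior temporal	0.045	0.043	0.043	0.001	-0.0002	0.395
Postcentral	0.054	0.051	0.051	0.002	-0.0005	0.139
Superior parietal	0.055	0.052	0.051	0.001	-0.0005	0.102
Inferior parietal	0.059	0.055	0.053	0.002	-0.0007	0.042
Supramarginal	0.054	0.051	0.050	0.002	-0.0007	0.057
Angular	0.057	0.053	0.052	0.002	-0.0007	0.052
Precuneus	0.058	0.055	0.054	0.002	-0.0007	0.044
Calcarine	0.054	0.051	0.050	0.001	-0.0004	0.046
Cuneus	0.058	0.052	0.055	0.002	-0.0007	0.075
Lingual	0.048	0.046	0.046	0.001	-0.0004	0.207
Superior occipital	0.055	0.051	0.051	0.002	-0.0007	0.038
Middle occipital	0.053	0.049	0.049	0.002	-0.0006	0.094
Inferior occipital	0.049	0.048	0.048	0.002	-0.0002	0.576
Insula	0.045	0.044	0.044	0.001	-0.0003	0.280
Anterior cingulate	0.045	0.041	0.040	0.001	-0.0006	0.016
Middle cingulate	0.052	0.049	0.047	0.001	-0.0008	0.003
Posterior cingulate	0.055	0.053	0.051	0.001	-0.0006	0.054
Caudate	0.040	0.039	0.038	0.001	-0.0002	0.315
Putamen	0.042	0.041	0.042	0.001	-0.0002	0.330
Thalamus	0.038	0.038	0.036	0.001	-0.0002	0.199
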