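region	T0	T2	T4	SEM	fixed_effect	p_value
Precentral	0.026	0.026	0.025	0.003	0.0001	0.594
Superior frontal	0.025	0.025	0.024	0.003	0.0001	0.725
Orbital superior frontal (lateral)	0.025	0.025	0.024	0.003	0.0003	0.156
Middle frontal	0.028	0.027	0.025	0.003	0.0001	0.614
Orbital frontal	0.028	0.027	0.025	0.003	0.0002	0.392
Opercular Inferior frontal	0.026	0.025	0.024	0.003	0.0001	0.680
Triangular Inferior frontal	0.027	0.026	0.024	0.003	0.0001	0.624
Orbital Inferior frontal	0.026	0.025	0.024	0.003	0.0001	0.478
Rolandic operculum	0.024	0.023	0.022	0.003	0.0001	0.593
Supplementary motor area	0.026	0.026	0.025	0.003	0.0001	0.505
Olfactory cortex	0.019	0.018	0.017	0.002	0.0001	0.815
Medial superior frontal	0.026	0.025	0.023	0.003	0.0001	0.711
Orbital superior frontal (medial)	0.025	0.024	0.022	0.003	0.0001	0.616
Gyrus rectus	0.024	0.024	0.022	0.003	0.0001	0.593
Paracentral	0.029	0.029	0.028	0.004	0.0002	0.373
Hippocampus	0.019	0.018	0.017	0.002	0.0001	0.678
Parahippocampus	0.021	0.021	0.019	0.003	0.0001	0.907
Amygdala	0.019	0.016	0.016	0.002	0.0001	0.807
Fusiform gyrus	0.025	0.024	0.023	0.003	0.0001	0.648
Heschl gyrus	0.026	0.024	0.024	0.003	0.0002	0.665
Superior temporal	0.026	0.025	0.024	0.003	0.0001	0.567
Temporal pole	0.023	0.022	0.020	0.003	0.0002	0.883
Middle temporal	0.028	0.027	0.026	0.003	0.0001	0.552
Inferior temporal	0.028	0.026	0.025	0.003	0.0001	0.567
Postcentral	0.027	0.027	0.025	0.003	0.0001	0.477
Superior parietal	0.030	0.029	0.028	0.004	0.0002	0.409
Inferior parietal	0.029	0.028	0.027	0.003	0.0002	0.457
Supramarginal	0.028	0.027	0.026	0.003	0.0001	0.524
Angular	0.029	0.028	0.027	0.004	0.0001	0.636
Precuneus	0.030	0.029	0.028	0.004	0.0002	0.390
Calcarine	0.030	0.029	0.028	0.004	0.0002	0.347
Cuneus	0.032	0.031	0.031	0.004	0.0003	0.283
Lingual	0.027	0.027	0.026	0.003	0.0003	0.194
Superior occipital	0.030	0.030	0.029	0.004	0.0002	0.332
Middle occipital	0.030	0.030	0.029	0.004	0.0002	0.329
Inferior occipital	0.030	0.030	0.029	0.004	0.0004	0.110
Insula	0.022	0.021	0.020	0.003	0.0001	0.924
Anterior cingulate	0.022	0.021	0.019	0.003	0.0001	0.986
Middle cingulate	0.026	0.025	0.024	0.003	0.0001	0.590
Posterior cingulate	0.028	0.026	0.025	0.003	0.0001	0.530
Caudate	0.016	0.016	0.015	0.002	0.0001	0.841
Putamen	0.019	0.018	0.017	0.002	0.0001	0.970
Thalamus	0.021	0.020	0.019	0.003	0.0001	0.704
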