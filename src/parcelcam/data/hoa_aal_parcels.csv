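parcel_id,name,hemisphere,lobe,group
1,Frontal Pole,left,frontal,cortical
2,Frontal Pole,right,frontal,cortical
3,Insular Cortex,left,insular,cortical
4,Insular Cortex,right,insular,cortical
5,Superior Frontal Gyrus,left,frontal,cortical
6,Superior Frontal Gyrus,right,frontal,cortical
7,Middle Frontal Gyrus,left,frontal,cortical
8,Middle Frontal Gyrus,right,frontal,cortical
9,Inferior Frontal Gyrus pars triangularis,left,frontal,cortical
10,Inferior Frontal Gyrus pars triangularis,right,frontal,cortical
11,Inferior Frontal Gyrus pars opercularis,left,frontal,cortical
12,Inferior Frontal Gyrus pars opercularis,right,frontal,cortical
13,Precentral Gyrus,left,frontal,cortical
14,Precentral Gyrus,right,frontal,cortical
15,Temporal Pole,left,temporal,cortical
16,Temporal Pole,right,temporal,cortical
17,Superior Temporal Gyrus anterior division,left,temporal,cortical
18,Superior Temporal Gyrus anterior division,right,temporal,cortical
19,Superior Temporal Gyrus posterior division,left,temporal,cortical
20,Superior Temporal Gyrus posterior division,right,temporal,cortical
21,Middle Temporal Gyrus anterior division,left,temporal,cortical
22,Middle Temporal Gyrus anterior division,right,temporal,cortical
23,Middle Temporal Gyrus posterior division,left,temporal,cortical
24,Middle Temporal Gyrus posterior division,right,temporal,cortical
25,Middle Temporal Gyrus temporooccipital part,left,temporal,cortical
26,Middle Temporal Gyrus temporooccipital part,right,temporal,cortical
27,Inferior Temporal Gyrus anterior division,left,temporal,cortical
28,Inferior Temporal Gyrus anterior division,right,temporal,cortical
29,Inferior Temporal Gyrus posterior division,left,temporal,cortical
30,Inferior Temporal Gyrus posterior division,right,temporal,cortical
31,Inferior Temporal Gyrus temporooccipital part,left,temporal,cortical
32,Inferior Temporal Gyrus temporooccipital part,right,temporal,cortical
33,Postcentral Gyrus,left,parietal,cortical
34,Postcentral Gyrus,right,parietal,cortical
35,Superior Parietal Lobule,left,parietal,cortical
36,Superior Parietal Lobule,right,parietal,cortical
37,Supramarginal Gyrus anterior division,left,parietal,cortical
38,Supramarginal Gyrus anterior division,right,parietal,cortical
39,Supramarginal Gyrus posterior division,left,parietal,cortical
40,Supramarginal Gyrus posterior division,right,parietal,cortical
41,Angular Gyrus,left,parietal,cortical
42,Angular Gyrus,right,parietal,cortical
43,Lateral Occipital Cortex superior division,left,occipital,cortical
44,Lateral Occipital Cortex superior division,right,occipital,cortical
45,Lateral Occipital Cortex inferior division,left,occipital,cortical
46,Lateral Occipital Cortex inferior division,right,occipital,cortical
47,Intracalcarine Cortex,left,occipital,cortical
48,Intracalcarine Cortex,right,occipital,cortical
49,Juxtapositional Lobule Cortex,left,frontal,cortical
50,Juxtapositional Lobule Cortex,right,frontal,cortical
51,Paracingulate Gyrus,left,limbic,cortical
52,Paracingulate Gyrus,right,limbic,cortical
53,Cuneal Cortex,left,occipital,cortical
54,Cuneal Cortex,right,occipital,cortical
55,Frontal Orbital Cortex,left,frontal,cortical
56,Frontal Orbital Cortex,right,frontal,cortical
57,Parahippocampal Gyrus anterior division,left,limbic,cortical
58,Parahippocampal Gyrus anterior division,right,limbic,cortical
59,Parahippocampal Gyrus posterior division,left,limbic,cortical
60,Parahippocampal Gyrus posterior division,right,limbic,cortical
61,Lingual Gyrus,left,occipital,cortical
62,Lingual Gyrus,right,occipital,cortical
63,Temporal Fusiform Cortex anterior division,left,temporal,cortical
64,Temporal Fusiform Cortex anterior division,right,temporal,cortical
65,Temporal Fusiform Cortex posterior division,left,temporal,cortical
66,Temporal Fusiform Cortex posterior division,right,temporal,cortical
67,Temporal Occipital Fusiform Cortex,left,temporal,cortical
68,Temporal Occipital Fusiform Cortex,right,temporal,cortical
69,Occipital Fusiform Gyrus,left,occipital,cortical
70,Occipital Fusiform Gyrus,right,occipital,cortical
71,Frontal Operculum Cortex,left,frontal,cortical
72,Frontal Operculum Cortex,right,frontal,cortical
73,Central Opercular Cortex,left,frontal,cortical
74,Central Opercular Cortex,right,frontal,cortical
75,Parietal Operculum Cortex,left,parietal,cortical
76,Parietal Operculum Cortex,right,parietal,cortical
77,Planum Polare,left,temporal,cortical
78,Planum Polare,right,temporal,cortical
79,Heschl's Gyrus,left,temporal,cortical
80,Heschl's Gyrus,right,temporal,cortical
81,Planum Temporale,left,temporal,cortical
82,Planum Temporale,right,temporal,cortical
83,Supracalcarine Cortex,left,occipital,cortical
84,Supracalcarine Cortex,right,occipital,cortical
85,Occipital Pole,left,occipital,cortical
86,Occipital Pole,right,occipital,cortical
87,Frontal Medial Cortex,midline,frontal,cortical
88,Subcallosal Cortex,midline,limbic,cortical
89,Cingulate Gyrus anterior division,midline,limbic,cortical
90,Cingulate Gyrus posterior division,midline,limbic,cortical
91,Precuneous Cortex,midline,parietal,cortical
92,Thalamus,left,subcortical,subcortical
93,Thalamus,right,subcortical,subcortical
94,Caudate,left,subcortical,subcortical
95,Caudate,right,subcortical,subcortical
96,Putamen,left,subcortical,subcortical
97,Putamen,right,subcortical,subcortical
98,Pallidum,left,subcortical,subcortical
99,Pallidum,right,subcortical,subcortical
100,Hippocampus,left,subcortical,subcortical
101,Hippocampus,right,subcortical,subcortical
102,Amygdala,left,subcortical,subcortical
103,Amygdala,right,subcortical,subcortical
104,Accumbens,left,subcortical,subcortical
105,Accumbens,right,subcortical,subcortical
106,Brainstem,midline,subcortical,subcortical
107,Cerebellum Crus I,left,cerebellar,cerebellar
108,Cerebellum Crus I,right,cerebellar,cerebellar
109,Cerebellum Crus II,left,cerebellar,cerebellar
110,Cerebellum Crus II,right,cerebellar,cerebellar
111,Cerebellum III,left,cerebellar,cerebellar
112,Cerebellum III,right,cerebellar,cerebellar
113,Cerebellum IV-V,left,cerebellar,cerebellar
114,Cerebellum IV-V,right,cerebellar,cerebellar
115,Cerebellum VI,left,cerebellar,cerebellar
116,Cerebellum VI,right,cerebellar,cerebellar
117,Cerebellum VIIb,left,cerebellar,cerebellar
118,Cerebellum VIIb,right,cerebellar,cerebellar
119,Cerebellum VIII,left,cerebellar,cerebellar
120,Cerebellum VIII,right,cerebellar,cerebellar
121,Cerebellum IX,left,cerebellar,cerebellar
122,Cerebellum IX,right,cerebellar,cerebellar
123,Cerebellum X,left,cerebellar,cerebellar
124,Cerebellum X,right,cerebellar,cerebellar
125,Vermis I-II,midline,cerebellar,cerebellar
126,Vermis III,midline,cerebellar,cerebellar
127,Vermis IV-V,midline,cerebellar,cerebellar
128,Vermis VI,midline,cerebellar,cerebellar
129,Vermis VII,midline,cerebellar,cerebellar
130,Vermis VIII,midline,cerebellar,cerebellar
131,Vermis IX,midline,cerebellar,cerebellar
132,Vermis X,midline,cerebellar,cerebellar
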