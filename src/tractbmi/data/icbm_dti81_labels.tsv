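label	tract_name
1	Middle cerebellar peduncle
2	Pontine crossing tract
3	Genu of corpus callosum
4	Body of corpus callosum
5	Splenium of corpus callosum
6	Fornix (column and body)
7	Corticospinal tract R
8	Corticospinal tract L
9	Medial lemniscus R
10	Medial lemniscus L
11	Inferior cerebellar peduncle R
12	Inferior cerebellar peduncle L
13	Superior cerebellar peduncle R
14	Superior cerebellar peduncle L
15	Cerebral peduncle R
16	Cerebral peduncle L
17	Anterior limb of internal capsule R
18	Anterior limb of internal capsule L
19	Posterior limb of internal capsule R
20	Posterior limb of internal capsule L
21	Retrolenticular part of internal capsule R
22	Retrolenticular part of internal capsule L
23	Anterior corona radiata R
24	Anterior corona radiata L
25	Superior corona radiata R
26	Superior corona radiata L
27	Posterior corona radiata R
28	Posterior corona radiata L
29	Posterior thalamic radiation R
30	Posterior thalamic radiation L
31	Sagittal stratum R
32	Sagittal stratum L
33	External capsule R
34	External capsule L
35	Cingulum (cingulate gyrus) R
36	Cingulum (cingulate gyrus) L
37	Cingulum (hippocampus) R
38	Cingulum (hippocampus) L
39	Fornix (cres) / Stria terminalis R
40	Fornix (cres) / Stria terminalis L
41	Superior longitudinal fasciculus R
42	Superior longitudinal fasciculus L
43	Superior fronto-occipital fasciculus R
44	Superior fronto-occipital fasciculus L
45	Uncinate fasciculus R
46	Uncinate fasciculus L
47	Tapetum R
48	Tapetum L
49	Inferior fronto-occipital fasciculus R
50	Inferior fronto-occipital fasciculus L
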