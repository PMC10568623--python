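roi_number,name,hemisphere,lobe
1,superiorfrontal_rh,right,frontal
2,superiorfrontal_lh,left,frontal
3,rostralmiddlefrontal_rh,right,frontal
4,rostralmiddlefrontal_lh,left,frontal
5,caudalmiddlefrontal_rh,right,frontal
6,caudalmiddlefrontal_lh,left,frontal
7,parsopercularis_rh,right,frontal
8,parsopercularis_lh,left,frontal
9,parstriangularis_rh,right,frontal
10,parstriangularis_lh,left,frontal
11,parsorbitalis_rh,right,frontal
12,parsorbitalis_lh,left,frontal
13,lateralorbitofrontal_rh,right,frontal
14,lateralorbitofrontal_lh,left,frontal
15,medialorbitofrontal_rh,right,frontal
16,medialorbitofrontal_lh,left,frontal
17,precentral_rh,right,frontal
18,precentral_lh,left,frontal
19,paracentral_rh,right,frontal
20,paracentral_lh,left,frontal
21,superiortemporal_rh,right,temporal
22,superiortemporal_lh,left,temporal
23,middletemporal_rh,right,temporal
24,middletemporal_lh,left,temporal
25,inferiortemporal_rh,right,temporal
26,inferiortemporal_lh,left,temporal
27,bankssts_rh,right,temporal
28,bankssts_lh,left,temporal
29,fusiform_rh,right,temporal
30,fusiform_lh,left,temporal
31,transversetemporal_rh,right,temporal
32,transversetemporal_lh,left,temporal
33,entorhinal_rh,right,temporal
34,entorhinal_lh,left,temporal
35,temporalpole_rh,right,temporal
36,temporalpole_lh,left,temporal
37,parahippocampal_rh,right,temporal
38,parahippocampal_lh,left,temporal
39,superiorparietal_rh,right,parietal
40,superiorparietal_lh,left,parietal
41,inferiorparietal_rh,right,parietal
42,inferiorparietal_lh,left,parietal
43,supramarginal_rh,right,parietal
44,supramarginal_lh,left,parietal
45,postcentral_rh,right,parietal
46,postcentral_lh,left,parietal
47,precuneus_rh,right,parietal
48,precuneus_lh,left,parietal
49,lateraloccipital_rh,right,occipital
50,lateraloccipital_lh,left,occipital
51,lingual_rh,right,occipital
52,lingual_lh,left,occipital
53,cuneus_rh,right,occipital
54,cuneus_lh,left,occipital
55,pericalcarine_rh,right,occipital
56,pericalcarine_lh,left,occipital
57,isthmuscingulate_rh,right,isthmus
58,isthmuscingulate_lh,left,isthmus
59,caudalanteriorcingulate_rh,right,others
60,caudalanteriorcingulate_lh,left,others
61,posteriorcingulate_rh,right,others
62,posteriorcingulate_lh,left,others
63,rostralanteriorcingulate_rh,right,others
64,rostralanteriorcingulate_lh,left,others
65,insula_rh,right,others
66,insula_lh,left,others
67,frontalpole_rh,right,others
68,frontalpole_lh,left,others
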