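cluster,impact_score,n_patches,morphology
33,0.792793,1407,lymphocyte infiltration
15,0.652546,1348,lymphocyte infiltration and epithelium
9,0.626349,1542,epithelium and a little lymphocyte infiltration
35,0.588725,213,shape
10,0.57435,2209,muscle and connective tissue
23,0.570966,264,shape
19,0.568363,613,muscle and connective tissue
38,0.568304,694,muscle and connective tissue
26,0.565786,1605,muscle and light-colored connective tissue
1,0.563333,165,shape
18,0.55593,614,muscle and connective tissue
24,0.551183,369,shape
32,0.549619,169,shape
28,0.544116,706,shape
29,0.541248,1078,basal layer (excluding lymphocyte-rich areas)
16,0.53363,238,shape
36,0.528598,813,muscle and loose connective tissue
22,0.526346,1078,light-colored
37,0.524113,1783,muscle and loose connective tissue
5,0.517068,791,muscle and keratinized tissue
6,0.514626,165,keratinized layer
11,0.513952,2218,muscle and connective tissue
14,0.513298,1715,spinous and granular layers
8,0.507854,780,"Muscle, adipose and connective tissue"
25,0.503648,705,muscle and connective tissue
20,0.496371,719,muscle and connective tissue
3,0.491524,954,"Muscle, adipose and connective tissue"
12,0.464026,621,muscle and connective tissue
7,0.448971,156,shape
4,0.446255,1748,"Muscle, adipose and connective tissue"
34,0.430969,221,shape
13,0.429933,217,shape
21,0.416876,212,shape
17,0.364027,149,shape
31,0.361109,177,shape
2,0.299376,1938,areas containing blood vessels
27,0.241073,2144,loose connective tissue
30,0.237406,1289,epithelium and lamina propria (excluding lymphocyte-rich areas)
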