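region_id,name,abbreviation,hemisphere
1,Left caudate putamen,CPu.L,L
2,Right caudate putamen,CPu.R,R
3,Left medial prefrontal cortex,mPFC.L,L
4,Right medial prefrontal cortex,mPFC.R,R
5,Left entorhinal cortex,EC.L,L
6,Right entorhinal cortex,EC.R,R
7,Left frontal association cortex,FAC.L,L
8,Right frontal association cortex,FAC.R,R
9,Left interstitial nucleus of the posterior limb of the anterior commissure,IPAC.L,L
10,Right interstitial nucleus of the posterior limb of the anterior commissure,IPAC.R,R
11,Left globus pallidus,GP.L,L
12,Right globus pallidus,GP.R,R
13,Left visual cortex,VC.L,L
14,Right visual cortex,VC.R,R
15,Left lateral hypothalamus,LHy.L,L
16,Right lateral hypothalamus,LHy.R,R
17,Left medial hypothalamus,MHy.L,L
18,Right medial hypothalamus,MHy.R,R
19,Left diagonal band,DB.L,L
20,Right diagonal band,DB.R,R
21,Left anterodorsal hippocampus,ADH.L,L
22,Right anterodorsal hippocampus,ADH.R,R
23,Left posterodorsal hippocampus,PDH.L,L
24,Right posterodorsal hippocampus,PDH.R,R
25,Left bed nucleus of the stria terminalis,BNST.L,L
26,Right bed nucleus of the stria terminalis,BNST.R,R
27,Left substantia nigra,SN.L,L
28,Right substantia nigra,SN.R,R
29,Left septum,Sep.L,L
30,Right septum,Sep.R,R
31,Left motor cortex,MC.L,L
32,Right motor cortex,MC.R,R
33,Left auditory cortex,AC.L,L
34,Right auditory cortex,AC.R,R
35,Left piriform cortex,PC.L,L
36,Right piriform cortex,PC.R,R
37,Left zona incerta,ZI.L,L
38,Right zona incerta,ZI.R,R
39,Left posterior hippocampus,PH.L,L
40,Right posterior hippocampus,PH.R,R
41,Left internal capsule,Internal_Capsule.L,L
42,Right internal capsule,Internal_Capsule.R,R
43,Left insular cortex,IC.L,L
44,Right insular cortex,IC.R,R
45,Left subiculum hippocampus,SH.L,L
46,Right subiculum hippocampus,SH.R,R
47,Left somatosensory cortex,SSC.L,L
48,Right somatosensory cortex,SSC.R,R
49,Left orbitofrontal cortex,OFC.L,L
50,Right orbitofrontal cortex,OFC.R,R
51,Left cingulate cortex,Cg.L,L
52,Right cingulate cortex,Cg.R,R
53,Left retrosplenial cortex,RSC.L,L
54,Right retrosplenial cortex,RSC.R,R
55,Left thalamus,Th.L,L
56,Right thalamus,Th.R,R
57,Left dorsolateral thalamus,DLTh.L,L
58,Right dorsolateral thalamus,DLTh.R,R
59,Left ventral posterior thalamus,VPTh.L,L
60,Right ventral posterior thalamus,VPTh.R,R
61,Left amygdala,Amy.L,L
62,Right amygdala,Amy.R,R
63,Left nucleus accumbens,NAc.L,L
64,Right nucleus accumbens,NAc.R,R
65,Left ventral hippocampus,VH.L,L
66,Right ventral hippocampus,VH.R,R
67,Left olfactory bulb,OB.L,L
68,Right olfactory bulb,OB.R,R
69,Left cerebellum,Cer.L,L
70,Right cerebellum,Cer.R,R
71,Left periaqueductal gray,PAG.L,L
72,Right periaqueductal gray,PAG.R,R
73,Left ventral tegmental area,VTA.L,L
74,Right ventral tegmental area,VTA.R,R
75,Left habenula,Hb.L,L
76,Right habenula,Hb.R,R
77,Left posterior parietal cortex,PPC.L,L
78,Right posterior parietal cortex,PPC.R,R
79,Left temporal association cortex,TeA.L,L
80,Right temporal association cortex,TeA.R,R
81,Left perirhinal cortex,PRh.L,L
82,Right perirhinal cortex,PRh.R,R
83,Left subthalamic nucleus,STh.L,L
84,Right subthalamic nucleus,STh.R,R
85,Left superior colliculus,SuC.L,L
86,Right superior colliculus,SuC.R,R
87,Left inferior colliculus,InfC.L,L
88,Right inferior colliculus,InfC.R,R
89,Left pons,Po.L,L
90,Right pons,Po.R,R
91,Left medulla,Med.L,L
92,Right medulla,Med.R,R
93,Left claustrum,Cl.L,L
94,Right claustrum,Cl.R,R
95,Left olfactory tubercle,Tu.L,L
96,Right olfactory tubercle,Tu.R,R
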