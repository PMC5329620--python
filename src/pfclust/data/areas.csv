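id,name,lobe,subdivision,reference_cluster
V6A,visual area 6A,parietal,SPL,pmSPL
PGm,medial parietal area PGm (7m),parietal,SPL,pmSPL
31,posterior cingulate area 31,parietal,SPL,pmSPL
PEci,area PE cingulate sector,parietal,SPL,mdSPL
PEc,caudal area PE,parietal,SPL,mdSPL
MIP,medial intraparietal area,parietal,SPL,mdSPL
PEa,area PE intraparietal sector,parietal,SPL,mdSPL
PE,superior parietal area PE,parietal,SPL,aSPL
SI,primary somatosensory cortex,parietal,SPL,aSPL
Opt,area Opt,parietal,IPL,pIPL
MST,medial superior temporal area,parietal,IPL,pIPL
LIP,lateral intraparietal area,parietal,IPL,pIPL
VIP,ventral intraparietal area,parietal,IPL,pIPL
PF,inferior parietal area PF,parietal,IPL,aIPL
PFG,inferior parietal area PFG,parietal,IPL,aIPL
PG,inferior parietal area PG,parietal,IPL,aIPL
AIP,anterior intraparietal area,parietal,IPL,aIPL
SII,second somatosensory region,parietal,IPL,aIPL
F1,primary motor cortex (MI),frontal,premotor,MI-dmPM
F2cd,dorsal premotor area F2 precentral dimple sector,frontal,premotor,MI-dmPM
F2vr,dorsal premotor area F2 ventrorostral sector,frontal,premotor,MI-dmPM
F3,supplementary motor area (SMA),frontal,premotor,MI-dmPM
F6,pre-supplementary motor area (pre-SMA),frontal,premotor,MI-dmPM
F7,dorsal premotor area F7,frontal,premotor,MI-dmPM
F4,ventral premotor area F4,frontal,premotor,vPM
F5a,ventral premotor area F5a with area 44,frontal,premotor,vPM
F5c,ventral premotor area F5 convexity sector,frontal,premotor,vPM
F5p,ventral premotor area F5 posterior sector,frontal,premotor,vPM
24a,cingulate gyrus area 24a,frontal,cingulate,CING
24b,cingulate gyrus area 24b,frontal,cingulate,CING
24c,rostral cingulate motor area (24c/CMAr),frontal,cingulate,CING
23c,caudal cingulate motor area (23c/CMAc),frontal,cingulate,CING
8B,prefrontal area 8B,frontal,prefrontal,pPFC
SEF,supplementary eye field (F7-SEF),frontal,prefrontal,pPFC
8Ad,dorsal area 8A with lateral FEF,frontal,prefrontal,pPFC
8Av,ventral area 8A with ventral FEF,frontal,prefrontal,pPFC
45B,prefrontal area 45B,frontal,prefrontal,pPFC
46dc,caudal dorsal area 46,frontal,prefrontal,pPFC
46vcc,caudal ventral area 46 caudal sector,frontal,prefrontal,pPFC
12rc,area 12r caudal sector,frontal,prefrontal,pPFC
10,frontal polar area 10,frontal,prefrontal,dmPFC
9m,medial area 9,frontal,prefrontal,dmPFC
9l,lateral area 9,frontal,prefrontal,dmPFC
32,medial prefrontal area 32,frontal,prefrontal,dmPFC
14,ventromedial orbitofrontal area 14 (with 13a/13b),frontal,prefrontal,dmPFC
46dr,rostral dorsal area 46,frontal,prefrontal,dmPFC
45A,prefrontal area 45A,frontal,prefrontal,dmPFC
11l,orbitofrontal area 11,frontal,orbitofrontal,voPFC
13lm,orbitofrontal area 13 (13l/13m),frontal,orbitofrontal,voPFC
12om,orbitofrontal area 12o/12m,frontal,orbitofrontal,voPFC
12l,area 12 lateral sector,frontal,orbitofrontal,voPFC
12rr,area 12r rostral and intermediate sectors,frontal,orbitofrontal,voPFC
46vcr,caudal ventral area 46 rostral sector,frontal,prefrontal,voPFC
46vr,rostral ventral area 46,frontal,prefrontal,voPFC
GrFO,granular frontal opercular area,frontal,orbitofrontal,voPFC
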