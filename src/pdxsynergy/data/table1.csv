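Name,Model,Mutation,Amplification,Fusion
HCC1143,Cell line,TP53 (c.743G>A),CCND1; FGF19; FGF3; KIT; MDM2; PDGFRA,
HCC1187,Cell line,BAP1 (c.781C>T); TP53 (c.322_324delGGT),TP53; CCND3,
MCF7,Cell line,PIK3CA (c.1633G>A),GNAS; RAD51C,ESR1-CCDC170
MDA231,Cell line,BRAF (c.1391G>T); KRAS (c.38G>A); NF1 (c.1398_1399insC); NF2 (c.691G>T); NOTCH3 (c.1102A>T); TERT (c.-124C>T); TP53 (c.839G>A),,
MDA453,Cell line,FGFR4 (c.1100A>G); PIK3CA (c.3140A>G); PTEN (c.919G>A),CCND1; ERBB2; MDM4,
MDA468,Cell line,PTEN (c.253+1G>T); TP53 (c.818G>A),CCNE1; EGFR,
SUM149,Cell line,BRCA1 (c.2169delT); NF1 (c.4195C>T); TP53 (c.711G>A),,
T47D,Cell line,ARID1A (c.2830C>T); PIK3CA (c.3140A>G); TP53 (c.580C>T),PIK3CA,
UCD115,Cell line,TP53 (c.892_911dupGAGCTGCCCCCAGGGAGCAC),ERCC2; MYC; ROS1,
UCD12,Cell line,BRCA2 (c.4943delC); PIK3CA (c.3140A>T),FGFR1; RAD51C,
UCD178,Cell line,NF1 (c.6322_6323insG),AKT3; MYC; NTRK1,SEC16A-NOTCH1
UCD4,Cell line,BRCA2 (c.1755_1759delGAAAA); ESR1 (c.1613A>G); RAD51B (c.246C>G),FANCD2; FGFR3; RAF1,
UCD46,Cell line,TP53 (c.281C>G),CCND2; PIK3CA,
UCD65,Cell line,NF1 (c.2372dupT); NOTCH2 (c.6403_6404delCT),CCND1; FGF19; FGF3; FGFR1; GNAS,
BCM0132,PDX,TP53* (c.524G>A),MYC; NTRK1,
BCM15034,PDX,NOTCH3 (c.1487_1488insT),ERBB2,
BCM15057,PDX,NOTCH1 (c.5402C>G); TP53 (c.438G>A); PIK3CA* (c.1624G>A),CCND1; FGFR1; MDM2,ESR1-CCDC170
BCM2147,PDX,PDGFRA (c.2471dupT),MYC,
BCM2277,PDX,NOTCH3 (c.3060dupC; n.-1413dupC); KRAS (c.182A>G),,
BCM3887,PDX,TP53* (c.438G>A); BRCA1 (c.5406+5G>T),,
BCM5097,PDX,BRCA2 (c.3545_3546delTT); NOTCH1* (c.3835C>T),,
BCM7482,PDX,BRCA1* (c.5177_5180delGAAA; c.650_653delGAAA); TP53* (c.586C>T); NF1 (c.925G>A),FLT3; RAF1; IGF1R,
BCM7821,PDX,TP53* (c.330_333delTCTG),CCNE1; MYC; PDGFRA; IGF1R,
HCI-001,PDX,BRCA2* (c.3847_3848delGT); TP53* (c.783delT); AR (c.1127C>T),AKT3; CCND3*; MYC*; NBN; ROS1*,
HCI-001CR,PDX,BRCA2 (c.3847_3861delGTAAGTGAAAAAAAT); TP53 (c.783delT),CCND3; MYC; ROS1,
HCI-008,PDX,PIK3CA (c.3140A>G); TP53 (c.818G>A),CCND1; EGFR; RAF1; ROS1,
HCI-009,PDX,PIK3CA (c.1624G>A),AKT1,SEC16A-NOTCH1
HCI-011,PDX,PIK3CA (c.1633G>A); TP53 (c.993+1G>T),FGFR1; GNAS,
HCI-013,PDX,ESR1 (c.1610A>C); PIK3CA (c.3140A>G),,
UCD52,PDX,TP53 (c.880G>T); PTEN (c.368A>C),PIK3CA,
UCD52CR,PDX,TP53* (c.880G>T); PTEN* (c.368A>C),KIT; KRAS*; MYC*; PDGFRA; PIK3CA*,
WHIM2,PDX,TP53 (c.497dupC),EGFR; KIT; NTRK1; PDGFRA; AKT3; AR; JAK2; MDM4,
WHIM30,PDX,TP53 (c.375+2T>A),NBN,
WHIM30CR,PDX,TP53 (c.375+2T>A),,
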