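abbreviation,name,hemisphere,lobe
PreCG.L,Precentral gyrus (left),L,Central
PreCG.R,Precentral gyrus (right),R,Central
SFGdor.L,Superior frontal gyrus; dorsolateral (left),L,Frontal
SFGdor.R,Superior frontal gyrus; dorsolateral (right),R,Frontal
ORBsup.L,Superior frontal gyrus; orbital part (left),L,Frontal
ORBsup.R,Superior frontal gyrus; orbital part (right),R,Frontal
MFG.L,Middle frontal gyrus (left),L,Frontal
MFG.R,Middle frontal gyrus (right),R,Frontal
ORBmid.L,Middle frontal gyrus; orbital part (left),L,Frontal
ORBmid.R,Middle frontal gyrus; orbital part (right),R,Frontal
IFGoperc.L,Inferior frontal gyrus; opercular part (left),L,Frontal
IFGoperc.R,Inferior frontal gyrus; opercular part (right),R,Frontal
IFGtriang.L,Inferior frontal gyrus; triangular part (left),L,Frontal
IFGtriang.R,Inferior frontal gyrus; triangular part (right),R,Frontal
ORBinf.L,Inferior frontal gyrus; orbital part (left),L,Frontal
ORBinf.R,Inferior frontal gyrus; orbital part (right),R,Frontal
ROL.L,Rolandic operculum (left),L,Central
ROL.R,Rolandic operculum (right),R,Central
SMA.L,Supplementary motor area (left),L,Frontal
SMA.R,Supplementary motor area (right),R,Frontal
OLF.L,Olfactory cortex (left),L,Frontal
OLF.R,Olfactory cortex (right),R,Frontal
SFGmed.L,Superior frontal gyrus; medial (left),L,Frontal
SFGmed.R,Superior frontal gyrus; medial (right),R,Frontal
ORBsupmed.L,Superior frontal gyrus; medial orbital (left),L,Frontal
ORBsupmed.R,Superior frontal gyrus; medial orbital (right),R,Frontal
REC.L,Gyrus rectus (left),L,Frontal
REC.R,Gyrus rectus (right),R,Frontal
INS.L,Insula (left),L,Limbic
INS.R,Insula (right),R,Limbic
ACG.L,Anterior cingulate and paracingulate gyri (left),L,Limbic
ACG.R,Anterior cingulate and paracingulate gyri (right),R,Limbic
DCG.L,Median cingulate and paracingulate gyri (left),L,Limbic
DCG.R,Median cingulate and paracingulate gyri (right),R,Limbic
PCG.L,Posterior cingulate gyrus (left),L,Limbic
PCG.R,Posterior cingulate gyrus (right),R,Limbic
HIP.L,Hippocampus (left),L,Limbic
HIP.R,Hippocampus (right),R,Limbic
PHG.L,Parahippocampal gyrus (left),L,Limbic
PHG.R,Parahippocampal gyrus (right),R,Limbic
AMYG.L,Amygdala (left),L,Subcortical-nuclei
AMYG.R,Amygdala (right),R,Subcortical-nuclei
CAL.L,Calcarine fissure and surrounding cortex (left),L,Occipital
CAL.R,Calcarine fissure and surrounding cortex (right),R,Occipital
CUN.L,Cuneus (left),L,Occipital
CUN.R,Cuneus (right),R,Occipital
LING.L,Lingual gyrus (left),L,Occipital
LING.R,Lingual gyrus (right),R,Occipital
SOG.L,Superior occipital gyrus (left),L,Occipital
SOG.R,Superior occipital gyrus (right),R,Occipital
MOG.L,Middle occipital gyrus (left),L,Occipital
MOG.R,Middle occipital gyrus (right),R,Occipital
IOG.L,Inferior occipital gyrus (left),L,Occipital
IOG.R,Inferior occipital gyrus (right),R,Occipital
FFG.L,Fusiform gyrus (left),L,Occipital
FFG.R,Fusiform gyrus (right),R,Occipital
PoCG.L,Postcentral gyrus (left),L,Central
PoCG.R,Postcentral gyrus (right),R,Central
SPG.L,Superior parietal gyrus (left),L,Parietal
SPG.R,Superior parietal gyrus (right),R,Parietal
IPL.L,Inferior parietal; but supramarginal and angular gyri (left),L,Parietal
IPL.R,Inferior parietal; but supramarginal and angular gyri (right),R,Parietal
SMG.L,Supramarginal gyrus (left),L,Parietal
SMG.R,Supramarginal gyrus (right),R,Parietal
ANG.L,Angular gyrus (left),L,Parietal
ANG.R,Angular gyrus (right),R,Parietal
PCUN.L,Precuneus (left),L,Parietal
PCUN.R,Precuneus (right),R,Parietal
PCL.L,Paracentral lobule (left),L,Frontal
PCL.R,Paracentral lobule (right),R,Frontal
CAU.L,Caudate nucleus (left),L,Subcortical-nuclei
CAU.R,Caudate nucleus (right),R,Subcortical-nuclei
PUT.L,Lenticular nucleus; putamen (left),L,Subcortical-nuclei
PUT.R,Lenticular nucleus; putamen (right),R,Subcortical-nuclei
PAL.L,Lenticular nucleus; pallidum (left),L,Subcortical-nuclei
PAL.R,Lenticular nucleus; pallidum (right),R,Subcortical-nuclei
THA.L,Thalamus (left),L,Subcortical-nuclei
THA.R,Thalamus (right),R,Subcortical-nuclei
HES.L,Heschl gyrus (left),L,Temporal
HES.R,Heschl gyrus (right),R,Temporal
STG.L,Superior temporal gyrus (left),L,Temporal
STG.R,Superior temporal gyrus (right),R,Temporal
TPOsup.L,Temporal pole: superior temporal gyrus (left),L,Limbic
TPOsup.R,Temporal pole: superior temporal gyrus (right),R,Limbic
MTG.L,Middle temporal gyrus (left),L,Temporal
MTG.R,Middle temporal gyrus (right),R,Temporal
TPOmid.L,Temporal pole: middle temporal gyrus (left),L,Limbic
TPOmid.R,Temporal pole: middle temporal gyrus (right),R,Limbic
ITG.L,Inferior temporal gyrus (left),L,Temporal
ITG.R,Inferior temporal gyrus (right),R,Temporal
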