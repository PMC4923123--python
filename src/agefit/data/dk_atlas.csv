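region,group,paired,in_profile,fs_name
Superior Frontal,Frontal,1,1,superiorfrontal
Rostral Middle Frontal,Frontal,1,1,rostralmiddlefrontal
Caudal Middle Frontal,Frontal,1,1,caudalmiddlefrontal
Pars Opercularis,Frontal,1,1,parsopercularis
Pars Triangularis,Frontal,1,1,parstriangularis
Pars Orbitalis,Frontal,1,1,parsorbitalis
Lateral Orbitofrontal,Frontal,1,1,lateralorbitofrontal
Medial Orbitofrontal,Frontal,1,1,medialorbitofrontal
Frontal Pole,Frontal,1,1,frontalpole
Precentral,Frontal,1,1,precentral
Paracentral,Frontal,1,1,paracentral
Superior Temporal,Temporal,1,1,superiortemporal
Middle Temporal,Temporal,1,1,middletemporal
Inferior Temporal,Temporal,1,1,inferiortemporal
Banks of the STS,Temporal,1,1,bankssts
Fusiform,Temporal,1,1,fusiform
Transverse Temporal,Temporal,1,1,transversetemporal
Entorhinal,Temporal,1,1,entorhinal
Temporal Pole,Temporal,1,1,temporalpole
Parahippocampal,Temporal,1,1,parahippocampal
Superior Parietal,Parietal,1,1,superiorparietal
Inferior Parietal,Parietal,1,1,inferiorparietal
Supramarginal,Parietal,1,1,supramarginal
Postcentral,Parietal,1,1,postcentral
Precuneus,Parietal,1,1,precuneus
Lateral Occipital,Occipital,1,1,lateraloccipital
Lingual,Occipital,1,1,lingual
Cuneus,Occipital,1,1,cuneus
Pericalcarine,Occipital,1,1,pericalcarine
Insula,Insula,1,1,insula
Rostral Anterior Cingulate,Cingulate,1,1,rostralanteriorcingulate
Caudal Anterior Cingulate,Cingulate,1,1,caudalanteriorcingulate
Posterior Cingulate,Cingulate,1,1,posteriorcingulate
Isthmus Cingulate,Cingulate,1,1,isthmuscingulate
CC Posterior,Corpus Callosum,0,1,CC_Posterior
CC Mid-Posterior,Corpus Callosum,0,1,CC_Mid_Posterior
CC Central,Corpus Callosum,0,1,CC_Central
CC Mid-Anterior,Corpus Callosum,0,1,CC_Mid_Anterior
CC Anterior,Corpus Callosum,0,1,CC_Anterior
Hippocampus,Subcortical,1,1,Hippocampus
Amygdala,Subcortical,1,1,Amygdala
Caudate,Subcortical,1,1,Caudate
Putamen,Subcortical,1,1,Putamen
Pallidum,Subcortical,1,1,Pallidum
Accumbens,Subcortical,1,1,Accumbens-area
Thalamus Proper,Subcortical,1,1,Thalamus-Proper
Brain-Stem,Subcortical,0,1,Brain-Stem
Ventral Diencephalon,Subcortical,1,1,VentralDC
Lateral Ventricle,Ventricle,1,0,Lateral-Ventricle
Inferior Lateral Ventricle,Ventricle,1,0,Inf-Lat-Vent
3rd Ventricle,Ventricle,0,0,3rd-Ventricle
4th Ventricle,Ventricle,0,0,4th-Ventricle
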