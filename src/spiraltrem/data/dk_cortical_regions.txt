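# Desikan-Killiany cortical region base names (34 per hemisphere).
# Fine-grained ~500 mm^2 parcels are named <hemi>_<region>_part<N>;
# thickness tables prefix the region with ct_ (e.g. lh_ct_precentral_part7).
bankssts
caudalanteriorcingulate
caudalmiddlefrontal
cuneus
entorhinal
frontalpole
fusiform
inferiorparietal
inferiortemporal
insula
isthmuscingulate
lateraloccipital
lateralorbitofrontal
lingual
medialorbitofrontal
middletemporal
paracentral
parahippocampal
parsopercularis
parsorbitalis
parstriangularis
pericalcarine
postcentral
posteriorcingulate
precentral
precuneus
rostralanteriorcingulate
rostralmiddlefrontal
superiorfrontal
superiorparietal
superiortemporal
supramarginal
temporalpole
transversetemporal
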