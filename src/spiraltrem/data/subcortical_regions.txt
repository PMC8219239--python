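# Subcortical structure base names (prefixed lh_/rh_ in tables).
Thalamus
Caudate
Putamen
Pallidum
Hippocampus
Amygdala
Accumbens
VentralDC
Cerebellum_White_Matter
Cerebellum_Cortex
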