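# Yeo 7-network base names as used for cerebellar network volumes
# (prefixed lh_/rh_ in tables).
Visual
Somato_Motor
Dorsal_Attention
Ventral_Attention
Limbic
Control
Default
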