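# Yeo 17-network base names (prefixed lh_/rh_ in tables).
Visual_A
Visual_B
Somato_Motor_A
Somato_Motor_B
Dorsal_Attention_A
Dorsal_Attention_B
Ventral_Attention_A
Ventral_Attention_B
Limbic_A
Limbic_B
Control_A
Control_B
Control_C
Default_A
Default_B
Default_C
Temporal_Parietal
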