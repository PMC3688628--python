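state,NO_COMPONENT,ISO_ABDOMINAL_OBESITY,ISO_HIGH_TG,ISO_LOW_HDL,ISO_HIGH_BP,ISO_HIGH_FPG,TWO_COMPONENT,METS
NO_COMPONENT,92.82,1.67,0.32,2.73,0.41,0.16,1.49,0.41
ISO_ABDOMINAL_OBESITY,2.22,85.42,0.00,0.27,0.01,0.01,6.39,5.70
ISO_HIGH_TG,5.58,1.27,80.28,5.58,0.63,0.01,4.05,2.62
ISO_LOW_HDL,10.24,0.66,0.11,85.23,0.54,0.01,3.11,0.54
ISO_HIGH_BP,4.23,0.01,0.79,2.44,83.91,0.01,6.19,2.44
ISO_HIGH_FPG,6.70,5.19,0.59,2.44,0.59,80.81,3.10,0.59
TWO_COMPONENT,4.82,1.55,0.17,1.73,0.85,0.01,86.67,4.21
METS,0.45,0.90,0.22,1.13,0.45,0.45,4.10,92.31
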