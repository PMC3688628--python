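state,NO_COMPONENT,ISO_ABDOMINAL_OBESITY,ISO_HIGH_TG,ISO_LOW_HDL,ISO_HIGH_BP,ISO_HIGH_FPG,TWO_COMPONENT,METS
NO_COMPONENT,92.89,0.91,1.08,0.74,1.99,0.20,1.73,0.45
ISO_ABDOMINAL_OBESITY,2.16,86.77,0.35,0.70,0.35,0.01,6.76,2.93
ISO_HIGH_TG,4.65,0.25,84.35,0.25,0.75,0.25,6.89,2.62
ISO_LOW_HDL,12.89,0.01,0.32,79.64,2.31,0.01,3.02,1.63
ISO_HIGH_BP,6.10,0.32,0.64,0.96,85.66,0.64,3.38,2.31
ISO_HIGH_FPG,11.29,0.90,1.84,0.00,1.84,79.41,3.84,0.90
TWO_COMPONENT,2.27,1.29,1.17,0.69,0.81,0.58,86.33,6.87
METS,0.52,0.65,0.26,0.13,0.91,0.26,6.14,91.14
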