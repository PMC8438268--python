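material,H,C,N,O,Na,Mg,P,S,Cl,Ar,K,Ca
air,0.0,0.00012,0.75527,0.23178,0.0,0.0,0.0,0.0,0.0,0.01283,0.0,0.0
lung,0.103,0.107,0.032,0.746,0.002,0.0,0.002,0.003,0.003,0.0,0.002,0.0
fat,0.1196,0.7687,0.0,0.1117,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
adipose,0.114,0.588,0.008,0.287,0.001,0.0,0.0,0.001,0.001,0.0,0.0,0.0
soft tissue,0.104,0.231,0.028,0.627,0.001,0.0,0.002,0.003,0.002,0.002,0.0,0.0
muscle,0.102,0.142,0.034,0.711,0.001,0.0,0.002,0.003,0.001,0.0,0.004,0.0
bone-scapula,0.087,0.309,0.026,0.483,0.002,0.001,0.030,0.004,0.002,0.0,0.0,0.056
bone-mineral,0.036,0.159,0.042,0.448,0.003,0.002,0.094,0.003,0.0,0.0,0.0,0.213
tooth,0.022,0.095,0.029,0.421,0.0,0.007,0.137,0.0,0.0,0.0,0.0,0.289
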