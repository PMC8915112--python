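subject_id,group,CQ,OQ,SQ,MRGA
N1,normophonic,0.36,0.81,1.25,0.23
N2,normophonic,0.36,0.61,0.72,0.05
N3,normophonic,0.37,0.65,0.76,0.00
N4,normophonic,0.48,0.81,0.69,0.09
N5,normophonic,0.42,0.67,0.62,0.01
N6,normophonic,0.49,0.78,0.57,0.22
N7,normophonic,0.40,0.76,0.90,0.01
N8,normophonic,0.13,0.26,1.08,0.00
N9,normophonic,0.45,0.69,0.53,0.17
N10,normophonic,0.38,0.66,0.74,0.06
N11,normophonic,0.49,0.77,0.59,0.20
D1,dysphonic,0.49,1,1.04,0.33
D2,dysphonic,0.53,1,0.89,0.60
D3,dysphonic,0.54,1,0.85,0.52
D4,dysphonic,0.49,1,1.04,0.52
D5,dysphonic,0.55,0.92,0.67,0.01
D6,dysphonic,0.47,0.92,0.96,0.03
D7,dysphonic,0.47,0.95,1.02,0.30
D8,dysphonic,0.48,1,1.08,0.69
D9,dysphonic,0.49,1,1.04,0.40
D10,dysphonic,0.52,1,0.92,0.35
D11,dysphonic,0.53,0.93,0.77,0.05
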