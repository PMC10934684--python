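subject_id,group,steps_sSC,steps_SC
N1,T,105,68
N2,T,119,68
N3,T,129,69
N4,T,113,68
N5,T,76,68
N6,T,103,68
N7,T,110,67
N8,T,124,69
N9,T,134,67
N10,T,119,69
N11,T,137,68
N12,T,131,67
N13,O,72,69
N14,O,93,68
N15,O,89,67
N16,O,106,69
N17,O,91,69
N18,O,81,69
N19,O,99,68
N20,O,84,67
N21,O,79,67
N22,O,65,68
N23,O,78,68
N24,O,124,68
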