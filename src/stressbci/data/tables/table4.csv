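participant,group,lstm2_accuracy,stai_c
L2,ASD,92.83,37
L3,ASD,92.83,32
L4,ASD,93.72,24
L5,ASD,93.69,30
L6,ASD,92.57,33
L7,ASD,93.72,32
L8,ASD,93.97,46
T1,neurotypical,92.83,25
T2,neurotypical,93.08,37
T4,neurotypical,93.47,42
T5,neurotypical,93.24,28
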