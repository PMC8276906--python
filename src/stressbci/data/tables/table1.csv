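participant,guided_vs_stressor,baseline_vs_stressor,unguided_vs_guided,unguided_vs_stressor
L2,98.75,97.92,100.00,96.30
L3,80.00,95.83,75.00,80.56
L4,68.75,91.67,70.00,75.93
L5,81.25,91.67,87.50,77.78
L6,67.50,81.25,57.50,71.30
L7,87.50,81.25,97.50,90.74
L8,90.00,93.75,86.25,70.37
T1,90.00,93.75,76.25,71.30
T2,83.75,89.58,91.25,83.33
T4,72.50,79.17,73.75,69.44
T5,65.00,70.83,71.25,74.04
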