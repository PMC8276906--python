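class,deep_convnet,shallow_convnet,eegnet
stressor,60.73,49.14,59.31
unguided,59.38,56.25,60.38
guided,53.76,81.07,59.99
baseline,61.34,64.90,61.18
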