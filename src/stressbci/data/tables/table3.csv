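class,lstm1,lstm2,lstm3,lstm_fcn
stressor,63.95,90.82,74.75,57.19
unguided,62.89,91.19,70.43,57.52
guided,80.09,94.57,67.76,72.32
baseline,73.53,96.50,76.07,64.84
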