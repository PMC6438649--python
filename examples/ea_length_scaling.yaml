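# Elitist crossing times on a shortcut-free segment vs dimension n
valley: {l1: 2, l2: 2, d1: 1.0, d2: 2.0}   # effective length 3
ns: [16, 24, 32, 48]
replicates: 400
seed: 1
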