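# Exact crossing times of m concatenated valleys (linearity in m)
valley: {l1: 2, l2: 2, d1: 2.0, d2: 4.0}
rule: {algo: sswm, beta: 1.0, N: 2}
ms: [1, 2, 3, 4, 5, 6, 7, 8]
seed: 0
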