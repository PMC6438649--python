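# Chain-mode Monte Carlo vs the exact linear solve
valley: {l1: 2, l2: 2, d1: 2.0, d2: 4.0}
rule: {algo: sswm, beta: 1.0, N: 2}
n: 16
k: 8
replicates: 800
seed: 5
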