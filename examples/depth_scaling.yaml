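# Exact depth-scaling study: slope of ln E(T) against valley depth d1
valley: {l1: 4, l2: 4, d1: 4.0, d2: 5.0}   # d1 is overridden by the grid, d2 = d1 + 1
rule: {algo: sswm, beta: 1.0, N: 2}
d1_grid: [4.0, 6.0, 8.0, 10.0, 12.0]
seed: 0
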