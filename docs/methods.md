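# Methods

## The process being modelled

All three algorithms are instances of one loop: keep a single current search
point `x`; propose a mutant `y = mutate(x)`; accept (`x ← y`) with probability
`p_acc(f(y) − f(x))`; repeat. One proposal = one function evaluation. The
rules differ only in `mutate` and `p_acc`:

| rule       | mutation                | `p_acc(Δf)` for `Δf ≥ 0` | for `Δf < 0` |
|------------|-------------------------|--------------------------|--------------|
| elitist    | every bit w.p. `1/n`    | 1                        | 0            |
| Metropolis | one uniform bit         | 1                        | `e^{αΔf}`    |
| SSWM       | one uniform bit         | `p_fix(Δf)`              | `p_fix(Δf)`  |

`p_fix(Δf) = (1 − e^{−2βΔf}) / (1 − e^{−2NβΔf})` is the Kimura fixation
probability of a mutant with selective advantage `βΔf` appearing in one copy
in a population of `N` individuals; the loop is the macro-view of strong
selection / weak mutation evolution, where each iteration is the appearance
and fate of one mutation. `N` is a parameter of the acceptance function, not
an explicit population. Tie-breaks follow each rule's definition exactly:
elitist and Metropolis accept ties with probability 1, SSWM with `1/N` (the
defined `Δf → 0` limit).

## Landscapes

Long k-paths give a one-dimensional landscape with no positional mutation
bias: every interior point has exactly one on-path Hamming neighbour in each
direction, so local mutation proposes "forward" and "backward" with the same
probability `1/n` regardless of position. Shortcuts need `≥ k` simultaneous
flips (probability `≤ 1/k!`), so for the simulated segment sizes the path is
effectively shortcut-free; the segment-jump mode makes this exact by
requiring `k` larger than the segment.

Heights are assigned to a prefix of the path (Valley or ValleyPath profiles,
see the README for the formulas); all other strings map to a distinguished
off-path sentinel object, rejected with probability exactly 0 by every rule —
a sentinel rather than a large negative float so that `e^{αΔf}` cannot leak a
subnormal acceptance probability. Heights are double precision; no rational
mode is provided, as every tested comparison has tolerance ≥ 1e−12 and slopes
are ratios of small numbers.

The ValleyPath formula indexes valleys `1 … m`, which places the first peak
at height `d2` rather than `d1`; the constant offset cancels from every
fitness difference, so the dynamics are unaffected. Boundary points between
valleys belong to both; the flattener resolves the ambiguity by the clamped
`⌈g/ℓ⌉` rule, which is value-irrelevant because the shared heights coincide.

## Reduction to relevant steps

Conditional on proposing an on-path neighbour (a *relevant step*), the
direction is uniform; all other proposals are rejected (off-path) or leave
the state unchanged. The on-path dynamics is therefore a birth–death chain:
per relevant step, up and down are each proposed with probability ½ and
accepted with `p_acc(Δh)`; the two path ends get a ½ self-loop for the
missing direction. Expected function evaluations = `n/2 ×` expected relevant
steps.

In full bitstring mode relevant steps are *counted*, not assumed: a proposal
decoding to index ±1 counts, and at an end state a proposal flipping one
fixed designated extra position also counts (standing in for the reduced
chain's self-loop proposal), so the relevant rate is exactly `2/n` in every
state and the `n/2` conversion emerges from the run rather than being
hard-coded.

## Exact analysis

On a linear slope the chain's transition probabilities are
position-independent, so first passages are Gambler's Ruin games with
self-loops: per round player 1 wins a dollar w.p. `p1`, loses w.p. `p2`,
nothing happens otherwise. Win probability is the classic
`(1 − (p2/p1)^{n1}) / (1 − (p2/p1)^{n1+n2})` (`n1/(n1+n2)` when `p1 = p2`),
unaffected by self-loops. The expected duration is
`n1·n2/(p1+p2)` when `p1 = p2` and `(n1 − (n1+n2)P1)/(p2 − p1)` otherwise —
the classic formula evaluated at the raw (unnormalised) probabilities already
incorporates the self-loop waiting time, as the package's linear-solve
regression tests confirm; the formula is homogeneous of degree −1 in
`(p1, p2)`.

The expected descent time from one step inside the valley to the bottom
decomposes as `E(T) = (E_GR + P_lose/p_peak→slope) / P_win`: a ruin game on
the slope (one dollar versus `ℓ1 − 1`) plus geometric restarts through the
starting peak. This closed form equals the first-step linear solve to
~1e−12 across the tested grid and remains correct far beyond the regime
where a float64 linear solve is meaningful (descent times up to e^several
hundred).

At an interior ValleyPath peak, the probabilities of first reaching the
left/right minimum (and, from a minimum, the left/right peak) determine the
drift in the number of remaining peaks. For any rule with
`p_acc(Δf)/p_acc(−Δf) = e^{λΔf}` (SSWM: `λ = 2β(N−1)`; Metropolis:
`λ = α`), the product ratio collapses to `e^{−λ(d2−d1)}` exactly; the
advance probability is `1/(1 + ratio)` and the drift `2·advance − 1`.

### Numerical choices

* SSWM acceptance, ratios and ruin powers are evaluated in log space with
  `expm1`/`log1p`; the `Δf = 0` limit `1/N` is returned below
  `|2NβΔf| < 1e−12`. Accuracy vs a 50-digit reference is ~1e−14 relative up
  to the float64 overflow edge (`|2NβΔf| ≈ 700`).
* The ruin equal-probability branch is taken when
  `|p1 − p2| ≤ 1e−12 (p1 + p2)`; the unequal branch uses the `expm1` form of
  the power ratio, which stays accurate arbitrarily close to the switch.
* Two-boundary absorption splits on birth–death chains use the closed-form
  harmonic sums (cumulative log `down/up` ratios + log-sum-exp of both
  tails), preserving relative accuracy for probabilities as small as
  1e−300; the sparse first-step solve is the general fallback and the
  independent cross-check in moderate regimes. General hitting times use the
  sparse solve with explicit reachability checks (an unreachable target
  raises rather than returning a garbage expectation); chains are capped at
  1e5 states.
* Self-loops are kept explicit in every chain; they are never renormalised
  away, because durations depend on them while absorption probabilities do
  not — both facts are regression-tested.

## Simulation modes and their equivalences

* **bitstring** — the process as defined; exact but `O(E(T_f))` work.
* **chain** — the reduced relevant-step process on the height profile;
  exact for local mutations, and the designated mode for SSWM/Metropolis
  experiments.
* **segment-jump** — the elitist algorithm on a shortcut-free segment,
  where a jump by `i` positions has probability `n^{−i}(1−1/n)^{n−i}` per
  direction. Simulated as the embedded jump chain with geometric waiting
  times between accepted moves: identical in distribution for the
  evaluation count, at the cost of the accepted moves only (orders of
  magnitude faster, which is what makes the length-scaling study cheap).

Reproducibility: every run takes a single integer seed; replicate `r` of a
batch uses `seed + r`. Identical seed and configuration give bit-identical
results. Budget exhaustion is a reported outcome (`hit_optimum = False`),
never an exception, so scaling sweeps can censor.

## Experiments: conditions and sizes

Asymptotic side conditions of the form "the scaled gradient is at least a
constant" are instantiated as `β d/ℓ ≥ 0.5` (resp. `α d/ℓ ≥ 0.5`) and
checked per grid cell; out-of-regime cells are reported with the reason,
never silently dropped. The drift condition for ValleyPath linearity is
instantiated as `λ(d2 − d1) ≥ 1`.

Problem sizes were chosen so every study runs on a laptop in minutes while
the fitted quantities are stable:

* length law: Valley(2, 2, 1, 2) (effective length 3), `n ∈ {16, 24, 32,
  48}`, 400 replicates per `n` — the fitted log-log slope is 3.0–3.2 with
  standard error ≈ 0.1 across seeds;
* depth law: exact solves (no sampling noise), `ℓ1 = ℓ2 = 4`,
  `d1 ∈ {4, …, 12}`, `d2 = d1 + 1`;
* ValleyPath: exact solves for `m ∈ {1, …, 8}`;
* cross-mode agreement: `n = 16`, `k = 8` (or `k = n` for the elitist
  comparison), 300–2000 replicates, three-standard-error bands.

Exact solves are preferred wherever the quantity is a chain functional;
Monte Carlo is reserved for the elitist jump process and cross-mode
validation.

## What the generators do and do not emulate

The landscapes are exactly the idealised objects of the theory: linear
slopes, equal-sized valleys, fitness differences depending only on path
distance. Passing tests therefore validate the mathematics and the
implementation, not the behaviour of these algorithms on real combinatorial
landscapes, where slopes are irregular, valleys heterogeneous, and off-path
moves are not uniformly catastrophic. The ValleyPath flattener is written to
admit heterogeneous valleys later, but the analysis layer asserts identical
valleys.

## Known limitations

* SSWM is implemented with local mutations only; the combination of
  non-elitism with global mutations is out of scope.
* No populations beyond the `N` parameter of the acceptance rule, no
  crossover, no restarts, no temperature schedules (constant `α` only).
* The elitist rule in chain mode cannot cross a valley (every downhill
  acceptance is 0); the hitting-time solver raises an unreachable-target
  error rather than returning infinity.
* Paths start at the first point; embedding the path into a larger search
  space with hints guiding random initialisation to the start is not
  implemented.
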