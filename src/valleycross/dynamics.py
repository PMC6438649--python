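"""Trajectory simulation: the single-individual mutate/accept loop.

Three execution modes cover the same underlying process at different levels of
reduction:

* ``bitstring``: the full process on bit strings.  Mutants are proposed by a
  mutation operator (single uniform bit flip, or independent per-bit flips
  with rate 1/n), evaluated through the path-embedded fitness, and accepted
  with the rule's probability of the fitness difference.  Off-path mutants
  cost an evaluation and are always rejected.
* ``chain``: the reduced relevant-step process on a height profile -- per step
  propose up or down with probability 1/2 each (self-loop at the two ends),
  accept with the rule's probability.  Exact for local mutations; expected
  function evaluations are ``n/2`` times the expected relevant steps, the
  waiting time for a local mutation to propose a path neighbour.
* ``segment-jump``: the elitist algorithm on a shortcut-free path segment
  (fold ``k`` larger than the segment), where a standard-bit-mutation jump by
  ``i`` positions has probability ``n^-i (1 - 1/n)^(n-i)`` in each direction.
  Simulated as the embedded jump chain with geometric waiting times between
  accepted moves, which is exact in distribution for the evaluation count.

Relevant-step counting in bitstring mode mirrors the reduction: a proposal of
an on-path neighbour counts, and at the two end states -- where the reduced
chain has a 1/2 self-loop in place of the missing neighbour -- a proposal
flipping one fixed designated extra position also counts, so that relevant
steps occur at rate exactly ``2/n`` in every state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .acceptance import AcceptanceRule, accept_probability
from .exact_analysis import build_valley_chain
from .landscapes import ValleySpec, valley_heights
from .longpath import OFF_PATH, OffPath, PathFitness

__all__ = [
    "SimulationConfig",
    "RunResult",
    "InvalidStartError",
    "mutate_local",
    "mutate_global",
    "run",
    "run_replicates",
    "run_chain",
    "run_segment_jump",
    "jump_distance_pmf",
]

MODES = ("bitstring", "chain", "segment-jump")


class InvalidStartError(ValueError):
    """The start string is not on the fitness-carrying path."""


class InvalidModeError(ValueError):
    """The requested mode is not valid for the given landscape geometry."""


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration: mode, evaluation budget, RNG seed, replicate count.

    The budget counts function evaluations in bitstring and segment-jump
    modes and relevant steps in chain mode.  Replicate ``r`` uses
    ``seed + r``; exceeding the budget is a reported outcome, not an error.
    """

    mode: str = "bitstring"
    max_evaluations: int = 10**8
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidModeError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.max_evaluations < 0:
            raise ValueError("budget must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class RunResult:
    """Outcome of one run.

    ``final_index`` is the path index of the final search point (or the
    off-path sentinel).  In chain mode ``function_evaluations`` equals the
    relevant-step count unless a dimension ``n`` was supplied for the
    ``n/2`` conversion.
    """

    function_evaluations: int
    relevant_steps: int
    hit_optimum: bool
    final_index: Union[int, OffPath]
    seed: int


def mutate_local(bits: str, rng: np.random.Generator) -> str:
    """Flip a single position chosen uniformly at random."""
    if not bits:
        raise ValueError("bit string must be non-empty")
    pos = int(rng.integers(len(bits)))
    flipped = "1" if bits[pos] == "0" else "0"
    return bits[:pos] + flipped + bits[pos + 1 :]


def mutate_global(bits: str, rng: np.random.Generator) -> str:
    """Flip each position independently with probability ``1/n``."""
    if not bits:
        raise ValueError("bit string must be non-empty")
    n = len(bits)
    mask = rng.random(n) < 1.0 / n
    if not mask.any():
        return bits
    chars = list(bits)
    for pos in np.flatnonzero(mask):
        chars[pos] = "1" if chars[pos] == "0" else "0"
    return "".join(chars)


def _flip(bits: str, pos: int) -> str:
    flipped = "1" if bits[pos] == "0" else "0"
    return bits[:pos] + flipped + bits[pos + 1 :]


def _end_state_positions(fitness: PathFitness) -> dict[int, tuple[int, int]]:
    """For each end state: (position flipping to the real neighbour, designated
    extra position counted as the reduced chain's self-loop proposal)."""
    out: dict[int, tuple[int, int]] = {}
    if fitness.m < 2:
        return out
    for end, nbr in ((0, 1), (fitness.m - 1, fitness.m - 2)):
        a, b = fitness.point(end), fitness.point(nbr)
        real = next(i for i in range(len(a)) if a[i] != b[i])
        out[end] = (real, 0 if real != 0 else 1)
    return out


def run(
    fitness: PathFitness,
    start: str,
    rule: AcceptanceRule,
    mutation: Union[str, Callable[[str, np.random.Generator], str]] = "local",
    config: SimulationConfig = SimulationConfig(),
) -> RunResult:
    """Full bitstring-mode run of the mutate/accept loop.

    Iterates until the fitness profile's optimum point is current or the
    evaluation budget is exhausted.  ``mutation`` is ``"local"``,
    ``"global"``, or any callable ``(bits, rng) -> bits``.
    """
    rng = np.random.default_rng(config.seed)
    ci = fitness.index(start)
    if ci is OFF_PATH:
        raise InvalidStartError("start must be on the fitness-carrying path")
    local = mutation == "local"
    if isinstance(mutation, str):
        if mutation not in ("local", "global"):
            raise ValueError(f"unknown mutation {mutation!r}")
        mutate = None  # fast inline paths below
    else:
        mutate = mutation
    h = fitness.heights
    n = fitness.spec.n
    opt = fitness.optimum_index
    end_pos = _end_state_positions(fitness) if local else {}
    cur = start
    evals = 0
    rel = 0
    while ci != opt and evals < config.max_evaluations:
        pos = -1
        if mutate is not None:
            y = mutate(cur, rng)
        elif local:
            pos = int(rng.integers(n))
            y = _flip(cur, pos)
        else:
            y = mutate_global(cur, rng)
        evals += 1
        yi = fitness.index(y)
        if yi is not OFF_PATH and abs(yi - ci) == 1:
            rel += 1
        elif local and ci in end_pos and pos == end_pos[ci][1]:
            rel += 1  # the reduced chain's end-state self-loop proposal
        delta = OFF_PATH if yi is OFF_PATH else h[yi] - h[ci]
        p = accept_probability(rule, delta)
        if p >= 1.0:
            accepted = True
        elif p <= 0.0:
            accepted = False
        else:
            accepted = rng.random() < p
        if accepted:
            cur, ci = y, yi
    return RunResult(
        function_evaluations=evals,
        relevant_steps=rel,
        hit_optimum=ci == opt,
        final_index=ci,
        seed=config.seed,
    )


def run_replicates(
    runner: Callable[[SimulationConfig], RunResult], config: SimulationConfig
) -> list[RunResult]:
    """Run ``config.replicates`` independent replicates; replicate ``r`` uses
    seed ``config.seed + r`` (stable across releases)."""
    out = []
    for r in range(config.replicates):
        rep_cfg = SimulationConfig(
            mode=config.mode,
            max_evaluations=config.max_evaluations,
            seed=config.seed + r,
            replicates=1,
        )
        out.append(runner(rep_cfg))
    return out


def run_chain(
    heights: Sequence[float],
    rule: AcceptanceRule,
    config: SimulationConfig = SimulationConfig(mode="chain"),
    n: Optional[int] = None,
    start: int = 0,
) -> RunResult:
    """Reduced relevant-step run on a height profile.

    Per step: propose up or down with probability 1/2 (out-of-range
    proposals are the end self-loops), accept with the rule's probability of
    the height difference.  The budget counts relevant steps; when ``n`` is
    given, ``function_evaluations`` reports the ``n/2`` conversion.
    """
    h = np.asarray(heights, dtype=float)
    if h.size < 1:
        raise ValueError("heights must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = int(np.flatnonzero(h == h.max())[-1]) if h.size > 1 else 0
    if h.size == 1:
        return RunResult(0, 0, True, 0, config.seed)
    chain = build_valley_chain(h, rule)
    # acceptance probability conditional on the direction being proposed
    p_up = np.minimum(2.0 * chain.up, 1.0)
    p_down = np.minimum(2.0 * chain.down, 1.0)
    s = start
    steps = 0
    while s != opt and steps < config.max_evaluations:
        steps += 1
        if rng.random() < 0.5:
            t, pa = s + 1, p_up[s]
        else:
            t, pa = s - 1, p_down[s]
        if pa >= 1.0 or (pa > 0.0 and rng.random() < pa):
            s = t
    evals = steps if n is None else int(round(steps * n / 2))
    return RunResult(
        function_evaluations=evals,
        relevant_steps=steps,
        hit_optimum=s == opt,
        final_index=s,
        seed=config.seed,
    )


def jump_distance_pmf(n: int, max_dist: int) -> np.ndarray:
    """P(standard bit mutation jumps exactly ``i`` path positions), i=0..max.

    ``n^-i (1 - 1/n)^(n-i)`` for one fixed direction (``i >= 1``); index 0 is
    the no-flip probability ``(1 - 1/n)^n``.  Valid on shortcut-free
    segments, where the only mutation reaching the point ``i`` steps away
    flips exactly the ``i`` differing bits.
    """
    i = np.arange(max_dist + 1)
    return n**(-i.astype(float)) * (1.0 - 1.0 / n) ** (n - i)


def run_segment_jump(
    spec: ValleySpec,
    n: int,
    config: SimulationConfig = SimulationConfig(mode="segment-jump"),
    k: Optional[int] = None,
) -> RunResult:
    """Elitist run on a shortcut-free Valley segment, by jump-chain simulation.

    Requires ``k > l1 + l2`` (all pairwise Hamming distances on the segment
    equal index differences, so the jump distribution is exact).  Per
    evaluation the mutant is ``i`` positions away with probability
    ``n^-i (1-1/n)^(n-i)`` per direction; the elitist rule accepts iff the
    height does not decrease.  The simulation samples the geometric waiting
    time to the next accepted move and then the move itself -- identical in
    distribution to per-evaluation sampling, at the cost of the moves only.
    """
    if k is None:
        k = n
    if k <= spec.length:
        raise InvalidModeError(
            f"segment-jump needs fold k > valley length {spec.length}, got k={k}"
        )
    if n % k != 0:
        raise InvalidModeError(f"k={k} must divide n={n}")
    if n < spec.length:
        raise InvalidModeError(f"path of dimension n={n} too short for the valley")
    h = valley_heights(spec)
    L = spec.length
    pmf = jump_distance_pmf(n, L)
    # per-state acceptable targets and their proposal probabilities
    targets: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    total: list[float] = []
    for s in range(L + 1):
        ts = np.array([t for t in range(L + 1) if t != s and h[t] >= h[s]], dtype=int)
        ps = pmf[np.abs(ts - s)]
        targets.append(ts)
        probs.append(ps / ps.sum() if ps.size else ps)
        total.append(float(ps.sum()))
    rng = np.random.default_rng(config.seed)
    s = 0
    evals = 0
    hit = False
    while True:
        if s == L:
            hit = True
            break
        if total[s] <= 0.0:  # no acceptable move: stuck until budget runs out
            evals = config.max_evaluations
            break
        g = int(rng.geometric(total[s]))
        if evals + g > config.max_evaluations:
            evals = config.max_evaluations
            break
        evals += g
        s = int(rng.choice(targets[s], p=probs[s]))
    return RunResult(
        function_evaluations=evals,
        relevant_steps=0,
        hit_optimum=hit,
        final_index=s,
        seed=config.seed,
    )
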