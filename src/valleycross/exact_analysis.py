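"""Exact first-passage analysis: Gambler's Ruin with self-loops, birth-death
chains, and ValleyPath peak drift.

The reduced dynamics of any single-trajectory rule with local mutations on a
path landscape is a birth-death chain: per *relevant step* the walker proposes
up or down with probability 1/2 each and accepts with the rule's probability
of the height difference, so ``p_up + p_down <= 1`` and the remainder is a
self-loop.  On a linear slope the transition probabilities are
position-independent and the walk is a Gambler's Ruin game whose per-round
win/lose probabilities need not sum to one.

Self-loops leave absorption (win) probabilities untouched; they stretch
expected durations by the waiting time for a relevant move.  The closed forms
below are checked against direct linear solves of the first-step equations,
which are also the primary tool for drift and hitting-time computations on
full ValleyPath chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
import scipy.special

from .acceptance import AcceptanceRule, accept_probability, sswm_acceptance
from .landscapes import ValleyPathSpec, ValleySpec, enumerate_extrema, global_heights, valley_heights

__all__ = [
    "RuinGame",
    "ChainModel",
    "DriftReport",
    "UnreachableError",
    "ruin_win_probability",
    "ruin_expected_duration",
    "hitting_time",
    "absorption_probability",
    "build_valley_chain",
    "descent_time",
    "valley_expected_time",
    "sswm_ruin_bounds",
    "metropolis_ruin_bounds",
    "drift_report",
    "valleypath_expected_time",
]

#: Relative tolerance below which p1 and p2 are treated as equal.
_EQUAL_TOL = 1e-12

#: Largest chain (number of states) accepted for direct linear solves.
MAX_CHAIN_STATES = 100_000


class UnreachableError(RuntimeError):
    """The target set cannot be reached from the start state."""


@dataclass(frozen=True)
class RuinGame:
    """Gambler's Ruin with self-loops.

    Player 1 starts with ``n1`` dollars, player 2 with ``n2``.  Per round
    player 1 wins a dollar with probability ``p1``, loses one with
    probability ``p2``, and nothing happens otherwise.
    """

    n1: int
    n2: int
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError(f"starting dollars must be >= 1, got {self.n1}, {self.n2}")
        if self.p1 < 0 or self.p2 < 0 or self.p1 + self.p2 > 1 + 1e-12:
            raise ValueError(f"need p1, p2 >= 0 and p1 + p2 <= 1, got {self.p1}, {self.p2}")
        if self.p1 + self.p2 == 0:
            raise ValueError("p1 + p2 must be positive (the game must move)")


def ruin_win_probability(game: RuinGame) -> float:
    """Probability that player 1 wins all dollars before going bankrupt.

    ``n1 / (n1 + n2)`` for ``p1 = p2``; otherwise
    ``(1 - (p2/p1)^n1) / (1 - (p2/p1)^(n1+n2))``, evaluated in log space.
    Self-loops do not affect this probability.
    """
    n1, n2, p1, p2 = game.n1, game.n2, game.p1, game.p2
    if p1 == 0:
        return 0.0
    if p2 == 0:
        return 1.0
    if abs(p1 - p2) <= _EQUAL_TOL * (p1 + p2):
        return n1 / (n1 + n2)
    log_r = math.log(p2) - math.log(p1)
    n = n1 + n2
    if n * log_r <= 700.0:  # expm1 keeps full precision for r near 1
        return math.expm1(n1 * log_r) / math.expm1(n * log_r)
    # huge r^n: rewrite as (r^n1 - 1)/(r^n - 1) and factor the leading powers
    log_num = n1 * log_r + math.log(-math.expm1(-n1 * log_r))
    log_den = n * log_r + math.log(-math.expm1(-n * log_r))
    return math.exp(log_num - log_den)


def ruin_expected_duration(game: RuinGame) -> float:
    """Expected number of rounds (self-loops included) until a bankruptcy.

    ``n1 * n2 / (p1 + p2)`` for ``p1 = p2``; otherwise
    ``(n1 - (n1 + n2) P1) / (p2 - p1)`` with ``P1`` the win probability.
    The formula is homogeneous of degree -1 in ``(p1, p2)``: halving both
    probabilities doubles the duration, the self-loop stretching.
    """
    n1, n2, p1, p2 = game.n1, game.n2, game.p1, game.p2
    if abs(p1 - p2) <= _EQUAL_TOL * (p1 + p2):
        return n1 * n2 / (p1 + p2)
    P1 = ruin_win_probability(game)
    return (n1 - (n1 + n2) * P1) / (p2 - p1)


@dataclass(frozen=True)
class ChainModel:
    """Birth-death chain on states ``0 .. S`` with explicit self-loops.

    ``up[i] + down[i] + loop[i] == 1`` per state; ``down[0] == up[S] == 0``.
    Self-loops are never renormalised away: expected durations depend on
    them even though absorption probabilities do not.
    """

    up: np.ndarray
    down: np.ndarray
    loop: np.ndarray

    def __post_init__(self) -> None:
        up, down, loop = (np.asarray(a, dtype=float) for a in (self.up, self.down, self.loop))
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        object.__setattr__(self, "loop", loop)
        if not (up.shape == down.shape == loop.shape) or up.ndim != 1 or up.size < 1:
            raise ValueError("up/down/loop must be equal-length 1-D arrays")
        if np.any(up < -1e-15) or np.any(down < -1e-15) or np.any(loop < -1e-15):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(up + down + loop, 1.0, atol=1e-12):
            raise ValueError("per-state probabilities must sum to 1")
        if down[0] != 0 or up[-1] != 0:
            raise ValueError("boundary states must not step outside the chain")

    @property
    def n_states(self) -> int:
        return self.up.size


def _reachable(chain: ChainModel, sources: Iterable[int], forward: bool) -> set[int]:
    """States reachable from ``sources`` along nonzero transitions.

    ``forward=False`` follows edges backwards (who can reach the sources).
    """
    seen = set(sources)
    stack = list(seen)
    up, down = chain.up, chain.down
    while stack:
        i = stack.pop()
        if forward:
            nbrs = [j for j, p in ((i + 1, up[i] if i + 1 < chain.n_states else 0.0),
                                   (i - 1, down[i] if i > 0 else 0.0)) if p > 0]
        else:
            nbrs = []
            if i > 0 and up[i - 1] > 0:
                nbrs.append(i - 1)
            if i + 1 < chain.n_states and down[i + 1] > 0:
                nbrs.append(i + 1)
        for j in nbrs:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return seen


def hitting_time(
    chain: ChainModel, start: int, targets: Union[int, Iterable[int]]
) -> float:
    """Exact expected steps from ``start`` until any target state is reached.

    Solves the first-step equations ``(1 - loop_i) t_i - up_i t_{i+1} -
    down_i t_{i-1} = 1`` over the transient states with the targets made
    absorbing.  Raises :class:`UnreachableError` when the expectation is
    infinite (some state reachable from the start cannot reach a target).
    """
    S = chain.n_states
    target_set = {targets} if isinstance(targets, (int, np.integer)) else set(int(t) for t in targets)
    if not 0 <= start < S:
        raise IndexError(f"start {start} outside chain of {S} states")
    if any(not 0 <= t < S for t in target_set):
        raise IndexError("target outside chain")
    if start in target_set:
        return 0.0
    if S > MAX_CHAIN_STATES:
        raise ValueError(
            f"chain of {S} states exceeds the linear-solve cap {MAX_CHAIN_STATES}; "
            "use the simulation modes instead"
        )
    can_reach = _reachable(chain, target_set, forward=False)
    if start not in can_reach:
        raise UnreachableError(f"no target in {sorted(target_set)} reachable from {start}")
    fwd = _reachable(chain, {start}, forward=True) - target_set
    if not fwd <= can_reach:
        raise UnreachableError("start can reach a state from which no target is reachable")

    transient = sorted(set(range(S)) - target_set)
    pos = {s: i for i, s in enumerate(transient)}
    rows, cols, vals = [], [], []
    for i, s in enumerate(transient):
        rows.append(i); cols.append(i); vals.append(1.0 - chain.loop[s])
        if s + 1 < S and chain.up[s] > 0 and s + 1 not in target_set:
            rows.append(i); cols.append(pos[s + 1]); vals.append(-chain.up[s])
        if s - 1 >= 0 and chain.down[s] > 0 and s - 1 not in target_set:
            rows.append(i); cols.append(pos[s - 1]); vals.append(-chain.down[s])
    A = scipy.sparse.csc_matrix((vals, (rows, cols)), shape=(len(transient),) * 2)
    t = scipy.sparse.linalg.spsolve(A, np.ones(len(transient)))
    return float(t[pos[start]])


def _birth_death_split(
    chain: ChainModel, a: int, s: int, b: int
) -> Union[tuple[float, float], None]:
    """(P(hit a first), P(hit b first)) from ``a < s < b``, in log space.

    Uses the closed-form harmonic sums of a birth-death chain,
    ``P(hit b first) = sum_{i<s} w_i / sum_i w_i`` with
    ``w_i = prod_{j<=i} down_j/up_j``; both tails are summed directly so
    even astronomically small probabilities keep full relative accuracy
    (self-loops cancel).  Returns None when an interior transition
    probability vanishes (the closed form needs a positive walk).
    """
    up, down = chain.up, chain.down
    if any(up[j] <= 0 or down[j] <= 0 for j in range(a + 1, b)):
        return None
    logw = np.empty(b - a)
    logw[0] = 0.0
    for j in range(a + 1, b):
        logw[j - a] = logw[j - a - 1] + math.log(down[j]) - math.log(up[j])
    log_den = scipy.special.logsumexp(logw)
    log_pb = scipy.special.logsumexp(logw[: s - a]) - log_den
    log_pa = scipy.special.logsumexp(logw[s - a :]) - log_den
    return math.exp(log_pa), math.exp(log_pb)


def absorption_probability(
    chain: ChainModel, start: int, hit: Iterable[int], avoid: Iterable[int]
) -> float:
    """Probability of reaching any state in ``hit`` before any in ``avoid``.

    Two-boundary birth-death cases (single states bracketing the start) are
    evaluated by the stable closed-form split; anything else falls back to
    the first-step linear system.
    """
    S = chain.n_states
    hit_set = set(int(t) for t in hit)
    avoid_set = set(int(t) for t in avoid)
    if hit_set & avoid_set:
        raise ValueError("hit and avoid sets overlap")
    if start in hit_set:
        return 1.0
    if start in avoid_set:
        return 0.0
    if len(hit_set) == 1 and len(avoid_set) == 1:
        x, y = next(iter(hit_set)), next(iter(avoid_set))
        a, b = min(x, y), max(x, y)
        if a < start < b:
            split = _birth_death_split(chain, a, start, b)
            if split is not None:
                p_a, p_b = split
                return p_a if x == a else p_b
    absorbing = hit_set | avoid_set
    transient = sorted(set(range(S)) - absorbing)
    pos = {s: i for i, s in enumerate(transient)}
    rows, cols, vals = [], [], []
    b = np.zeros(len(transient))
    for i, s in enumerate(transient):
        rows.append(i); cols.append(i); vals.append(1.0 - chain.loop[s])
        for nbr, p in ((s + 1, chain.up[s]), (s - 1, chain.down[s])):
            if p <= 0 or not 0 <= nbr < S:
                continue
            if nbr in hit_set:
                b[i] += p
            elif nbr not in avoid_set:
                rows.append(i); cols.append(pos[nbr]); vals.append(-p)
    A = scipy.sparse.csc_matrix((vals, (rows, cols)), shape=(len(transient),) * 2)
    h = scipy.sparse.linalg.spsolve(A, b)
    return float(h[pos[start]])


def build_valley_chain(heights: Sequence[float], rule: AcceptanceRule) -> ChainModel:
    """Relevant-step chain of a rule on a height profile.

    Interior state ``i``: up with ``(1/2) p_acc(h[i+1] - h[i])``, down with
    ``(1/2) p_acc(h[i-1] - h[i])``, self-loop otherwise.  At the two ends the
    missing direction is folded into a self-loop of at least 1/2.
    """
    h = np.asarray(heights, dtype=float)
    if h.size < 2:
        raise ValueError("need at least two states")
    S = h.size
    up = np.zeros(S)
    down = np.zeros(S)
    for i in range(S):
        if i + 1 < S:
            up[i] = 0.5 * accept_probability(rule, h[i + 1] - h[i])
        if i - 1 >= 0:
            down[i] = 0.5 * accept_probability(rule, h[i - 1] - h[i])
    return ChainModel(up=up, down=down, loop=1.0 - up - down)


def _descent_game(spec: ValleySpec, rule: AcceptanceRule) -> RuinGame:
    """Ruin game for descending the first slope, starting one step in.

    Player 1 is the walker moving *down* the slope (away from the starting
    peak); winning means reaching the valley bottom at distance ``l1``.
    """
    step = spec.d1 / spec.l1
    p1 = 0.5 * accept_probability(rule, -step)
    p2 = 0.5 * accept_probability(rule, +step)
    return RuinGame(n1=1, n2=spec.l1 - 1, p1=p1, p2=p2)


def descent_time(spec: ValleySpec, rule: AcceptanceRule) -> float:
    """Exact expected relevant steps from one step into the valley to the bottom.

    Decomposes the first passage ``1 -> l1`` into a Gambler's Ruin on the
    slope plus the expected restarts through the peak::

        E(T_1->l1) = (1 / P_win) * (E(T_GR) + P_lose / p_0->1)

    where the game starts with one dollar against ``l1 - 1``, ``P_win`` is
    the probability of reaching the bottom before the peak, and ``p_0->1 =
    (1/2) p_acc(-d1/l1)`` is the per-step probability of re-entering the
    slope from the peak.  Equals the linear-solve first-passage time on the
    slope sub-chain exactly.
    """
    game = _descent_game(spec, rule)
    p_win = ruin_win_probability(game)
    if p_win == 0.0:
        raise UnreachableError("rule never accepts the downhill step; descent impossible")
    e_gr = ruin_expected_duration(game)
    p_restart = 1.0 - p_win
    p_01 = game.p1  # peak -> first slope state: same downhill acceptance
    return (e_gr + p_restart / p_01) / p_win


def valley_expected_time(spec: ValleySpec, rule: AcceptanceRule) -> float:
    """Exact expected relevant steps to cross a Valley, start at the peak."""
    chain = build_valley_chain(valley_heights(spec), rule)
    return hitting_time(chain, 0, spec.length)


def _pfix_form_bounds(two_beta: float, cap: int, delta_f: float) -> tuple[float, float]:
    """Bounds on ``(1 - e^{-c df})/(1 - e^{-c K df})`` with ``c = two_beta``.

    The sigmoid has the same shape as the SSWM acceptance probability with
    selection strength ``two_beta / 2`` and population parameter ``cap``, so
    the elementary fixation bounds apply verbatim.
    """
    a = two_beta * delta_f
    b = cap * a
    if abs(b) < 1e-12:
        return 1.0 / cap, 1.0 / cap  # degenerate: the sigmoid collapses to its limit
    if delta_f > 0:
        return a / (1.0 + a), a / (-math.expm1(-b))
    lower = (-a) * math.exp(b)
    log_den = -b if -b > 700 else math.log(math.expm1(-b))
    return lower, math.exp(-a - log_den)


def sswm_ruin_bounds(
    spec: ValleySpec, beta: float, N: int
) -> tuple[float, float, float]:
    """(lower, exact, upper) for the SSWM slope-descent win probability.

    The game of :func:`_descent_game` with SSWM probabilities: the ratio
    ``p2/p1`` collapses to ``exp(-2 (N-1) beta delta_f)`` and the win
    probability takes the fixation-probability form with strength
    ``(N-1) beta`` and cap ``l1``, bracketed by the elementary bounds.
    For ``N = 1`` the walk is symmetric and all three values are ``1/l1``.
    """
    rule = AcceptanceRule.sswm(beta, N)
    exact = ruin_win_probability(_descent_game(spec, rule))
    delta_f = -spec.d1 / spec.l1
    lower, upper = _pfix_form_bounds(2.0 * beta * (N - 1), spec.l1, delta_f)
    return lower, exact, upper


def metropolis_ruin_bounds(
    spec: ValleySpec, alpha: float
) -> tuple[float, float, float]:
    """(lower, exact, upper) for the Metropolis slope-descent win probability.

    Downhill moves are accepted with ``exp(alpha delta_f)`` (``delta_f < 0``)
    and uphill moves always, so ``p2/p1 = exp(-alpha delta_f)`` and the win
    probability takes the fixation form with ``lambda = alpha`` and cap
    ``l1``.
    """
    rule = AcceptanceRule.metropolis(alpha)
    exact = ruin_win_probability(_descent_game(spec, rule))
    delta_f = -spec.d1 / spec.l1
    lower, upper = _pfix_form_bounds(alpha, spec.l1, delta_f)
    return lower, exact, upper


@dataclass(frozen=True)
class DriftReport:
    """Peak-to-peak transition diagnostics at an interior ValleyPath peak.

    ``p_down_left/right``: from the peak, probability that the first minimum
    reached is the left/right one.  ``p_up_left/right``: from the left
    minimum, probability that the first peak reached is its left/right
    neighbour.  ``ratio = (p_down_left * p_up_left) / (p_down_right *
    p_up_right)``, which for any rule with the exponential acceptance-ratio
    property equals ``exp(-lam (d2 - d1))``.  ``peak_advance_prob`` is the
    probability that the next peak-to-peak transition moves toward the
    optimum (one fewer peak remaining), ``1 / (1 + ratio)``; the drift in
    remaining peaks is ``2 * peak_advance_prob - 1``.
    """

    p_down_left: float
    p_down_right: float
    p_up_left: float
    p_up_right: float
    ratio: float
    lam: float
    peak_advance_prob: float
    drift: float


class BoundaryPeakError(ValueError):
    """Drift is defined only at peaks with both neighbours."""


def drift_report(
    spec: ValleyPathSpec, rule: AcceptanceRule, peak: int = 1
) -> DriftReport:
    """Exact drift over peaks at interior peak ``peak`` (1 .. m-1).

    All four probabilities are absorption probabilities computed by linear
    solves on the flattened chain; by the landscape's translational symmetry
    they are identical at every interior peak/minimum.  Requires ``m >= 2``.
    """
    if spec.m < 2:
        raise BoundaryPeakError("a ValleyPath with m >= 2 is needed for an interior peak")
    if not 1 <= peak <= spec.m - 1:
        raise BoundaryPeakError(f"peak {peak} is not interior (1 .. {spec.m - 1})")
    heights = global_heights(spec)
    chain = build_valley_chain(heights, rule)
    ell, l1, l2 = spec.valley.length, spec.valley.l1, spec.valley.l2
    g = peak * ell
    left_min, right_min = g - l2, g + l1
    split = _birth_death_split(chain, left_min, g, right_min)
    if split is None:
        p_down_left = absorption_probability(chain, g, {left_min}, {right_min})
        p_down_right = 1.0 - p_down_left
    else:
        p_down_left, p_down_right = split
    left_peak = (peak - 1) * ell
    split = _birth_death_split(chain, left_peak, left_min, g)
    if split is None:
        p_up_left = absorption_probability(chain, left_min, {left_peak}, {g})
        p_up_right = 1.0 - p_up_left
    else:
        p_up_left, p_up_right = split
    ratio = (p_down_left * p_up_left) / (p_down_right * p_up_right)
    advance = 1.0 / (1.0 + ratio)
    return DriftReport(
        p_down_left=p_down_left,
        p_down_right=p_down_right,
        p_up_left=p_up_left,
        p_up_right=p_up_right,
        ratio=ratio,
        lam=rule.lam,
        peak_advance_prob=advance,
        drift=2.0 * advance - 1.0,
    )


def valleypath_expected_time(spec: ValleyPathSpec, rule: AcceptanceRule) -> float:
    """Exact expected relevant steps from the first peak to the global optimum."""
    heights = global_heights(spec)
    if heights.size > MAX_CHAIN_STATES:
        raise ValueError(
            f"ValleyPath chain of {heights.size} states exceeds the solve cap; "
            "use the simulation modes"
        )
    chain = build_valley_chain(heights, rule)
    return hitting_time(chain, 0, heights.size - 1)
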