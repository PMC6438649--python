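"""Gambler's Ruin closed forms, chain solves, descent decomposition, drift."""

import math

import numpy as np
import pytest

from valleycross import (
    AcceptanceRule,
    ChainModel,
    RuinGame,
    ValleyPathSpec,
    ValleySpec,
    absorption_probability,
    build_valley_chain,
    descent_time,
    drift_report,
    fixation_ratio,
    hitting_time,
    metropolis_ruin_bounds,
    ruin_expected_duration,
    ruin_win_probability,
    sswm_ruin_bounds,
    valley_expected_time,
    valley_heights,
    valleypath_expected_time,
)
from valleycross.exact_analysis import BoundaryPeakError, UnreachableError


def brute_force_absorption(game: RuinGame) -> tuple[float, float]:
    """(win probability, expected duration) by dense linear solve.

    Independent oracle: first-step equations on the full (n1+n2+1)-state
    chain, absorbing at 0 and n1+n2.
    """
    S = game.n1 + game.n2
    n_tr = S - 1
    A = np.zeros((n_tr, n_tr))
    b_win = np.zeros(n_tr)
    b_dur = np.ones(n_tr)
    for row, i in enumerate(range(1, S)):
        A[row, row] = game.p1 + game.p2
        if i + 1 < S:
            A[row, row + 1] = -game.p1
        else:
            b_win[row] = game.p1
        if i - 1 > 0:
            A[row, row - 1] = -game.p2
    win = np.linalg.solve(A, b_win)
    dur = np.linalg.solve(A, b_dur)
    return float(win[game.n1 - 1]), float(dur[game.n1 - 1])


def random_game(rng) -> RuinGame:
    n1 = int(rng.integers(1, 8))
    n2 = int(rng.integers(1, 8))
    p1 = float(rng.uniform(0.01, 0.5))
    if rng.random() < 0.2:  # exercise the equal / near-equal branch
        p2 = p1 * (1.0 + rng.choice([0.0, 1e-13, -1e-13]))
    else:
        p2 = float(rng.uniform(0.01, 0.5))
    return RuinGame(n1, n2, p1, p2)


class TestRuinClosedForms:
    def test_symmetric_win_probability(self):
        assert ruin_win_probability(RuinGame(1, 3, 0.2, 0.2)) == pytest.approx(0.25)

    def test_biased_win_probability(self):
        # p2/p1 = 1/2, one dollar each: (1 - 1/2)/(1 - 1/4) = 2/3
        assert ruin_win_probability(RuinGame(1, 1, 0.4, 0.2)) == pytest.approx(2 / 3)

    def test_degenerate_probabilities(self):
        assert ruin_win_probability(RuinGame(2, 3, 0.3, 0.0)) == 1.0
        assert ruin_win_probability(RuinGame(2, 3, 0.0, 0.3)) == 0.0
        with pytest.raises(ValueError):
            RuinGame(1, 1, 0.0, 0.0)

    def test_symmetric_duration_unit_case(self):
        assert ruin_expected_duration(RuinGame(1, 1, 0.5, 0.5)) == pytest.approx(1.0)

    def test_self_loop_scaling(self):
        """Halving both win/lose probabilities doubles the duration."""
        g = RuinGame(2, 4, 0.3, 0.15)
        h = RuinGame(2, 4, 0.15, 0.075)
        assert ruin_expected_duration(h) == pytest.approx(2 * ruin_expected_duration(g), rel=1e-12)

    def test_duration_matches_brute_force_example(self):
        got = ruin_expected_duration(RuinGame(1, 2, 0.3, 0.1))
        _, expected = brute_force_absorption(RuinGame(1, 2, 0.3, 0.1))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_closed_forms_vs_linear_solve_on_random_games(self, rng):
        for _ in range(150):
            game = random_game(rng)
            win, dur = brute_force_absorption(game)
            assert ruin_win_probability(game) == pytest.approx(win, rel=1e-9)
            assert ruin_expected_duration(game) == pytest.approx(dur, rel=1e-9)

    def test_branch_switch_is_continuous(self):
        base = RuinGame(3, 4, 0.2, 0.2)
        near = RuinGame(3, 4, 0.2, 0.2 * (1 + 1e-9))
        assert ruin_win_probability(near) == pytest.approx(ruin_win_probability(base), rel=1e-8)
        assert ruin_expected_duration(near) == pytest.approx(ruin_expected_duration(base), rel=1e-6)

    def test_extreme_ratio_log_space(self):
        game = RuinGame(50, 50, 0.45, 0.05)  # ratio 1/9 to the 100th power
        p = ruin_win_probability(game)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(1.0, rel=1e-12)


class TestChainModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            ChainModel(up=[0.5, 0.0], down=[0.0, 0.6], loop=[0.5, 0.5])
        with pytest.raises(ValueError):
            ChainModel(up=[0.5, 0.1], down=[0.0, 0.4], loop=[0.5, 0.5])  # up at last state

    def test_hitting_time_trivial_cases(self):
        chain = ChainModel(up=[1.0, 1.0, 0.0], down=[0.0, 0.0, 0.0], loop=[0.0, 0.0, 1.0])
        assert hitting_time(chain, 0, 2) == pytest.approx(2.0)  # deterministic up-chain
        assert hitting_time(chain, 2, 2) == 0.0

    def test_hitting_time_matches_ruin_duration(self, rng):
        for _ in range(50):
            game = random_game(rng)
            S = game.n1 + game.n2
            up = np.full(S + 1, game.p1)
            down = np.full(S + 1, game.p2)
            up[-1] = down[0] = 0.0
            up[0] = down[-1] = 0.0  # both boundaries held by absorption targets
            chain = ChainModel(up=up, down=down, loop=1 - up - down)
            t = hitting_time(chain, game.n1, [0, S])
            assert t == pytest.approx(ruin_expected_duration(game), rel=1e-9)

    def test_unreachable_target(self):
        chain = ChainModel(up=[0.0, 0.5, 0.0], down=[0.0, 0.5, 0.5], loop=[1.0, 0.0, 0.5])
        with pytest.raises(UnreachableError):
            hitting_time(chain, 0, 2)

    def test_absorption_probability_matches_ruin(self, rng):
        for _ in range(50):
            game = random_game(rng)
            S = game.n1 + game.n2
            up = np.full(S + 1, game.p1)
            down = np.full(S + 1, game.p2)
            up[-1] = down[0] = up[0] = down[-1] = 0.0
            chain = ChainModel(up=up, down=down, loop=1 - up - down)
            p = absorption_probability(chain, game.n1, {S}, {0})
            assert p == pytest.approx(ruin_win_probability(game), rel=1e-9)


class TestValleyChain:
    def test_rows_sum_to_one_random(self, rng):
        for _ in range(200):
            heights = rng.normal(size=rng.integers(2, 12))
            rule = AcceptanceRule.sswm(float(rng.uniform(0.1, 3)), int(rng.integers(1, 6)))
            chain = build_valley_chain(heights, rule)
            assert np.allclose(chain.up + chain.down + chain.loop, 1.0)

    def test_elitist_cannot_descend(self):
        heights = [3.0, 2.0, 1.0, 0.0]
        chain = build_valley_chain(heights, AcceptanceRule.elitist())
        assert np.all(chain.up == 0.0)  # every forward step loses height
        assert np.all(chain.down[1:] == 0.5)

    def test_up_down_ratio_is_fixation_ratio(self, sswm_rule):
        heights = valley_heights(ValleySpec(3, 4, 2.0, 3.0))
        chain = build_valley_chain(heights, sswm_rule)
        for i in range(1, len(heights) - 1):
            step = heights[i + 1] - heights[i]
            # acceptance ratio of the +step move vs the -step move from i+1
            got = chain.up[i] / chain.down[i + 1]
            expected = 1.0 / fixation_ratio(sswm_rule.beta, sswm_rule.N, step)
            assert got == pytest.approx(expected, rel=1e-12)


class TestDescentDecomposition:
    @pytest.mark.parametrize(
        "rule",
        [AcceptanceRule.sswm(1.0, 2), AcceptanceRule.sswm(0.5, 3),
         AcceptanceRule.metropolis(1.0), AcceptanceRule.metropolis(0.5)],
        ids=["sswm-b1N2", "sswm-b05N3", "met-a1", "met-a05"],
    )
    @pytest.mark.parametrize("valley", [ValleySpec(4, 4, 4.0, 4.0), ValleySpec(3, 3, 3.0, 3.0),
                                        ValleySpec(2, 5, 1.0, 2.0), ValleySpec(6, 2, 2.0, 6.0)])
    def test_equals_linear_solve(self, rule, valley):
        """Ruin-plus-restart decomposition == first-passage linear solve."""
        slope = [valley_heights(valley)[i] for i in range(valley.l1 + 1)]
        chain = build_valley_chain(slope, rule)
        oracle = hitting_time(chain, 1, valley.l1)
        assert descent_time(valley, rule) == pytest.approx(oracle, rel=1e-9)

    def test_symmetric_walk_closed_form(self):
        """Neutral SSWM (N=1) accepts everything: the walk is symmetric.

        The ruin game has p1 = p2 = 1/2 so the decomposition reduces to the
        classic duration (l1 - 1) plus the restart through the peak.
        """
        valley = ValleySpec(5, 2, 1.0, 2.0)
        rule = AcceptanceRule.sswm(1.0, 1)
        l1 = valley.l1
        # E_GR = n1*n2/(p1+p2) = (l1-1); P_win = 1/l1; p_{0->1} = 1/2
        expected = l1 * ((l1 - 1) + (1 - 1 / l1) / 0.5)
        assert descent_time(valley, rule) == pytest.approx(expected, rel=1e-12)


class TestRuinBounds:
    def test_bracketing_on_grids(self, rng):
        for _ in range(200):
            l1, l2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            d1 = float(rng.uniform(0.5, 4.0))
            valley = ValleySpec(l1, l2, d1, d1 + float(rng.uniform(0.0, 3.0)))
            lo, exact, hi = sswm_ruin_bounds(valley, float(rng.uniform(0.1, 3.0)), int(rng.integers(2, 10)))
            assert lo - 1e-12 <= exact <= hi + 1e-12
            lo, exact, hi = metropolis_ruin_bounds(valley, float(rng.uniform(0.2, 3.0)))
            assert lo - 1e-12 <= exact <= hi + 1e-12

    def test_neutral_population_gives_symmetric_game(self):
        valley = ValleySpec(5, 3, 2.0, 2.5)
        _, exact, _ = sswm_ruin_bounds(valley, 1.0, 1)
        assert exact == pytest.approx(1 / valley.l1)

    def test_metropolis_strong_selection_descends_rarely(self):
        """Large inverse temperature: the downhill escape almost never wins."""
        valley = ValleySpec(4, 4, 2.0, 3.0)
        _, exact_cold, _ = metropolis_ruin_bounds(valley, 20.0)
        _, exact_hot, _ = metropolis_ruin_bounds(valley, 0.01)
        assert exact_cold < 1e-8
        assert exact_hot == pytest.approx(1 / valley.l1, rel=1e-2)


class TestDriftReport:
    def test_zero_exponent_gives_zero_drift(self):
        """lambda = 0 (neutral SSWM): both directions balanced exactly."""
        spec = ValleyPathSpec(m=3, valley=ValleySpec(3, 3, 1.0, 2.0))
        rep = drift_report(spec, AcceptanceRule.sswm(1.0, 1))
        assert rep.ratio == pytest.approx(1.0, rel=1e-12)
        assert rep.drift == pytest.approx(0.0, abs=1e-12)

    def test_probabilities_are_complementary(self, sswm_rule):
        spec = ValleyPathSpec(m=4, valley=ValleySpec(2, 3, 1.0, 2.0))
        rep = drift_report(spec, sswm_rule, peak=2)
        assert rep.p_down_left + rep.p_down_right == pytest.approx(1.0, abs=1e-12)
        assert rep.p_up_left + rep.p_up_right == pytest.approx(1.0, abs=1e-12)
        assert -1.0 <= rep.drift <= 1.0

    def test_ratio_identity_sswm_and_metropolis(self):
        for rule in (AcceptanceRule.sswm(0.8, 3), AcceptanceRule.metropolis(1.2)):
            spec = ValleyPathSpec(m=3, valley=ValleySpec(3, 5, 2.0, 3.0))
            rep = drift_report(spec, rule)
            assert rep.ratio == pytest.approx(math.exp(-rule.lam * 1.0), rel=1e-9)

    def test_report_agrees_with_independent_linear_solve(self, metropolis_rule):
        """Closed-form split vs the sparse first-step solve, moderate regime."""
        from valleycross.exact_analysis import absorption_probability, build_valley_chain
        from valleycross.landscapes import global_heights

        spec = ValleyPathSpec(m=3, valley=ValleySpec(2, 3, 1.0, 2.0))
        rep = drift_report(spec, metropolis_rule, peak=1)
        chain = build_valley_chain(global_heights(spec), metropolis_rule)
        ell, l1, l2 = spec.valley.length, spec.valley.l1, spec.valley.l2
        g = ell
        solve_left = absorption_probability(chain, g, {g - l2}, {g + l1})
        assert rep.p_down_left == pytest.approx(solve_left, rel=1e-9)

    def test_boundary_peak_rejected(self, sswm_rule):
        spec = ValleyPathSpec(m=3, valley=ValleySpec(2, 2, 1.0, 2.0))
        with pytest.raises(BoundaryPeakError):
            drift_report(spec, sswm_rule, peak=0)
        with pytest.raises(BoundaryPeakError):
            drift_report(ValleyPathSpec(m=1, valley=ValleySpec(2, 2, 1.0, 2.0)), sswm_rule)


class TestValleyPathTime:
    def test_single_valley_reduces_to_valley_time(self, standard_valley, sswm_rule):
        vp = ValleyPathSpec(m=1, valley=standard_valley)
        assert valleypath_expected_time(vp, sswm_rule) == pytest.approx(
            valley_expected_time(standard_valley, sswm_rule), rel=1e-12
        )

    def test_strictly_increasing_in_m(self, standard_valley, sswm_rule):
        times = [
            valleypath_expected_time(ValleyPathSpec(m=m, valley=standard_valley), sswm_rule)
            for m in range(1, 6)
        ]
        assert all(a < b for a, b in zip(times, times[1:]))

    def test_per_valley_cost_stays_bounded(self, standard_valley, sswm_rule):
        per = [
            valleypath_expected_time(ValleyPathSpec(m=m, valley=standard_valley), sswm_rule) / m
            for m in range(2, 9)
        ]
        assert max(per) / min(per) < 3.0
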