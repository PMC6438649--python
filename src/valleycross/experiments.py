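"""Reproducible desk-scale experiments verifying the runtime laws.

Four experiment kinds:

* ``ea-length-scaling``: Monte-Carlo crossing times of the elitist algorithm
  on a shortcut-free Valley segment across dimensions ``n``; the log-log
  slope of the mean time against ``n`` estimates the exponent of the
  ``Theta(n**l*)`` law, ``l* = l1 + ceil(d1 l2 / d2)`` the effective length.
* ``depth-scaling``: exact expected relevant steps of a non-elitist rule as
  the valley depth ``d1`` grows (``d2 = d1 + 1``); the slope of
  ``ln E(T)`` against ``d1`` must land inside the analytic sandwich
  (SSWM: ``[2 (N-1) beta (l1-1)/l1, 2 N beta (l1+1)/l1]``; Metropolis:
  ``[alpha (1 - 1/l1), alpha (1 + 1/l1)]``).
* ``valleypath-scaling``: exact crossing times of ``m``-valley ValleyPaths;
  with a positive drift over peaks the time grows linearly in ``m``.
* ``cross-mode-check``: bitstring, chain and segment-jump modes agree in
  mean, and function evaluations are ``n/2`` times relevant steps.

Asymptotic side conditions of the form "the scaled gradient is at least a
constant" are instantiated as ``>= 0.5`` and checked per grid cell; cells out
of regime are reported, never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__
from .acceptance import AcceptanceRule
from .dynamics import RunResult, SimulationConfig, run_chain, run_segment_jump
from .exact_analysis import drift_report, valley_expected_time, valleypath_expected_time
from .landscapes import ValleyPathSpec, ValleySpec, effective_length, valley_heights
from .longpath import LongKPathSpec, build_path, point_at

__all__ = [
    "ExperimentPlan",
    "ea_length_scaling",
    "depth_scaling",
    "valleypath_scaling",
    "cross_mode_check",
    "generate_fixtures",
    "GRADIENT_FLOOR",
]

#: Instantiation of the "scaled gradient is Omega(1)" side conditions.
GRADIENT_FLOOR = 0.5


@dataclass(frozen=True)
class ExperimentPlan:
    """A named experiment with its parameter grid, replicates and seed."""

    kind: str
    valley: ValleySpec
    rule: Optional[AcceptanceRule] = None
    ns: tuple[int, ...] = ()
    d1_grid: tuple[float, ...] = ()
    ms: tuple[int, ...] = ()
    replicates: int = 50
    seed: int = 0
    budget: int = 10**8

    KINDS = ("ea-length-scaling", "depth-scaling", "valleypath-scaling", "cross-mode-check")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")

    def provenance(self) -> dict:
        """Machine-readable header for exact reproduction."""
        d = {
            "kind": self.kind,
            "valley": vars(self.valley).copy(),
            "rule": None if self.rule is None else {
                k: v for k, v in vars(self.rule).items() if v is not None
            },
            "ns": list(self.ns),
            "d1_grid": list(self.d1_grid),
            "ms": list(self.ms),
            "replicates": self.replicates,
            "seed": self.seed,
            "budget": self.budget,
            "package_version": __version__,
        }
        return d


@dataclass
class ScalingResult:
    """Table plus fitted slope (with standard error) of a scaling study."""

    table: pd.DataFrame
    slope: float
    slope_se: float
    plan: ExperimentPlan
    warnings: list[str] = field(default_factory=list)


def ea_length_scaling(plan: ExperimentPlan) -> ScalingResult:
    """Monte-Carlo elitist crossing times vs dimension; log-log slope fit."""
    if not plan.ns:
        raise ValueError("ea-length-scaling needs a non-empty n grid")
    warnings: list[str] = []
    if plan.replicates < 20:
        warnings.append(f"only {plan.replicates} replicates; slope estimate will be noisy")
    lstar = effective_length(plan.valley)
    rows = []
    for cell, n in enumerate(plan.ns):
        times = []
        censored = 0
        for r in range(plan.replicates):
            cfg = SimulationConfig(
                mode="segment-jump",
                max_evaluations=plan.budget,
                seed=plan.seed + 10_000 * cell + r,
            )
            res = run_segment_jump(plan.valley, n, cfg)
            times.append(res.function_evaluations)
            censored += not res.hit_optimum
        times = np.asarray(times, dtype=float)
        rows.append({
            "n": n,
            "mean_evaluations": times.mean(),
            "se": times.std(ddof=1) / math.sqrt(len(times)),
            "censored": censored,
            "effective_length": lstar,
        })
    table = pd.DataFrame(rows)
    fit = scipy.stats.linregress(np.log(table["n"]), np.log(table["mean_evaluations"]))
    return ScalingResult(table, fit.slope, fit.stderr, plan, warnings)


def _depth_sandwich(rule: AcceptanceRule, l1: int) -> tuple[float, float]:
    if rule.variant == "sswm":
        return (
            2.0 * (rule.N - 1) * rule.beta * (l1 - 1) / l1,
            2.0 * rule.N * rule.beta * (l1 + 1) / l1,
        )
    if rule.variant == "metropolis":
        return rule.alpha * (1.0 - 1.0 / l1), rule.alpha * (1.0 + 1.0 / l1)
    raise ValueError("depth scaling applies to the non-elitist rules")


def _gradient_ok(rule: AcceptanceRule, valley: ValleySpec) -> tuple[bool, str]:
    strength = rule.beta if rule.variant == "sswm" else rule.alpha
    g1 = strength * valley.d1 / valley.l1
    g2 = strength * valley.d2 / valley.l2
    ok = g1 >= GRADIENT_FLOOR and g2 >= GRADIENT_FLOOR
    return ok, f"scaled gradients {g1:.3g}, {g2:.3g} (floor {GRADIENT_FLOOR})"


def depth_scaling(plan: ExperimentPlan) -> ScalingResult:
    """Exact E(T) vs depth ``d1`` (with ``d2 = d1 + 1``); ln-slope sandwich."""
    if plan.rule is None or not plan.d1_grid:
        raise ValueError("depth-scaling needs a rule and a d1 grid")
    l1, l2 = plan.valley.l1, plan.valley.l2
    rows = []
    for d1 in plan.d1_grid:
        v = ValleySpec(l1=l1, l2=l2, d1=d1, d2=d1 + 1)
        ok, why = _gradient_ok(plan.rule, v)
        if not ok:
            rows.append({"d1": d1, "expected_steps": np.nan, "in_regime": False, "note": why})
            continue
        rows.append({
            "d1": d1,
            "expected_steps": valley_expected_time(v, plan.rule),
            "in_regime": True,
            "note": why,
        })
    table = pd.DataFrame(rows)
    used = table[table["in_regime"]]
    if len(used) < 2:
        raise ValueError("fewer than two in-regime depth cells; cannot fit a slope")
    fit = scipy.stats.linregress(used["d1"], np.log(used["expected_steps"]))
    lo, hi = _depth_sandwich(plan.rule, l1)
    table.attrs["sandwich"] = (lo, hi)
    table.attrs["slope_in_sandwich"] = bool(lo <= fit.slope <= hi)
    return ScalingResult(table, fit.slope, fit.stderr, plan)


def valleypath_scaling(plan: ExperimentPlan) -> ScalingResult:
    """Exact E(T_m) over the m grid; linearity ratio and per-cell drift."""
    if plan.rule is None or not plan.ms:
        raise ValueError("valleypath-scaling needs a rule and an m grid")
    v = plan.valley
    lam = plan.rule.lam
    drift_condition = lam * (v.d2 - v.d1) >= 1.0
    report = drift_report(ValleyPathSpec(m=max(2, max(plan.ms)), valley=v), plan.rule)
    rows = []
    for m in plan.ms:
        et = valleypath_expected_time(ValleyPathSpec(m=m, valley=v), plan.rule)
        rows.append({
            "m": m,
            "expected_steps": et,
            "per_valley": et / m,
            "drift": report.drift,
            "drift_condition": drift_condition,
        })
    table = pd.DataFrame(rows)
    per = table["per_valley"]
    table.attrs["linearity_ratio"] = float(per.max() / per.min())
    table.attrs["drift_report"] = report
    # slope of E(T_m) in m; SE for reference
    fit = scipy.stats.linregress(table["m"], table["expected_steps"])
    warnings = [] if drift_condition else [
        f"drift condition lam*(d2-d1) >= 1 not met (lam={lam:.3g}); linearity not asserted"
    ]
    return ScalingResult(table, fit.slope, fit.stderr, plan, warnings)


def cross_mode_check(
    valley: ValleySpec,
    rule: AcceptanceRule,
    n: int,
    k: int,
    replicates: int,
    seed: int,
    budget: int = 10**8,
) -> dict:
    """Chain-mode means vs the exact solve, and the n/2 conversion ratio.

    Runs the reduced chain for ``rule`` and reports mean relevant steps with
    standard errors next to the exact linear-solve expectation.  The
    bitstring and segment-jump comparisons live in the test suite (they need
    the full path machinery); this driver covers the chain/exact pair, the
    cheapest reproducible cross-check.
    """
    heights = valley_heights(valley)
    exact = valley_expected_time(valley, rule)
    steps = []
    for r in range(replicates):
        cfg = SimulationConfig(mode="chain", max_evaluations=budget, seed=seed + r)
        steps.append(run_chain(heights, rule, cfg, n=n).relevant_steps)
    steps = np.asarray(steps, dtype=float)
    return {
        "exact_relevant_steps": exact,
        "mean_relevant_steps": float(steps.mean()),
        "se": float(steps.std(ddof=1) / math.sqrt(len(steps))),
        "evaluation_estimate": float(steps.mean() * n / 2),
        "n_over_2": n / 2,
        "replicates": replicates,
    }


def generate_fixtures(seed: int, outdir: Path) -> list[Path]:
    """Write deterministic small regression instances.

    The worked long-path example (n=9, k=3, 22 points), three canonical
    Valley specs and one ValleyPath spec with their exact expected crossing
    times under reference rules.  Byte-identical across runs with the same
    seed (the content is deterministic; the seed is recorded for provenance).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    path_file = outdir / "longpath_n9_k3.tsv"
    lines = [f"{p.index}\t{p.bits}" for p in build_path(LongKPathSpec(9, 3))]
    path_file.write_text("\n".join(lines) + "\n")
    written.append(path_file)

    valleys = {
        "shallow": ValleySpec(2, 2, 1.0, 2.0),
        "standard": ValleySpec(2, 2, 2.0, 4.0),
        "asymmetric": ValleySpec(3, 5, 2.0, 3.0),
    }
    rules = {
        "sswm_b1_N2": AcceptanceRule.sswm(1.0, 2),
        "metropolis_a1": AcceptanceRule.metropolis(1.0),
    }
    records = {}
    for vname, v in valleys.items():
        records[vname] = {
            "spec": vars(v).copy(),
            "effective_length": effective_length(v),
            "expected_steps": {
                rname: valley_expected_time(v, r) for rname, r in rules.items()
            },
        }
    vp = ValleyPathSpec(m=4, valley=valleys["standard"])
    records["valleypath_m4_standard"] = {
        "m": vp.m,
        "valley": vars(vp.valley).copy(),
        "expected_steps": {
            rname: valleypath_expected_time(vp, r) for rname, r in rules.items()
        },
    }
    fixture_file = outdir / "exact_times.json"
    fixture_file.write_text(json.dumps({"seed": seed, "instances": records}, indent=2, sort_keys=True) + "\n")
    written.append(fixture_file)
    return written
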