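"""Valley and ValleyPath height functions.

A Valley is the canonical tunable fitness valley: starting from a local
optimum of height ``d1`` the fitness drops linearly over ``l1`` steps to 0,
then rises linearly over ``l2`` steps to the opposite optimum of height
``d2``.  The slope steepnesses are ``d1/l1`` and ``d2/l2``.  With
``d2 > d1`` the far end is the unique optimum.

A ValleyPath concatenates ``m`` identical valleys, each shifted upward by
``d2 - d1`` relative to its predecessor so that consecutive peaks gain
exactly that amount: a rugged landscape with a global gradient toward the
last peak, the global optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ValleySpec",
    "ValleyPathSpec",
    "valley_height",
    "valley_heights",
    "valleypath_height",
    "global_heights",
    "effective_length",
    "enumerate_extrema",
]


@dataclass(frozen=True)
class ValleySpec:
    """Geometry of one valley: slope lengths ``l1, l2 >= 2``, peak heights
    ``d1, d2 > 0`` with ``d1 <= d2``."""

    l1: int
    l2: int
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.l1 < 2 or self.l2 < 2:
            raise ValueError(f"slope lengths must be >= 2, got l1={self.l1}, l2={self.l2}")
        if not (self.d1 > 0 and self.d2 > 0):
            raise ValueError(f"peak heights must be positive, got d1={self.d1}, d2={self.d2}")
        if self.d1 > self.d2:
            raise ValueError(f"need d1 <= d2, got d1={self.d1} > d2={self.d2}")

    @property
    def length(self) -> int:
        """Total valley length ``l = l1 + l2``."""
        return self.l1 + self.l2


@dataclass(frozen=True)
class ValleyPathSpec:
    """``m >= 1`` consecutive identical valleys; requires strict ``d1 < d2``
    so consecutive peaks strictly increase."""

    m: int
    valley: ValleySpec

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"number of valleys must be >= 1, got m={self.m}")
        if not self.valley.d1 < self.valley.d2:
            raise ValueError(
                f"ValleyPath requires d1 < d2, got d1={self.valley.d1}, d2={self.valley.d2}"
            )

    @property
    def length(self) -> int:
        """Number of path steps, ``m * l``; the optimum sits at this index."""
        return self.m * self.valley.length


def valley_height(spec: ValleySpec, i: int) -> float:
    """Height ``h(i)`` at position ``0 <= i <= l`` of a single valley."""
    if not 0 <= i <= spec.length:
        raise IndexError(f"position {i} outside [0, {spec.length}]")
    if i <= spec.l1:
        return spec.d1 - i * spec.d1 / spec.l1
    return (i - spec.l1) * spec.d2 / spec.l2


def valley_heights(spec: ValleySpec) -> np.ndarray:
    """All heights ``h(0..l)`` of a single valley."""
    return np.array([valley_height(spec, i) for i in range(spec.length + 1)])


def valleypath_height(spec: ValleyPathSpec, j: int, i: int) -> float:
    """Height ``h(i, j)`` at within-valley position ``i`` of valley ``j``.

    ``1 <= j <= m`` and ``0 <= i <= l``; valley ``j`` is offset upward by
    ``j * (d2 - d1)``.  The boundary values coincide:
    ``h(l, j) == h(0, j+1)``.
    """
    v = spec.valley
    if not 1 <= j <= spec.m:
        raise IndexError(f"valley index {j} outside [1, {spec.m}]")
    if not 0 <= i <= v.length:
        raise IndexError(f"position {i} outside [0, {v.length}]")
    shift = j * (v.d2 - v.d1)
    if i <= v.l1:
        return shift + v.d1 - i * v.d1 / v.l1
    return shift + (i - v.l1) * v.d2 / v.l2


def global_heights(spec: ValleyPathSpec) -> np.ndarray:
    """Flattened height profile over global indices ``0 .. m*l``.

    Global index ``g`` maps to valley ``j = clamp(ceil(g / l), 1, m)`` and
    within-valley position ``i = g - (j - 1) * l``; the shared boundary
    points have equal heights in both adjoining valleys, so the clamping
    choice is value-irrelevant but fixes the indexing.
    """
    ell = spec.valley.length
    out = np.empty(spec.m * ell + 1)
    for g in range(spec.m * ell + 1):
        j = min(max(-(-g // ell), 1), spec.m)
        out[g] = valleypath_height(spec, j, g - (j - 1) * ell)
    return out


def effective_length(spec: ValleySpec) -> int:
    """Effective length ``l* = l1 + ceil(d1 * l2 / d2)``.

    The distance from the starting peak to the first valley point of at
    least equal fitness -- the jump distance an elitist algorithm must cover,
    which governs its ``Theta(n**l*)`` crossing time.
    """
    return spec.l1 + math.ceil(spec.d1 * spec.l2 / spec.d2)


def enumerate_extrema(spec: ValleyPathSpec) -> tuple[list[int], list[int]]:
    """Global indices of the ``m + 1`` peaks and ``m`` minima of a ValleyPath."""
    ell = spec.valley.length
    peaks = [j * ell for j in range(spec.m + 1)]
    minima = [(j - 1) * ell + spec.valley.l1 for j in range(1, spec.m + 1)]
    return peaks, minima
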