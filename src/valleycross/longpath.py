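"""Long k-paths: Hamming paths of exponential length in :math:`\\{0,1\\}^n`.

A long k-path is a sequence of bit strings in which consecutive points differ
in exactly one bit, yet whose length ``k * 2**(n/k) - k + 1`` is exponential in
``n`` when ``k = Theta(sqrt(n))``.  Its defining feature is shortcut
resistance: any two points that are ``i < k`` positions apart on the path are
at Hamming distance exactly ``i``, while points ``>= k`` apart are at Hamming
distance at least ``k``, so skipping ahead requires flipping at least ``k``
bits simultaneously.

The construction is recursive.  The path of dimension 0 is the empty string.
Given the path ``(p_1, ..., p_L)`` of dimension ``n - k``, the dimension-``n``
path is the concatenation of

* ``S0 = (0^k p_1, ..., 0^k p_L)``,
* the bridge ``B = (0^{k-1} 1 p_L, 0^{k-2} 1^2 p_L, ..., 0 1^{k-1} p_L)``,
* ``S1 = (1^k p_L, ..., 1^k p_1)`` (the recursive path reversed).

Points are generated and decoded lazily by recursion on the index, so a prefix
of an exponentially long path costs only what the prefix needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator, Optional, Sequence, Union

__all__ = [
    "LongKPathSpec",
    "PathPoint",
    "HammingReport",
    "OFF_PATH",
    "OffPath",
    "path_length",
    "build_path",
    "point_at",
    "index_of",
    "verify_hamming_property",
    "embed_fitness",
    "PathFitness",
    "largest_fold",
]

#: Cap on full materialisation of a path (number of points).
MATERIALISE_CAP = 1 << 20


class OffPath:
    """Sentinel for strings that are not on the (fitness-carrying) path.

    A distinguished object rather than a huge negative float so that every
    acceptance rule maps it to probability 0 exactly (including Metropolis,
    where ``exp(alpha * delta)`` of a large negative float would merely be
    tiny, not zero).
    """

    _instance: Optional["OffPath"] = None

    def __new__(cls) -> "OffPath":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "OFF_PATH"


OFF_PATH = OffPath()


class InvalidSpecError(ValueError):
    """The (n, k) pair does not describe a long k-path."""


@dataclass(frozen=True)
class LongKPathSpec:
    """Dimension ``n`` and fold parameter ``k`` of a long k-path.

    ``n`` must be a non-negative multiple of ``k`` (``n = 0`` gives the
    trivial path containing only the empty string).
    """

    n: int
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidSpecError(f"fold parameter k must be >= 1, got k={self.k}")
        if self.n < 0:
            raise InvalidSpecError(f"dimension n must be >= 0, got n={self.n}")
        if self.n % self.k != 0:
            raise InvalidSpecError(
                f"dimension n={self.n} is not a multiple of fold parameter k={self.k}"
            )


@dataclass(frozen=True)
class PathPoint:
    """A point on a long k-path: 0-based ``index`` and its bit string."""

    index: int
    bits: str


def path_length(spec: LongKPathSpec) -> int:
    """Number of points on the path: ``k * 2**(n/k) - k + 1`` (1 for n=0)."""
    if spec.n == 0:
        return 1
    return spec.k * 2 ** (spec.n // spec.k) - spec.k + 1


def point_at(spec: LongKPathSpec, index: int) -> str:
    """Bit string of the path point at ``index`` (lazy recursive descent)."""
    length = path_length(spec)
    if not 0 <= index < length:
        raise IndexError(f"index {index} outside path of length {length}")
    n, k = spec.n, spec.k
    parts: list[str] = []
    while n > 0:
        sub = LongKPathSpec(n - k, k)
        sub_len = path_length(sub)
        if index < sub_len:  # inside S0
            parts.append("0" * k)
        elif index < sub_len + (k - 1):  # on the bridge
            j = index - sub_len + 1  # 1 .. k-1 ones
            parts.append("0" * (k - j) + "1" * j)
            index = sub_len - 1
        else:  # inside S1, recursion reversed
            parts.append("1" * k)
            index = 2 * sub_len + k - 2 - index
        n -= k
    return "".join(parts)


def build_path(
    spec: LongKPathSpec, limit: Optional[int] = None
) -> list[PathPoint]:
    """The first ``limit`` points of the path (all points if ``limit`` is None).

    Full materialisation is refused above ``MATERIALISE_CAP`` points; pass an
    explicit ``limit`` for long paths.
    """
    length = path_length(spec)
    if limit is None:
        if length > MATERIALISE_CAP:
            raise InvalidSpecError(
                f"path has {length} points, above the materialisation cap "
                f"{MATERIALISE_CAP}; pass limit= to take a prefix"
            )
        limit = length
    if not 0 <= limit <= length:
        raise IndexError(f"limit {limit} outside [0, {length}]")
    return [PathPoint(i, point_at(spec, i)) for i in range(limit)]


def iter_path(spec: LongKPathSpec, limit: Optional[int] = None) -> Iterator[PathPoint]:
    """Lazily iterate path points in order."""
    length = path_length(spec)
    stop = length if limit is None else min(limit, length)
    for i in range(stop):
        yield PathPoint(i, point_at(spec, i))


def index_of(spec: LongKPathSpec, bits: str) -> Union[int, OffPath]:
    """Index of ``bits`` on the path, or :data:`OFF_PATH` if it is not on it.

    Recursive decode mirroring the construction: a ``0^k`` prefix places the
    string in ``S0``, a ``1^k`` prefix in ``S1`` (reversed recursion), a
    ``0^{k-j} 1^j`` prefix in the bridge provided the tail is the last point
    of the recursive path; anything else is off the path.
    """
    if len(bits) != spec.n:
        raise ValueError(f"bit string of length {len(bits)} != n={spec.n}")
    if any(c not in "01" for c in bits):
        raise ValueError("bit string must consist of 0/1 characters")
    return _decode(spec.n, spec.k, bits)


def _decode(n: int, k: int, bits: str) -> Union[int, OffPath]:
    if n == 0:
        return 0
    prefix = bits[:k]
    sub_len = path_length(LongKPathSpec(n - k, k))
    ones = prefix.count("1")
    if ones == 0:  # S0: same orientation as the recursive path
        return _decode(n - k, k, bits[k:])
    if ones == k:  # S1: recursive path reversed
        t = _decode(n - k, k, bits[k:])
        if t is OFF_PATH:
            return OFF_PATH
        return path_length(LongKPathSpec(n, k)) - 1 - t
    if prefix == "0" * (k - ones) + "1" * ones:
        # bridge point with j=ones leading ones; tail must be the last
        # point of the recursive path
        t = _decode(n - k, k, bits[k:])
        if t is OFF_PATH or t != sub_len - 1:
            return OFF_PATH
        return sub_len + ones - 1
    return OFF_PATH


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class HammingReport:
    """Outcome of the shortcut-resistance check over all point pairs."""

    spec: LongKPathSpec
    ok: bool
    violations: tuple[tuple[int, int, int], ...]  # (s, s+i, observed distance)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def verify_hamming_property(spec: LongKPathSpec) -> HammingReport:
    """Check H(P_s, P_{s+i}) == i for i < k and >= k for i >= k, all pairs."""
    points = [p.bits for p in build_path(spec)]
    violations: list[tuple[int, int, int]] = []
    for s in range(len(points)):
        for t in range(s, len(points)):
            i = t - s
            d = hamming(points[s], points[t])
            if i < spec.k:
                if d != i:
                    violations.append((s, t, d))
            elif d < spec.k:
                violations.append((s, t, d))
    return HammingReport(spec, not violations, tuple(violations))


class PathFitness:
    """Fitness embedding of a height profile on the first ``m`` path points.

    ``f(x) = heights[i]`` when ``x`` is the i-th path point and ``i < m``;
    every other string (off the path, or on it beyond the profile) maps to the
    :data:`OFF_PATH` sentinel, which every acceptance rule rejects with
    probability exactly 0.

    The first ``m`` points are materialised into a dict for O(1) lookup, so
    ``m`` must stay below the materialisation cap; the path itself may be
    exponentially long.
    """

    def __init__(self, spec: LongKPathSpec, heights: Sequence[float]):
        if len(heights) == 0:
            raise InvalidSpecError("heights must be non-empty")
        if len(heights) > path_length(spec):
            raise InvalidSpecError(
                f"{len(heights)} heights exceed path length {path_length(spec)}"
            )
        self.spec = spec
        self.heights = tuple(float(h) for h in heights)
        self.m = len(heights)
        self._index = {point_at(spec, i): i for i in range(self.m)}
        self._points = sorted(self._index, key=self._index.get)
        self.optimum_index = max(range(self.m), key=lambda i: (self.heights[i], i))

    def __call__(self, bits: str) -> Union[float, OffPath]:
        i = self._index.get(bits)
        return OFF_PATH if i is None else self.heights[i]

    def index(self, bits: str) -> Union[int, OffPath]:
        """Index among the fitness-carrying points, OFF_PATH otherwise."""
        i = self._index.get(bits)
        return OFF_PATH if i is None else i

    def point(self, i: int) -> str:
        return self._points[i]

    @property
    def optimum_bits(self) -> str:
        return self._points[self.optimum_index]


def embed_fitness(spec: LongKPathSpec, heights: Sequence[float]) -> PathFitness:
    """Build the path fitness function for a height profile (see PathFitness)."""
    return PathFitness(spec, heights)


def largest_fold(n: int) -> int:
    """Largest k <= ceil(sqrt(n)) dividing n (the usual shortcut-resistant fold).

    The theory fixes ``k = sqrt(n)``, which rarely divides ``n`` exactly; this
    helper picks the closest admissible value from below.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cap = math.isqrt(n)
    if cap * cap < n:
        cap += 1  # ceil(sqrt(n))
    for k in range(min(cap, n), 0, -1):
        if n % k == 0:
            return k
    return 1  # pragma: no cover - unreachable, 1 divides n
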