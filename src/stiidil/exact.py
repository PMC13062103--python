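"""Exact (enumerative) Shapley-Taylor interaction index, order 2.

The order-2 Shapley-Taylor index attributes a model's output change
``v(N) - v(0)`` to per-feature main effects and symmetric pairwise
interaction effects.  Pair values average the discrete derivative

    I(f, S) = sum_{T subset N\\S}  w(t)  *  delta_S f(T),   |S| = 2,

where ``delta_S f(T)`` is the inclusion-exclusion second difference of the
coalition value over subsets of S on top of context T and ``w`` is a
coalition-size weighting kernel (see the variant note below).

Exact computation enumerates all 2^d coalitions and is gated by a cap
(default d <= 12); beyond that use the kernel estimator.
"""

# Two weighting conventions are provided (they coincide on additive +
# pairwise models, which is the regime the kernel estimator targets):
#
# * ``sundararajan`` — the order-2 Shapley-Taylor index: mains are the
#   lowest-order discrete derivative delta_i f(0); pairs average the second
#   derivative with weight 2 / (n * C(n-1, t)).  Attributions provably sum
#   to v(N) - v(0) for every coalition game (the efficiency axiom).
# * ``shapley_interaction`` — the classical Shapley interaction index:
#   mains are Shapley values (weight t! (n-t-1)! / n!) and pairs use weight
#   t! (n-t-2)! / (n-1)!.  This convention does not satisfy efficiency on
#   games with third-or-higher-order structure.

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional

import numpy as np
from scipy.special import gammaln

from .core import Coalition, PatientState, ValueFunction, coalition_value

__all__ = [
    "ExplanationCoefficients",
    "UnsupportedOrderError",
    "EnumerationCapError",
    "STII_VARIANTS",
    "discrete_derivative",
    "stii_set_value",
    "explain_exact",
    "efficiency_gap",
    "memoized_game",
]

STII_VARIANTS = ("sundararajan", "shapley_interaction")


class UnsupportedOrderError(ValueError):
    """Requested interaction order is not supported (this tool is order-2)."""


class EnumerationCapError(ValueError):
    """d exceeds the exact-enumeration cap; use the kernel estimator."""


@dataclass
class ExplanationCoefficients:
    """Explanation coefficients: main-effect vector + symmetric pair matrix.

    ``main[i]`` and ``pair[i, j]`` are in the model's output units (U of
    insulin adjustment).  ``intercept`` anchors the explanation at the
    empty-coalition prediction v(0).  The canonical in-memory layout is
    d mains plus an upper-triangular pair matrix mirrored to symmetric;
    :meth:`flatten` emits the redundant d^2 + d layout (ordered pairs each
    carrying half the interaction) for serialization compatibility.
    """

    main: np.ndarray
    pair: np.ndarray
    intercept: float = 0.0
    variant: str = "sundararajan"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.main = np.asarray(self.main, dtype=float)
        self.pair = np.asarray(self.pair, dtype=float)
        d = self.main.shape[0]
        if self.pair.shape != (d, d):
            raise ValueError("pair matrix shape must be (d, d)")
        if not np.allclose(self.pair, self.pair.T, atol=1e-12, rtol=0.0):
            raise ValueError("pair matrix must be symmetric")
        if np.any(np.abs(np.diag(self.pair)) > 1e-12):
            raise ValueError("pair matrix must have zero diagonal")
        if not (np.all(np.isfinite(self.main)) and np.all(np.isfinite(self.pair))):
            raise ValueError("coefficients must be finite")
        # exact symmetry / zero diagonal after validation
        self.pair = 0.5 * (self.pair + self.pair.T)
        np.fill_diagonal(self.pair, 0.0)

    @property
    def d(self) -> int:
        return int(self.main.shape[0])

    def total(self) -> float:
        """Sum of all attributions: mains plus each unordered pair once."""
        iu = np.triu_indices(self.d, k=1)
        return float(self.main.sum() + self.pair[iu].sum())

    def flatten(self) -> np.ndarray:
        """d^2 + d flat layout: mains, then row-major ordered pairs (halved)."""
        d = self.d
        out = np.empty(d * d + d)
        out[:d] = self.main
        out[d:] = (0.5 * self.pair).ravel()
        return out

    @classmethod
    def from_flat(cls, flat: np.ndarray, variant: str = "sundararajan") -> "ExplanationCoefficients":
        flat = np.asarray(flat, dtype=float)
        # d^2 + d = len  =>  d = (-1 + sqrt(1 + 4 len)) / 2
        d = int(round((-1 + np.sqrt(1 + 4 * flat.size)) / 2))
        if d * d + d != flat.size:
            raise ValueError(f"flat length {flat.size} is not of the form d^2 + d")
        main = flat[:d].copy()
        half = flat[d:].reshape(d, d)
        pair = half + half.T
        np.fill_diagonal(pair, 0.0)
        return cls(main=main, pair=pair, variant=variant)


def discrete_derivative(
    v: Callable[[Coalition], float], S: Coalition, T: Coalition
) -> float:
    """Inclusion-exclusion difference: sum_{W subset S} (-1)^{|S|-|W|} v(T u W)."""
    if S.members & T.members:
        raise ValueError(f"S and T must be disjoint; overlap {sorted(S.members & T.members)}")
    s_list = sorted(S.members)
    total = 0.0
    for r in range(len(s_list) + 1):
        sign = (-1.0) ** (len(s_list) - r)
        for W in combinations(s_list, r):
            total += sign * v(Coalition(T.members | set(W)))
    return total


def _log_weight(n: int, t: int, s: int, variant: str) -> float:
    """Context-size weight in log space (factorials via log-gamma)."""
    if variant == "sundararajan":
        if s == 2:
            # 2 / (n * C(n-1, t))
            return (
                np.log(2.0)
                - np.log(n)
                - (gammaln(n) - gammaln(t + 1) - gammaln(n - t))
            )
        raise AssertionError("sundararajan singletons are not context-averaged")
    # shapley_interaction: t! (n-t-s)! / (n-s+1)!
    return gammaln(n - t - s + 1) + gammaln(t + 1) - gammaln(n - s + 2)


def stii_set_value(
    v: Callable[[Coalition], float],
    S: Coalition,
    N_size: int,
    variant: str = "sundararajan",
) -> float:
    """Attribution of a feature set S by full enumeration of contexts T.

    Only |S| in {1, 2} is supported: the tool is an order-2 explainer.
    Under the default variant a singleton is the plain discrete derivative
    at the empty context; under ``shapley_interaction`` it is the classical
    Shapley value.
    """
    if variant not in STII_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {STII_VARIANTS}")
    s = len(S)
    if s not in (1, 2):
        raise UnsupportedOrderError(f"|S|={s}: only orders 1 and 2 are supported")
    if s == 1 and variant == "sundararajan":
        return discrete_derivative(v, S, Coalition())
    rest = sorted(set(range(N_size)) - S.members)
    total = 0.0
    for t in range(len(rest) + 1):
        w = float(np.exp(_log_weight(N_size, t, s, variant)))
        for T in combinations(rest, t):
            total += w * discrete_derivative(v, S, Coalition(T))
    return total


def memoized_game(f: ValueFunction, x: PatientState) -> Callable[[Coalition], float]:
    """Wrap v(S) with a bitmask-keyed cache; one model call per distinct coalition."""
    cache: dict[int, float] = {}

    def v(S: Coalition) -> float:
        key = 0
        for i in S.members:
            key |= 1 << i
        if key not in cache:
            cache[key] = coalition_value(f, x, S)
        return cache[key]

    return v


def explain_exact(
    f: ValueFunction,
    x: PatientState,
    variant: str = "sundararajan",
    cap: int = 12,
) -> ExplanationCoefficients:
    """Exact order-2 Shapley-Taylor coefficients by full enumeration.

    Evaluates the model on all 2^d coalitions (memoized), then assembles
    main effects (per the selected variant) and pairwise interactions.
    """
    if variant not in STII_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {STII_VARIANTS}")
    d = x.d
    if d > cap:
        raise EnumerationCapError(
            f"d={d} exceeds the exact-enumeration cap ({cap}); "
            "use stiidil.kernel.explain_kernel instead"
        )
    v = memoized_game(f, x)
    empty = Coalition()
    v0 = v(empty)

    main = np.zeros(d)
    for i in range(d):
        if variant == "sundararajan":
            main[i] = v(Coalition({i})) - v0
        else:  # context-averaged singleton = classical Shapley value
            main[i] = stii_set_value(v, Coalition({i}), d, variant=variant)

    pair = np.zeros((d, d))
    for i, j in combinations(range(d), 2):
        val = stii_set_value(v, Coalition({i, j}), d, variant=variant)
        pair[i, j] = pair[j, i] = val

    return ExplanationCoefficients(
        main=main, pair=pair, intercept=v0, variant=variant, meta={"method": "exact", "d": d}
    )


def efficiency_gap(coeffs: ExplanationCoefficients, f: ValueFunction, x: PatientState) -> float:
    """|sum of all attributions - (v(N) - v(0))|, in U."""
    vN = coalition_value(f, x, Coalition(range(x.d)))
    v0 = coalition_value(f, x, Coalition())
    return float(abs(coeffs.total() - (vN - v0)))
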