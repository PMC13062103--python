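"""Comparator explainers: first-order kernel SHAP, integrated gradients,
permutation importance.

All three are model-agnostic over the same :class:`~stiidil.core.ValueFunction`
contract and share the coalition/baseline semantics of the main explainer,
so their attribution vectors are directly comparable with the order-2
Shapley-Taylor main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Coalition, PatientState, ValueFunction, coalition_value
from .kernel import sample_coalitions, shapley_kernel_weight, solve_anchored

__all__ = [
    "AttributionVector",
    "kernel_shap",
    "integrated_gradients",
    "permutation_importance",
]


@dataclass
class AttributionVector:
    """Per-feature attribution in model output units (U)."""

    values: np.ndarray
    method: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attributions must be finite")
        if self.method not in ("shap", "ig", "permutation"):
            raise ValueError(f"unknown method {self.method!r}")


def kernel_shap(
    f: ValueFunction,
    x: PatientState,
    M: Optional[int] = None,
    seed: int = 0,
    exhaustive_cap: int = 14,
) -> AttributionVector:
    """First-order Shapley values via the anchored kernel regression.

    The design keeps only the main (mask) columns; the efficiency anchors
    force sum(phi) = v(N) - v(0).  With exhaustive coalitions (the default
    for d <= ``exhaustive_cap``) this reproduces classical Shapley values
    exactly for any coalition game.
    """
    d = x.d
    scheme = "exhaustive" if (M is None and d <= exhaustive_cap) else "kernel_prop"
    samples = sample_coalitions(
        d, M if M is not None else 2048, seed=seed, scheme=scheme, exhaustive_cap=exhaustive_cap
    )
    v0 = coalition_value(f, x, Coalition())
    vN = coalition_value(f, x, Coalition(range(d)))
    X = np.array([s.mask for s in samples], dtype=float)
    y = np.array([coalition_value(f, x, Coalition(np.flatnonzero(s.mask))) for s in samples])
    w = np.array([s.weight for s in samples])
    A = X.T @ (X * w[:, None])
    b = X.T @ (w * (y - v0))
    phi = solve_anchored(A, b, vN - v0)
    return AttributionVector(
        values=phi,
        method="shap",
        extras={"scheme": scheme, "seed": seed, "n_coalitions": len(samples)},
    )


def integrated_gradients(
    f: ValueFunction,
    x: PatientState,
    steps: int = 64,
    fd_fallback: bool = True,
) -> AttributionVector:
    """Path attribution along the straight line baseline -> x.

    IG_i = (x_i - b_i) * mean_t df/dz_i(b + t (x - b)) over the midpoint
    grid t = (k + 1/2)/steps.  Gradients come from the model's analytic
    gradient when available, otherwise (with ``fd_fallback``) from central
    finite differences with step 1e-4 per feature scale.  The completeness
    gap |sum IG - (f(x) - f(b))| is reported in ``extras``.
    """
    if steps < 8:
        raise ValueError("steps must be >= 8")
    if f.gradient is None and not fd_fallback:
        raise ValueError("model exposes no gradient and finite-difference fallback is disabled")
    delta = x.values - x.baseline
    d = x.d
    if f.gradient is not None:
        grad = lambda z: np.asarray(f.gradient(z), dtype=float)
    else:
        h = 1e-4 * np.maximum(1.0, np.abs(delta))

        def grad(z: np.ndarray) -> np.ndarray:
            g = np.zeros(d)
            for i in range(d):
                zp, zm = z.copy(), z.copy()
                zp[i] += h[i]
                zm[i] -= h[i]
                g[i] = (f(zp) - f(zm)) / (2.0 * h[i])
            return g

    ts = (np.arange(steps) + 0.5) / steps
    avg = np.zeros(d)
    for t in ts:
        avg += grad(x.baseline + t * delta)
    avg /= steps
    attr = delta * avg
    gap = abs(float(attr.sum()) - (f(x.values) - f(x.baseline)))
    return AttributionVector(
        values=attr, method="ig", extras={"steps": steps, "completeness_gap": gap}
    )


def permutation_importance(
    f: ValueFunction,
    dataset: Sequence[PatientState],
    n_repeats: int = 10,
    seed: int = 0,
) -> AttributionVector:
    """Mean squared-prediction shift under within-column shuffling.

    Scores are self-consistent (against the model's own unshuffled
    predictions) since synthetic cohorts carry no observed dose labels.
    Constant columns score exactly 0 and are listed in ``extras``.
    """
    if len(dataset) < 10:
        raise ValueError("permutation importance needs a dataset of >= 10 instances")
    d = dataset[0].d
    Xmat = np.array([p.values for p in dataset])
    base_pred = np.array([f(row) for row in Xmat])
    rng = np.random.default_rng(seed)
    scores = np.zeros(d)
    constant = []
    for i in range(d):
        if np.ptp(Xmat[:, i]) == 0.0:
            constant.append(i)
            continue
        acc = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(len(dataset))
            Xs = Xmat.copy()
            Xs[:, i] = Xmat[perm, i]
            pred = np.array([f(row) for row in Xs])
            acc += float(np.mean((pred - base_pred) ** 2))
        scores[i] = acc / n_repeats
    return AttributionVector(
        values=scores,
        method="permutation",
        extras={"n_repeats": n_repeats, "seed": seed, "constant_columns": constant},
    )
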