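"""Kernel-regression estimation of order-2 Shapley-Taylor coefficients.

Instead of enumerating all coalitions, the estimator draws M coalition
masks, evaluates the black-box model once per distinct mask, and solves a
Shapley-kernel-weighted regression of the coalition values onto a design
of main-effect columns (the mask itself) and pairwise columns (ANDs of
mask pairs):

    min_alpha  sum_m w_m (<alpha, x_m> + v0 - y_m)^2  +  lambda ||alpha||_1

with the kernel weight w_m = (d-1) / (C(d, z) z (d - z)), z = ||x_m||_0.
The two infinite-weight coalitions (empty and full) are enforced as hard
anchors: the intercept equals v(empty) and the coefficients sum to
v(N) - v(empty), which makes every fit satisfy the efficiency axiom
exactly.  On models whose coalition game is multilinear of degree <= 2
(additive + pairwise), the exhaustive unpenalized fit reproduces the exact
order-2 Shapley-Taylor coefficients.

The solver here is shared with the clinical-constraint layer
(:mod:`stiidil.constraints`), which passes an additional convex penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import comb

from .core import Coalition, PatientState, ValueFunction, coalition_value
from .exact import ExplanationCoefficients

__all__ = [
    "CoalitionSample",
    "DesignMatrix",
    "IllPosedFitError",
    "shapley_kernel_weight",
    "sample_coalitions",
    "build_design",
    "pair_column_index",
    "solve_anchored",
    "fit_weighted_lasso",
    "explain_kernel",
    "fit_random_forest_surrogate",
]

SAMPLING_SCHEMES = ("uniform_z", "kernel_prop", "exhaustive")


class IllPosedFitError(RuntimeError):
    """The unpenalized weighted regression is singular/underdetermined."""


@dataclass
class CoalitionSample:
    """One (deduplicated) coalition row of the regression design."""

    mask: np.ndarray  # bool, length d; True = feature kept from x
    z: int  # number of kept features
    weight: float  # regression weight (kernel and/or multiplicity)
    multiplicity: int = 1
    y: float = float("nan")  # coalition value, filled after model evaluation


def shapley_kernel_weight(d: int, z: int) -> float:
    """Shapley kernel weight (d-1) / (C(d,z) * z * (d-z)) for 1 <= z <= d-1."""
    if d < 2:
        raise ValueError("d must be >= 2")
    if not 1 <= z <= d - 1:
        raise ValueError(
            f"z={z} has infinite kernel weight for d={d}; "
            "the empty/full coalitions are handled as hard anchors"
        )
    return (d - 1) / (comb(d, z, exact=True) * z * (d - z))


def pair_column_index(d: int, i: int, j: int) -> int:
    """Column of unordered pair (i, j), i < j, after the d main columns."""
    if not 0 <= i < j < d:
        raise ValueError(f"need 0 <= i < j < d, got ({i}, {j}), d={d}")
    return d + i * d - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class DesignMatrix:
    """Regression design: main columns then upper-triangular pair columns."""

    X: np.ndarray  # (M, p) float 0/1
    d: int
    columns: list  # ("main", i) or ("pair", (i, j)) per column

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(masks: np.ndarray, d: int) -> DesignMatrix:
    """Main column i = mask[i]; pair column (i,j) = mask[i] AND mask[j]."""
    masks = np.asarray(masks, dtype=bool)
    M = masks.shape[0]
    p = d + d * (d - 1) // 2
    X = np.zeros((M, p))
    X[:, :d] = masks
    columns: list = [("main", i) for i in range(d)]
    col = d
    for i, j in combinations(range(d), 2):
        X[:, col] = masks[:, i] & masks[:, j]
        columns.append(("pair", (i, j)))
        col += 1
    return DesignMatrix(X=X, d=d, columns=columns)


def _exhaustive_masks(d: int) -> np.ndarray:
    """All 2^d - 2 proper coalition masks, in bitmask order."""
    n = 2**d
    masks = np.zeros((n - 2, d), dtype=bool)
    for row, code in enumerate(range(1, n - 1)):
        for i in range(d):
            if code >> i & 1:
                masks[row, i] = True
    return masks


def sample_coalitions(
    d: int,
    M: int,
    seed: int = 0,
    scheme: str = "kernel_prop",
    exhaustive_cap: int = 14,
) -> list[CoalitionSample]:
    """Draw coalition masks and attach regression weights.

    Schemes:
      * ``exhaustive`` — all 2^d - 2 proper coalitions, weighted by the
        Shapley kernel (only for d <= ``exhaustive_cap``).
      * ``kernel_prop`` — complete coalition-size levels are enumerated
        exactly, outermost (highest per-mask kernel weight) first, while
        the budget M allows; the residual levels are sampled proportional
        to their aggregated kernel mass, each mask paired with its
        complement (antithetic pairing).  Enumerated rows carry their
        exact kernel weight; sampled rows share the residual kernel mass
        in proportion to their multiplicity.
      * ``uniform_z`` — z uniform on 1..d-1, mask uniform given z; row
        weight = multiplicity * kernel(d, z) * C(d, z) (importance
        correction back to the kernel measure).

    Deterministic given ``seed``; duplicate masks are merged with their
    multiplicity recorded.  Weights are normalized to sum to 1.
    """
    if scheme not in SAMPLING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SAMPLING_SCHEMES}")
    if d < 2:
        raise ValueError("d must be >= 2")

    if scheme == "exhaustive":
        if d > exhaustive_cap:
            raise ValueError(f"exhaustive sampling capped at d={exhaustive_cap}, got d={d}")
        masks = _exhaustive_masks(d)
        samples = []
        for row in masks:
            z = int(row.sum())
            samples.append(
                CoalitionSample(mask=row, z=z, weight=shapley_kernel_weight(d, z))
            )
        _normalize_weights(samples)
        return samples

    if M < 1:
        raise ValueError("M must be >= 1")
    p = d + d * (d - 1) // 2
    if M < p:
        warnings.warn(
            f"M={M} < p={p} design columns: the fit is underdetermined without "
            "an L1 penalty; increase M or rely on lambda_lasso > 0",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    zs = np.arange(1, d)

    if scheme == "uniform_z":
        counts: dict[bytes, int] = {}
        order: list[bytes] = []
        for _ in range(M):
            z = int(rng.integers(1, d))
            idx = rng.choice(d, size=z, replace=False)
            mask = np.zeros(d, dtype=bool)
            mask[idx] = True
            key = np.packbits(mask).tobytes()
            if key not in counts:
                counts[key] = 0
                order.append(key)
            counts[key] += 1
        samples = []
        for key in order:
            mask = np.unpackbits(np.frombuffer(key, dtype=np.uint8), count=d).astype(bool)
            z = int(mask.sum())
            mult = counts[key]
            weight = mult * shapley_kernel_weight(d, z) * comb(d, z, exact=True)
            samples.append(CoalitionSample(mask=mask, z=z, weight=weight, multiplicity=mult))
        _normalize_weights(samples)
        return samples

    # kernel_prop: enumerate complete outer levels, sample the rest
    level_mass = {
        z: comb(d, z, exact=True) * shapley_kernel_weight(d, z) for z in zs
    }
    # symmetric level pairs {z, d-z} ordered by per-mask weight (outermost first)
    level_pairs = []
    for z in range(1, d // 2 + 1):
        pair = sorted({z, d - z})
        if pair not in level_pairs:
            level_pairs.append(pair)
    enumerated: list[int] = []
    budget = M
    for pair in level_pairs:
        size = sum(comb(d, z, exact=True) for z in pair)
        if size <= budget:
            enumerated.extend(pair)
            budget -= size
        else:
            break
    samples = []
    for z in enumerated:
        from itertools import combinations as _comb

        for idx in _comb(range(d), z):
            mask = np.zeros(d, dtype=bool)
            mask[list(idx)] = True
            samples.append(
                CoalitionSample(mask=mask, z=z, weight=shapley_kernel_weight(d, z))
            )
    residual = [z for z in zs if z not in enumerated]
    if residual and budget > 1:
        res_mass = np.array([level_mass[z] for z in residual])
        res_pmf = res_mass / res_mass.sum()
        counts = {}
        order = []

        def _add(mask: np.ndarray) -> None:
            key = np.packbits(mask).tobytes()
            if key not in counts:
                counts[key] = 0
                order.append(key)
            counts[key] += 1

        n_draws = budget // 2
        for _ in range(n_draws):
            z = int(rng.choice(residual, p=res_pmf))
            idx = rng.choice(d, size=z, replace=False)
            mask = np.zeros(d, dtype=bool)
            mask[idx] = True
            _add(mask)
            _add(~mask)  # complement level is residual too, by symmetry
        total_mult = sum(counts.values())
        share = float(res_mass.sum()) / total_mult
        for key in order:
            mask = np.unpackbits(np.frombuffer(key, dtype=np.uint8), count=d).astype(bool)
            z = int(mask.sum())
            mult = counts[key]
            samples.append(
                CoalitionSample(mask=mask, z=z, weight=mult * share, multiplicity=mult)
            )
    _normalize_weights(samples)
    return samples


def _normalize_weights(samples: list[CoalitionSample]) -> None:
    tot = sum(s.weight for s in samples)
    for s in samples:
        s.weight /= tot


# ---------------------------------------------------------------------------
# Anchored penalized weighted least squares
# ---------------------------------------------------------------------------

_L1_EPS = 1e-9  # smoothing half-width for |a| ~ sqrt(a^2 + eps^2)


def solve_anchored(
    A: np.ndarray,
    b: np.ndarray,
    delta_v: float,
    lambda_lasso: float = 0.0,
    penalty=None,
    max_newton: int = 30,
    lbfgs_maxiter: int = 4000,
) -> np.ndarray:
    """Minimize a'Aa - 2b'a + lambda ||a||_1 + penalty(a)  s.t.  1'a = delta_v.

    ``A = X'WX`` and ``b = X'W(y - v0)`` are the normal-equation blocks of
    the kernel-weighted data term.  The efficiency anchor is the single
    equality constraint; it is eliminated exactly by a null-space
    parameterization, so every returned solution satisfies it to machine
    precision.

    Strategy: (1) closed-form KKT solve when the problem is purely
    quadratic; (2) otherwise an active-set Newton warm start over the
    quadratic penalty pieces followed by an L-BFGS polish of the full
    smooth objective (L1 smoothed with half-width 1e-9).
    """
    p = A.shape[0]
    ones = np.ones(p)

    def _kkt(A_eff: np.ndarray, b_eff: np.ndarray) -> np.ndarray:
        K = np.zeros((p + 1, p + 1))
        K[:p, :p] = 2.0 * A_eff
        K[:p, p] = ones
        K[p, :p] = ones
        rhs = np.concatenate([2.0 * b_eff, [delta_v]])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError as e:
            raise IllPosedFitError(
                "anchored weighted regression is singular; increase the number "
                "of sampled coalitions M or set lambda_lasso > 0"
            ) from e
        if not np.all(np.isfinite(sol)):
            raise IllPosedFitError(
                "anchored weighted regression produced non-finite solution; "
                "increase M or set lambda_lasso > 0"
            )
        return sol[:p]

    if lambda_lasso == 0.0 and penalty is None:
        if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, float(np.trace(A)))) < p - 1:
            # rank p-1 can still be fine thanks to the anchor; below that it is not
            raise IllPosedFitError(
                "design is rank deficient for an unpenalized fit; "
                "increase M or set lambda_lasso > 0"
            )
        return _kkt(A, b)

    # --- active-set Newton warm start on the quadratic pieces -------------
    ridge = 1e-10 * max(1.0, float(np.trace(A)) / p)
    alpha = _kkt(A + ridge * np.eye(p), b)
    if penalty is not None:
        for _ in range(max_newton):
            diag_add, lin_add = penalty.quadratic_terms(alpha)
            A_eff = A + np.diag(diag_add) + ridge * np.eye(p)
            b_eff = b + lin_add
            new = _kkt(A_eff, b_eff)
            if np.max(np.abs(new - alpha)) < 1e-12 * max(1.0, np.max(np.abs(new))):
                alpha = new
                break
            alpha = new

    if lambda_lasso == 0.0 and (penalty is None or penalty.is_quadratic):
        return alpha

    # --- L-BFGS polish of the full smooth objective ------------------------
    # null-space parameterization alpha = alpha0 + Z beta with 1'Z = 0
    alpha0 = np.full(p, delta_v / p)
    from scipy.linalg import null_space

    Z = null_space(ones[None, :])  # (p, p-1), orthonormal

    def fg(beta: np.ndarray):
        a = alpha0 + Z @ beta
        Aa = A @ a
        f = float(a @ Aa - 2.0 * b @ a)
        g = 2.0 * (Aa - b)
        if lambda_lasso > 0.0:
            sm = np.sqrt(a * a + _L1_EPS * _L1_EPS)
            f += lambda_lasso * float(sm.sum())
            g = g + lambda_lasso * a / sm
        if penalty is not None:
            f += penalty.value(a)
            g = g + penalty.grad(a)
        return f, Z.T @ g

    beta0 = Z.T @ (alpha - alpha0)
    res = minimize(
        fg,
        beta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": lbfgs_maxiter, "ftol": 1e-16, "gtol": 1e-12},
    )
    return alpha0 + Z @ res.x


def _coeffs_from_flat(
    alpha: np.ndarray, d: int, v0: float, variant: str, meta: dict
) -> ExplanationCoefficients:
    main = alpha[:d].copy()
    pair = np.zeros((d, d))
    col = d
    for i, j in combinations(range(d), 2):
        pair[i, j] = pair[j, i] = alpha[col]
        col += 1
    return ExplanationCoefficients(main=main, pair=pair, intercept=v0, variant=variant, meta=meta)


def fit_weighted_lasso(
    design: DesignMatrix,
    y: np.ndarray,
    w: np.ndarray,
    v0: float,
    vN: float,
    lambda_lasso: float = 0.0,
) -> ExplanationCoefficients:
    """Anchored Shapley-kernel weighted (optionally L1-penalized) regression."""
    if lambda_lasso < 0:
        raise ValueError("lambda_lasso must be >= 0")
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.shape[0] != design.X.shape[0] or w.shape[0] != design.X.shape[0]:
        raise ValueError("design, y and w must have the same number of rows")
    Xw = design.X * w[:, None]
    A = design.X.T @ Xw
    b = design.X.T @ (w * (y - v0))
    alpha = solve_anchored(A, b, vN - v0, lambda_lasso=lambda_lasso)
    return _coeffs_from_flat(
        alpha,
        design.d,
        v0,
        "sundararajan",
        {"method": "kernel", "lambda_lasso": lambda_lasso},
    )


def default_lambda_lasso(y: np.ndarray, scheme: str) -> float:
    """0 for exhaustive designs; 1e-3 * median|y - mean(y)| for sampled ones."""
    if scheme == "exhaustive":
        return 0.0
    y = np.asarray(y, dtype=float)
    return float(1e-3 * np.median(np.abs(y - y.mean())))


def explain_kernel(
    f: ValueFunction,
    x: PatientState,
    M: int = 2048,
    lambda_lasso: Optional[float] = None,
    seed: int = 0,
    scheme: str = "kernel_prop",
    constraints=None,
    exhaustive_cap: int = 14,
) -> ExplanationCoefficients:
    """Full kernel pipeline: sample -> evaluate model -> weight -> fit.

    When a :class:`~stiidil.constraints.ConstraintSet` is given, the fit is
    delegated to the constrained solver so the clinical penalties enter the
    same objective.  Deterministic given ``seed``.
    """
    d = x.d
    samples = sample_coalitions(d, M, seed=seed, scheme=scheme, exhaustive_cap=exhaustive_cap)
    for s in samples:
        s.y = coalition_value(f, x, Coalition(np.flatnonzero(s.mask)))
    v0 = coalition_value(f, x, Coalition())
    vN = coalition_value(f, x, Coalition(range(d)))

    masks = np.array([s.mask for s in samples])
    y = np.array([s.y for s in samples])
    w = np.array([s.weight for s in samples])
    design = build_design(masks, d)
    if lambda_lasso is None:
        lambda_lasso = default_lambda_lasso(y, scheme)

    meta = {
        "method": "kernel",
        "M": M,
        "seed": seed,
        "scheme": scheme,
        "lambda_lasso": lambda_lasso,
        "n_unique_masks": len(samples),
    }
    if constraints is None:
        coeffs = fit_weighted_lasso(design, y, w, v0, vN, lambda_lasso=lambda_lasso)
    else:
        from .constraints import fit_constrained

        coeffs = fit_constrained(design, y, w, v0, vN, lambda_lasso, constraints)
        meta["constraint_lambdas"] = [spec.strength for spec in constraints.specs]
    coeffs.meta.update(meta)
    return coeffs


def fit_random_forest_surrogate(
    design: DesignMatrix,
    y: np.ndarray,
    w: np.ndarray,
    seed: int = 0,
    n_estimators: int = 200,
) -> np.ndarray:
    """Random-forest substitution for the regression stage.

    Fits a forest of coalition masks -> coalition values and returns the
    impurity-based importance of every design column (mains then pairs).
    Importances are unsigned; this variant supports robustness comparisons
    only, not signed explanations.
    """
    from sklearn.ensemble import RandomForestRegressor

    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    forest.fit(design.X, np.asarray(y, dtype=float), sample_weight=np.asarray(w, dtype=float))
    return forest.feature_importances_
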