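"""Clinical-knowledge constraints folded into the attribution objective.

Clinician-vetted rules are compiled into penalty terms ``lambda_k * g_k(alpha)``
added to the kernel-weighted regression objective, narrowing the explanation
space to solutions consistent with medical practice.  Five rule families are
provided, mirroring the constraint categories a hospital expert panel
typically encodes for insulin titration:

* **BG change** — a blood-glucose record that rose (fell) versus the same
  slot the previous day must not contribute negatively (positively) to the
  predicted dose.
* **Antidiabetic medications** — a newly added oral glucose-lowering drug
  must not push the insulin dose up; a stopped one must not pull it down.
* **Missing content** — imputed (missing) records must not carry
  attribution mass.
* **Prescribed BG** — the BG records inside the explained insulin's action
  window should retain a minimum share of the attribution mass.
* **BG-insulin interaction** — when a dose reduction is followed by a BG
  rise (or a dose increase by a BG fall), the (insulin, BG) interaction
  term must not be negative.

Penalty shapes: sign rules use a squared hinge ``max(0, -s a)^2``; suppression
uses ``a^2``; group emphasis uses ``max(0, tau - sum |a|)^2`` with ``tau`` a
configured share of |v(N) - v(0)|.  Sign and suppression penalties are convex;
group emphasis is convex on each sign orthant and is solved from the
unconstrained warm start.  A squared hinge drives violations to O(1/lambda)
rather than exactly zero, so after convergence residual violations below a
snap tolerance are clamped to the feasible boundary and the efficiency anchor
is re-imposed on unconstrained coordinates.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import FeatureKind, FeatureSpace, PatientState, Regimen, Slot
from .exact import ExplanationCoefficients
from .kernel import DesignMatrix, pair_column_index, solve_anchored, _coeffs_from_flat

__all__ = [
    "ConstraintKind",
    "ConstraintSpec",
    "ConstraintSet",
    "CompiledPenalty",
    "compile_penalty",
    "fit_constrained",
    "bg_change_rule",
    "antidiabetic_med_rule",
    "missing_content_rule",
    "prescribed_bg_rule",
    "bg_insulin_interaction_rule",
    "build_constraints",
    "violation_report",
    "ACTION_WINDOW",
    "INJECTION_SLOT",
    "DEFAULT_CONFIG",
]


class ConstraintKind(str, enum.Enum):
    SIGN_MAIN = "sign_main"
    SIGN_PAIR = "sign_pair"
    SUPPRESS_MAIN = "suppress_main"
    SUPPRESS_PAIR = "suppress_pair"
    EMPHASIZE_GROUP = "emphasize_group"


Target = Union[int, tuple[int, int], tuple[int, ...]]


@dataclass(frozen=True)
class ConstraintSpec:
    """One compiled clinical rule: a penalty target with strength lambda_k."""

    kind: ConstraintKind
    target: Target
    expected_sign: Optional[int] = None
    strength: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind in (ConstraintKind.SIGN_MAIN, ConstraintKind.SIGN_PAIR):
            if self.expected_sign not in (-1, 1):
                raise ValueError(f"{self.kind.value} requires expected_sign in {{-1,+1}}")
        elif self.expected_sign is not None:
            raise ValueError(f"{self.kind.value} must not carry expected_sign")
        if not (np.isfinite(self.strength) and self.strength >= 0):
            raise ValueError("strength must be finite and >= 0")


@dataclass
class ConstraintSet:
    """Compiled constraints for one explanation instance."""

    specs: list[ConstraintSpec]
    generated_from: str = ""
    tau_share: float = 0.25  # emphasize target share of |v(N) - v(0)|

    def validate(self, d: int) -> None:
        for spec in self.specs:
            tgt = spec.target
            if spec.kind in (ConstraintKind.SIGN_MAIN, ConstraintKind.SUPPRESS_MAIN):
                if not (isinstance(tgt, (int, np.integer)) and 0 <= tgt < d):
                    raise ValueError(f"invalid main target {tgt!r} for d={d}")
            elif spec.kind in (ConstraintKind.SIGN_PAIR, ConstraintKind.SUPPRESS_PAIR):
                i, j = tgt  # type: ignore[misc]
                if not (0 <= i < d and 0 <= j < d and i != j):
                    raise ValueError(f"invalid pair target {tgt!r} for d={d}")
            else:
                for i in tgt:  # type: ignore[union-attr]
                    if not 0 <= i < d:
                        raise ValueError(f"invalid group member {i} for d={d}")


def _target_column(spec: ConstraintSpec, d: int) -> int:
    if spec.kind in (ConstraintKind.SIGN_MAIN, ConstraintKind.SUPPRESS_MAIN):
        return int(spec.target)  # type: ignore[arg-type]
    i, j = sorted(spec.target)  # type: ignore[arg-type]
    return pair_column_index(d, i, j)


_ABS_EPS = 1e-9  # smoothing for |a| inside the group-emphasis penalty


class CompiledPenalty:
    """alpha -> sum_k lambda_k g_k(alpha), with gradient and solver hooks."""

    def __init__(
        self,
        d: int,
        sign_terms: list[tuple[int, int, float]],  # (col, expected_sign, lam)
        suppress_terms: list[tuple[int, float]],  # (col, lam)
        group_terms: list[tuple[np.ndarray, float, float]],  # (cols, tau_abs, lam)
    ) -> None:
        self.d = d
        self.sign_terms = sign_terms
        self.suppress_terms = suppress_terms
        self.group_terms = group_terms

    @property
    def is_quadratic(self) -> bool:
        return not self.group_terms

    def value(self, a: np.ndarray) -> float:
        total = 0.0
        for col, s, lam in self.sign_terms:
            h = max(0.0, -s * a[col])
            total += lam * h * h
        for col, lam in self.suppress_terms:
            total += lam * a[col] * a[col]
        for cols, tau, lam in self.group_terms:
            mass = float(np.sqrt(a[cols] ** 2 + _ABS_EPS**2).sum())
            g = max(0.0, tau - mass)
            total += lam * g * g
        return total

    def grad(self, a: np.ndarray) -> np.ndarray:
        g = np.zeros_like(a)
        for col, s, lam in self.sign_terms:
            h = max(0.0, -s * a[col])
            if h > 0.0:
                g[col] += -2.0 * lam * s * h
        for col, lam in self.suppress_terms:
            g[col] += 2.0 * lam * a[col]
        for cols, tau, lam in self.group_terms:
            sm = np.sqrt(a[cols] ** 2 + _ABS_EPS**2)
            gap = max(0.0, tau - float(sm.sum()))
            if gap > 0.0:
                g[cols] += -2.0 * lam * gap * (a[cols] / sm)
        return g

    def quadratic_terms(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Active quadratic pieces for the Newton warm start.

        Returns (diag_add, lin_add): the objective restricted to active
        sign hinges and suppressions equals a'(A+diag(diag_add))a - 2(b+lin_add)'a
        up to constants; group emphasis is left to the polish phase.
        """
        diag = np.zeros_like(a)
        lin = np.zeros_like(a)
        for col, s, lam in self.sign_terms:
            if -s * a[col] > 0.0:
                diag[col] += lam
        for col, lam in self.suppress_terms:
            diag[col] += lam
        return diag, lin

    def constrained_columns(self) -> set[int]:
        cols = {c for c, _, _ in self.sign_terms}
        cols |= {c for c, _ in self.suppress_terms}
        return cols

    def snap(self, a: np.ndarray, tol: float = 1e-3) -> np.ndarray:
        """Clamp O(1/lambda) residual violations to the feasible boundary.

        Sign-constrained coefficients that ended wrong-signed by less than
        ``tol`` are set to 0, as are suppressed coefficients below ``tol``;
        the anchor deficit this creates is redistributed over columns not
        under any sign/suppression constraint.
        """
        a = a.copy()
        snapped = np.zeros(a.shape[0], dtype=bool)
        for col, s, lam in self.sign_terms:
            if lam > 0 and -s * a[col] > 0 and abs(a[col]) <= tol:
                a[col] = 0.0
                snapped[col] = True
        for col, lam in self.suppress_terms:
            if lam > 0 and abs(a[col]) <= tol:
                a[col] = 0.0
                snapped[col] = True
        return a, snapped


def compile_penalty(cs: ConstraintSet, d: int, delta_v: float) -> CompiledPenalty:
    """Compile a ConstraintSet into a differentiable penalty over the flat
    coefficient vector (d mains then upper-triangular pairs)."""
    cs.validate(d)
    sign_terms: list[tuple[int, int, float]] = []
    suppress_terms: list[tuple[int, float]] = []
    group_terms: list[tuple[np.ndarray, float, float]] = []
    for spec in cs.specs:
        if spec.kind in (ConstraintKind.SIGN_MAIN, ConstraintKind.SIGN_PAIR):
            sign_terms.append((_target_column(spec, d), int(spec.expected_sign), spec.strength))
        elif spec.kind in (ConstraintKind.SUPPRESS_MAIN, ConstraintKind.SUPPRESS_PAIR):
            suppress_terms.append((_target_column(spec, d), spec.strength))
        elif spec.kind is ConstraintKind.EMPHASIZE_GROUP:
            cols = np.array([int(i) for i in spec.target], dtype=int)
            tau_abs = cs.tau_share * abs(delta_v)
            group_terms.append((cols, tau_abs, spec.strength))
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown constraint kind {spec.kind!r}")
    return CompiledPenalty(d, sign_terms, suppress_terms, group_terms)


def fit_constrained(
    design: DesignMatrix,
    y: np.ndarray,
    w: np.ndarray,
    v0: float,
    vN: float,
    lambda_lasso: float,
    constraints: ConstraintSet,
    snap_tol: float = 1e-3,
) -> ExplanationCoefficients:
    """Anchored weighted LASSO with the compiled clinical penalty added.

    With an empty or zero-strength ConstraintSet this reduces exactly to
    :func:`stiidil.kernel.fit_weighted_lasso`.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    delta_v = vN - v0
    penalty = compile_penalty(constraints, design.d, delta_v)
    Xw = design.X * w[:, None]
    A = design.X.T @ Xw
    b = design.X.T @ (w * (y - v0))
    alpha = solve_anchored(A, b, delta_v, lambda_lasso=lambda_lasso, penalty=penalty)
    alpha, snapped = penalty.snap(alpha, tol=snap_tol)
    deficit = delta_v - alpha.sum()
    if deficit != 0.0:
        free = np.ones(alpha.shape[0], dtype=bool)
        free[list(penalty.constrained_columns())] = False
        free &= ~snapped
        if not free.any():
            free = ~snapped
        if free.any():
            alpha[free] += deficit / free.sum()
    coeffs = _coeffs_from_flat(
        alpha,
        design.d,
        v0,
        "sundararajan",
        {"method": "kernel+dil", "lambda_lasso": lambda_lasso, "K": len(constraints.specs)},
    )
    return coeffs


# ---------------------------------------------------------------------------
# Rule families
# ---------------------------------------------------------------------------

#: BG slots most relevant to each regimen's insulin action window
#: (the "prescribed BG" records).  Editable via the constraint config.
ACTION_WINDOW: dict[Regimen, list[Slot]] = {
    Regimen.BEDTIME_LONG: [Slot.T0],  # next-morning fasting glucose
    Regimen.PREBREAKFAST_PREMIX: [Slot.T1, Slot.T2, Slot.T3],
    Regimen.PREDINNER_PREMIX: [Slot.T5, Slot.T6],
    Regimen.PREBREAKFAST_SHORT: [Slot.T1, Slot.T2],
    Regimen.PRELUNCH_SHORT: [Slot.T3, Slot.T4],
    Regimen.PREDINNER_SHORT: [Slot.T5, Slot.T6],
}

#: Injection slot for each regimen.
INJECTION_SLOT: dict[Regimen, Slot] = {
    Regimen.BEDTIME_LONG: Slot.T6,
    Regimen.PREBREAKFAST_PREMIX: Slot.T0,
    Regimen.PREDINNER_PREMIX: Slot.T4,
    Regimen.PREBREAKFAST_SHORT: Slot.T0,
    Regimen.PRELUNCH_SHORT: Slot.T2,
    Regimen.PREDINNER_SHORT: Slot.T4,
}


def _bg_at(fs: FeatureSpace, day: int, slot: Slot) -> Optional[int]:
    hits = fs.find(FeatureKind.BG_RECORD, day_offset=day, slot=slot)
    return hits[0].index if hits else None


def bg_change_rule(
    x: PatientState,
    strength: float,
    deadband: float = 0.5,
    window: Optional[dict[Regimen, list[Slot]]] = None,
) -> list[ConstraintSpec]:
    """Sign constraints tying BG day-over-day changes to dose direction.

    A relevant BG record (action-window slot of the patient's regimen) that
    rose more than ``deadband`` mmol/L versus the same slot the prior day
    must contribute non-negatively to the predicted dose; a fall must
    contribute non-positively.  Missing records are skipped.
    """
    fs = x.space
    slots = (window or ACTION_WINDOW)[x.regimen]
    specs: list[ConstraintSpec] = []
    for day in (0, -1):
        for slot in slots:
            cur = _bg_at(fs, day, slot)
            prev = _bg_at(fs, day - 1, slot)
            if cur is None or prev is None:
                continue
            if x.missing_mask[cur] or x.missing_mask[prev]:
                continue
            delta = x.values[cur] - x.values[prev]
            if delta > deadband:
                sign = 1
            elif delta < -deadband:
                sign = -1
            else:
                continue
            specs.append(
                ConstraintSpec(
                    kind=ConstraintKind.SIGN_MAIN,
                    target=cur,
                    expected_sign=sign,
                    strength=strength,
                    provenance=f"bg_change: {fs[cur].name} moved {delta:+.1f} mmol/L vs prior day",
                )
            )
    return specs


def antidiabetic_med_rule(x: PatientState, strength: float) -> list[ConstraintSpec]:
    """A newly added oral antidiabetic must not push the dose up (and a
    stopped one must not pull it down)."""
    fs = x.space
    flags = fs.by_kind(FeatureKind.MED_FLAG)
    by_med: dict[str, dict[int, int]] = {}
    for f in flags:
        base = f.name.rsplit(":", 1)[0]
        by_med.setdefault(base, {})[f.day_offset if f.day_offset is not None else 0] = f.index
    specs: list[ConstraintSpec] = []
    for base, days in by_med.items():
        if 0 not in days or -1 not in days:
            continue
        change = x.values[days[0]] - x.values[days[-1]]
        if change > 0.5:  # added
            sign = -1
        elif change < -0.5:  # stopped
            sign = 1
        else:
            continue
        specs.append(
            ConstraintSpec(
                kind=ConstraintKind.SIGN_MAIN,
                target=days[0],
                expected_sign=sign,
                strength=strength,
                provenance=f"antidiabetic_med: {base} {'added' if sign < 0 else 'stopped'}",
            )
        )
    return specs


def missing_content_rule(x: PatientState, strength: float) -> list[ConstraintSpec]:
    """Suppress attribution on missing records and every pair touching them.

    A missing measurement is represented by an imputed value (missing_mask
    true) plus a set missing-indicator flag; both carry the missing record's
    identity, so both are suppressed.
    """
    fs = x.space
    missing = list(np.flatnonzero(x.missing_mask))
    for f in fs.by_kind(FeatureKind.MISSING_INDICATOR):
        if x.values[f.index] != 0.0 and not x.missing_mask[f.index]:
            missing.append(f.index)
    specs: list[ConstraintSpec] = []
    for i in missing:
        specs.append(
            ConstraintSpec(
                kind=ConstraintKind.SUPPRESS_MAIN,
                target=int(i),
                strength=strength,
                provenance=f"missing_content: {x.space[int(i)].name}",
            )
        )
    miss_set = set(int(i) for i in missing)
    for i in sorted(miss_set):
        for j in range(x.d):
            if j == i or (j in miss_set and j < i):
                continue
            specs.append(
                ConstraintSpec(
                    kind=ConstraintKind.SUPPRESS_PAIR,
                    target=(min(i, j), max(i, j)),
                    strength=strength,
                    provenance=f"missing_content: pair touches {x.space[i].name}",
                )
            )
    return specs


def prescribed_bg_rule(
    x: PatientState,
    strength: float,
    window: Optional[dict[Regimen, list[Slot]]] = None,
) -> list[ConstraintSpec]:
    """Emphasize the prescribed-BG group (action-window records)."""
    fs = x.space
    slots = set((window or ACTION_WINDOW)[x.regimen])
    group = [
        f.index
        for f in fs
        if f.is_prescribed_bg and f.slot in slots and not x.missing_mask[f.index]
    ]
    if not group:
        warnings.warn(
            f"prescribed_bg_rule: no prescribed BG features for regimen {x.regimen.value}",
            stacklevel=2,
        )
        return []
    return [
        ConstraintSpec(
            kind=ConstraintKind.EMPHASIZE_GROUP,
            target=tuple(group),
            strength=strength,
            provenance=f"prescribed_bg: action window {[s.value for s in sorted(slots, key=str)]}",
        )
    ]


def bg_insulin_interaction_rule(
    x: PatientState,
    strength: float,
    dose_deadband: float = 0.5,
    bg_deadband: float = 0.5,
    window: Optional[dict[Regimen, list[Slot]]] = None,
) -> list[ConstraintSpec]:
    """Dose-change / BG-response interactions must not be scored negative.

    When the prior dose was reduced and the subsequent action-window BG
    rose (or the dose was raised and the BG fell), the (insulin, BG) pair
    term carries negative-feedback evidence and must be non-negative.
    """
    fs = x.space
    slots = (window or ACTION_WINDOW)[x.regimen]
    ins = [
        f
        for f in fs.by_kind(FeatureKind.INSULIN_RECORD)
        if f.regimen_link is x.regimen or f.regimen_link is None
    ]
    by_day = {f.day_offset: f.index for f in ins}
    specs: list[ConstraintSpec] = []
    for day in (0, -1):
        if day not in by_day or (day - 1) not in by_day:
            continue
        d_dose = x.values[by_day[day]] - x.values[by_day[day - 1]]
        for slot in slots:
            cur = _bg_at(fs, day, slot)
            prev = _bg_at(fs, day - 1, slot)
            if cur is None or prev is None:
                continue
            if x.missing_mask[cur] or x.missing_mask[prev]:
                continue
            d_bg = x.values[cur] - x.values[prev]
            reduced_and_rose = d_dose <= -dose_deadband and d_bg >= bg_deadband
            raised_and_fell = d_dose >= dose_deadband and d_bg <= -bg_deadband
            if not (reduced_and_rose or raised_and_fell):
                continue
            i, j = sorted((by_day[day], cur))
            specs.append(
                ConstraintSpec(
                    kind=ConstraintKind.SIGN_PAIR,
                    target=(i, j),
                    expected_sign=1,
                    strength=strength,
                    provenance=(
                        f"bg_insulin_interaction: dose {d_dose:+.1f} U with "
                        f"{fs[cur].name} {d_bg:+.1f} mmol/L"
                    ),
                )
            )
    return specs


DEFAULT_CONFIG: dict = {
    "families": {
        "bg_change": {"enabled": True, "strength": None},  # None -> 10 * lasso scale
        "antidiabetic_med": {"enabled": True, "strength": None},
        "missing_content": {"enabled": True, "strength": None},  # None -> 100 * scale
        "prescribed_bg": {"enabled": True, "strength": None},
        "bg_insulin_interaction": {"enabled": True, "strength": None},
    },
    "bg_deadband": 0.5,  # mmol/L
    "dose_deadband": 0.5,  # U
    "tau_share": 0.25,
    "action_window": None,  # optional {regimen: [slots]} override
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)
_KNOWN_FAMILIES = set(DEFAULT_CONFIG["families"])


def build_constraints(
    x: PatientState,
    config: Optional[dict] = None,
    base_strength: float = 1.0,
) -> ConstraintSet:
    """Apply the enabled rule families to one patient instance.

    Family strengths default to 10x ``base_strength`` for sign rules and
    100x for missing-content suppression (suppression must dominate).
    """
    cfg = dict(DEFAULT_CONFIG)
    fam_cfg = {k: dict(v) for k, v in DEFAULT_CONFIG["families"].items()}
    if config:
        unknown = set(config) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown constraint-config keys: {sorted(unknown)}")
        for k, v in config.items():
            if k == "families":
                bad = set(v) - _KNOWN_FAMILIES
                if bad:
                    raise ValueError(f"unknown constraint families: {sorted(bad)}")
                for name, fv in v.items():
                    fam_cfg[name].update(fv)
            else:
                cfg[k] = v
    window = None
    if cfg.get("action_window"):
        window = {
            Regimen(k): [Slot(s) for s in v] for k, v in cfg["action_window"].items()
        }

    def lam(name: str, mult: float) -> float:
        s = fam_cfg[name].get("strength")
        return float(s) if s is not None else mult * base_strength

    specs: list[ConstraintSpec] = []
    if fam_cfg["bg_change"]["enabled"]:
        specs += bg_change_rule(x, lam("bg_change", 10.0), cfg["bg_deadband"], window)
    if fam_cfg["antidiabetic_med"]["enabled"]:
        specs += antidiabetic_med_rule(x, lam("antidiabetic_med", 10.0))
    if fam_cfg["missing_content"]["enabled"]:
        specs += missing_content_rule(x, lam("missing_content", 100.0))
    if fam_cfg["prescribed_bg"]["enabled"]:
        specs += prescribed_bg_rule(x, lam("prescribed_bg", 10.0), window)
    if fam_cfg["bg_insulin_interaction"]["enabled"]:
        specs += bg_insulin_interaction_rule(
            x,
            lam("bg_insulin_interaction", 10.0),
            cfg["dose_deadband"],
            cfg["bg_deadband"],
            window,
        )
    return ConstraintSet(specs=specs, generated_from=x.patient_id, tau_share=cfg["tau_share"])


def violation_report(
    coeffs: ExplanationCoefficients, cs: ConstraintSet, tol: float = 1e-6
) -> dict:
    """Count and total wrong-signed mass over the set's sign constraints."""
    count = 0
    mass = 0.0
    for spec in cs.specs:
        if spec.kind is ConstraintKind.SIGN_MAIN:
            val = coeffs.main[int(spec.target)]  # type: ignore[arg-type]
        elif spec.kind is ConstraintKind.SIGN_PAIR:
            i, j = spec.target  # type: ignore[misc]
            val = coeffs.pair[i, j]
        else:
            continue
        wrong = -spec.expected_sign * val
        if wrong > tol:
            count += 1
            mass += float(wrong)
    return {"count": count, "mass": mass}
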