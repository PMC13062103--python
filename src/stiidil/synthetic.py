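"""Synthetic inpatient-diabetes cohorts with known attribution ground truth.

Real titration cohorts are proprietary, so every component of this package
is exercised on generated records that share the clinical data shape: a
3-day x 7-slot blood-glucose grid (T0 pre-breakfast ... T6 before bedtime,
days -2/-1/0), per-day insulin injection history for the explained regimen,
oral antidiabetic medication flags, demographics, and optional missing
records encoded as an imputed value plus a paired missing-indicator flag.

Blood glucose follows an AR(1) process within each day with post-meal
bumps; this reproduces the tabular structure and plausible marginals
(BG in mmol/L, doses in U) but makes no claim of physiological fidelity.

The stand-in for the deployed deep-learning titration network is a
*surrogate* model with known additive + pairwise structure, for which the
order-2 Shapley-Taylor attribution has a closed form — the ground truth
that estimator tests recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .constraints import ACTION_WINDOW, INJECTION_SLOT
from .core import (
    FeatureKind,
    FeatureMeta,
    FeatureSpace,
    PatientState,
    Regimen,
    Slot,
    Units,
    ValueFunction,
)
from .exact import ExplanationCoefficients

__all__ = [
    "CohortConfig",
    "GroundTruthModel",
    "build_feature_space",
    "cohort_baseline",
    "simulate_cohort",
    "ground_truth_stii",
    "centered_pairwise_model",
    "random_pairwise_model",
    "make_clinical_surrogate",
    "make_adversarial_surrogate",
    "make_fig3f_case",
    "restrict_patient",
    "restrict_model",
]

ALL_SLOTS = tuple(s.value for s in Slot)

# cohort-level reference (baseline) values, also used for imputation
_DEMOGRAPHICS = (  # name, mean, sd, clip, units
    ("age", 58.5, 14.3, (18.0, 95.0), Units.YEARS),
    ("weight", 70.0, 15.0, (35.0, 150.0), Units.KG),
    ("hba1c", 9.3, 2.2, (4.5, 18.0), Units.DIMENSIONLESS),
)
_POSTMEAL_BUMP = {Slot.T1: 1.8, Slot.T3: 1.6, Slot.T5: 1.4}


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_patients: int = 50
    regimen: Regimen = Regimen.PRELUNCH_SHORT
    days: tuple[int, ...] = (-2, -1, 0)
    slots: tuple[str, ...] = ALL_SLOTS
    n_insulin_days: int = 3
    n_med: int = 1
    n_demo: int = 3
    bg_mean: float = 10.0  # mmol/L
    bg_sd: float = 2.5  # mmol/L (between/within-patient combined scale)
    insulin_dose_range: tuple[float, float] = (2.0, 20.0)  # U
    missing_rate: float = 0.0
    baseline_scheme: str = "cohort_mean"  # or "carry_forward"
    seed: int = 0

    def __post_init__(self) -> None:
        self.regimen = Regimen(self.regimen)
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be a probability in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.bg_sd <= 0 or self.bg_mean <= 0:
            raise ValueError("bg_mean and bg_sd must be positive")
        lo, hi = self.insulin_dose_range
        if not 0 <= lo < hi:
            raise ValueError("insulin_dose_range must satisfy 0 <= lo < hi")
        if not 0 <= self.n_demo <= len(_DEMOGRAPHICS):
            raise ValueError(f"n_demo must be in 0..{len(_DEMOGRAPHICS)}")
        if self.n_insulin_days > len(self.days):
            raise ValueError("n_insulin_days cannot exceed the number of days")
        bad = [s for s in self.slots if s not in ALL_SLOTS]
        if bad:
            raise ValueError(f"unknown slots {bad}")
        if self.baseline_scheme not in ("cohort_mean", "carry_forward"):
            raise ValueError("baseline_scheme must be 'cohort_mean' or 'carry_forward'")


def build_feature_space(cfg: CohortConfig) -> FeatureSpace:
    """Feature universe for a cohort config; ordering is BG grid, insulin
    history, med flags, demographics, then missing indicators (if any)."""
    feats: list[FeatureMeta] = []
    window = set(ACTION_WINDOW[cfg.regimen])

    def add(**kw) -> None:
        feats.append(FeatureMeta(index=len(feats), **kw))

    for day in cfg.days:
        for s in cfg.slots:
            slot = Slot(s)
            add(
                name=f"bg:{slot.value}:{day}d",
                kind=FeatureKind.BG_RECORD,
                day_offset=day,
                slot=slot,
                units=Units.MMOL_PER_L,
                is_prescribed_bg=slot in window,
            )
    inj = INJECTION_SLOT[cfg.regimen]
    for day in cfg.days[-cfg.n_insulin_days :] if cfg.n_insulin_days else []:
        add(
            name=f"ins:{inj.value}:{day}d",
            kind=FeatureKind.INSULIN_RECORD,
            day_offset=day,
            slot=inj,
            units=Units.INSULIN_U,
            regimen_link=cfg.regimen,
        )
    for m in range(cfg.n_med):
        for day in (-1, 0):
            add(
                name=f"med:oad{m}:{day}d",
                kind=FeatureKind.MED_FLAG,
                day_offset=day,
                units=Units.DIMENSIONLESS,
            )
    for name, _, _, _, units in _DEMOGRAPHICS[: cfg.n_demo]:
        add(name=f"demo:{name}", kind=FeatureKind.DEMOGRAPHIC, units=units)
    if cfg.missing_rate > 0:
        for day in cfg.days:
            for s in cfg.slots:
                slot = Slot(s)
                add(
                    name=f"miss:bg:{slot.value}:{day}d",
                    kind=FeatureKind.MISSING_INDICATOR,
                    day_offset=day,
                    slot=slot,
                )
    return FeatureSpace(feats)


def _baseline_vector(cfg: CohortConfig, fs: FeatureSpace) -> np.ndarray:
    base = np.zeros(fs.d)
    mid_dose = 0.5 * sum(cfg.insulin_dose_range)
    demo_means = {f"demo:{n}": mu for n, mu, _, _, _ in _DEMOGRAPHICS}
    for f in fs:
        if f.kind is FeatureKind.BG_RECORD:
            base[f.index] = cfg.bg_mean
        elif f.kind is FeatureKind.INSULIN_RECORD:
            base[f.index] = mid_dose
        elif f.kind is FeatureKind.DEMOGRAPHIC:
            base[f.index] = demo_means[f.name]
        # med flags and missing indicators: baseline 0 (absent / observed)
    return base


def cohort_baseline(cfg: CohortConfig, fs: Optional[FeatureSpace] = None) -> np.ndarray:
    """Cohort-level reference vector (means for continuous features, 0 for flags)."""
    return _baseline_vector(cfg, fs if fs is not None else build_feature_space(cfg))


def simulate_cohort(cfg: CohortConfig) -> list[PatientState]:
    """Generate ``cfg.n_patients`` patient states; deterministic per seed."""
    fs = build_feature_space(cfg)
    rng = np.random.default_rng(cfg.seed)
    baseline = _baseline_vector(cfg, fs)
    phi = 0.6  # within-day AR(1) persistence
    innov_sd = cfg.bg_sd * np.sqrt(1 - phi**2)
    lo, hi = cfg.insulin_dose_range
    patients: list[PatientState] = []
    for k in range(cfg.n_patients):
        values = baseline.copy()
        mask = np.zeros(fs.d, dtype=bool)
        mu_p = cfg.bg_mean + rng.normal(0.0, 0.3 * cfg.bg_sd)
        for day in cfg.days:
            prev = mu_p + rng.normal(0.0, cfg.bg_sd)
            for s in cfg.slots:
                slot = Slot(s)
                bump = _POSTMEAL_BUMP.get(slot, 0.0)
                val = mu_p + phi * (prev - mu_p) + bump + rng.normal(0.0, innov_sd)
                prev = val - bump
                hits = fs.find(FeatureKind.BG_RECORD, day_offset=day, slot=slot)
                values[hits[0].index] = float(np.clip(val, 2.0, 30.0))
        dose = round(2.0 * rng.uniform(lo, hi)) / 2.0
        for f in fs.by_kind(FeatureKind.INSULIN_RECORD):
            step = round(2.0 * rng.normal(0.0, 1.5)) / 2.0
            dose = float(np.clip(dose + step, lo, hi))
            values[f.index] = dose
        for f in fs.by_kind(FeatureKind.MED_FLAG):
            if f.day_offset == -1:
                values[f.index] = float(rng.random() < 0.4)
            else:
                prev_idx = fs.index_of(f.name.replace(":0d", ":-1d"))
                flip = rng.random() < 0.15
                values[f.index] = float(bool(values[prev_idx]) ^ flip)
        for (name, mu, sd, clip, _), f in zip(
            _DEMOGRAPHICS, fs.by_kind(FeatureKind.DEMOGRAPHIC)
        ):
            values[f.index] = float(np.clip(rng.normal(mu, sd), *clip))
        if cfg.missing_rate > 0:
            for f in fs.by_kind(FeatureKind.BG_RECORD):
                if rng.random() < cfg.missing_rate:
                    values[f.index] = cfg.bg_mean  # mean imputation
                    mask[f.index] = True
                    ind = fs.find(
                        FeatureKind.MISSING_INDICATOR, day_offset=f.day_offset, slot=f.slot
                    )
                    values[ind[0].index] = 1.0
        base_dose = values[fs.by_kind(FeatureKind.INSULIN_RECORD)[-1].index] if cfg.n_insulin_days else 0.0
        pbase = baseline.copy()
        if cfg.baseline_scheme == "carry_forward":
            # reference for a recent BG record = the same slot the day before,
            # so its attribution tracks the day-over-day change directly
            for f in fs.by_kind(FeatureKind.BG_RECORD):
                if f.day_offset in (-1, 0):
                    prev = fs.find(FeatureKind.BG_RECORD, day_offset=f.day_offset - 1, slot=f.slot)
                    if prev:
                        pbase[f.index] = values[prev[0].index]
        patients.append(
            PatientState(
                space=fs,
                values=values,
                missing_mask=mask,
                baseline=pbase,
                regimen=cfg.regimen,
                base_dose=float(base_dose),
                patient_id=f"p{k:04d}",
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Ground-truth surrogate models
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthModel:
    """Additive + pairwise surrogate: f(z) = c + w.z + sum_{i<j} W_ij z_i z_j.

    ``form='rule_based'`` allows an extra nonlinear term via ``rule``; such
    models have no closed-form attribution and must go through the exact
    enumerator instead of :func:`ground_truth_stii`.
    """

    main_weights: np.ndarray
    pair_weights: np.ndarray
    intercept: float = 0.0
    noise_sd: float = 0.0
    form: str = "linear_pairwise"
    rule: Optional[Callable[[np.ndarray], float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.main_weights = np.asarray(self.main_weights, dtype=float)
        self.pair_weights = np.asarray(self.pair_weights, dtype=float)
        d = self.main_weights.shape[0]
        if self.pair_weights.shape != (d, d):
            raise ValueError("pair_weights must be (d, d)")
        if not np.allclose(self.pair_weights, self.pair_weights.T):
            raise ValueError("pair_weights must be symmetric")
        if np.any(np.diag(self.pair_weights) != 0.0):
            raise ValueError("pair_weights must have zero diagonal")
        if self.form not in ("linear_pairwise", "rule_based"):
            raise ValueError("form must be 'linear_pairwise' or 'rule_based'")
        if self.form == "rule_based" and self.rule is None:
            raise ValueError("rule_based form requires a rule callable")
        self._noise_rng = np.random.default_rng(self.seed)

    @property
    def d(self) -> int:
        return int(self.main_weights.shape[0])

    def predict(self, z: np.ndarray) -> float:
        z = np.asarray(z, dtype=float)
        val = self.intercept + float(self.main_weights @ z)
        val += 0.5 * float(z @ self.pair_weights @ z)
        if self.rule is not None:
            val += float(self.rule(z))
        if self.noise_sd > 0:
            val += float(self._noise_rng.normal(0.0, self.noise_sd))
        return val

    def gradient(self, z: np.ndarray) -> np.ndarray:
        if self.rule is not None:
            raise ValueError("rule_based surrogates have no analytic gradient")
        return self.main_weights + self.pair_weights @ np.asarray(z, dtype=float)

    def to_value_function(self) -> ValueFunction:
        grad = None if (self.rule is not None or self.noise_sd > 0) else self.gradient
        return ValueFunction(predict=self.predict, gradient=grad, name="surrogate")

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "main_weights": self.main_weights.tolist(),
            "pair_weights": self.pair_weights.tolist(),
        }

    @classmethod
    def from_dict(cls, dd: dict) -> "GroundTruthModel":
        return cls(
            main_weights=np.array(dd["main_weights"], dtype=float),
            pair_weights=np.array(dd["pair_weights"], dtype=float),
            intercept=float(dd.get("intercept", 0.0)),
            noise_sd=float(dd.get("noise_sd", 0.0)),
            form=dd.get("form", "linear_pairwise"),
        )


def ground_truth_stii(
    model: GroundTruthModel, x: PatientState, variant: str = "sundararajan"
) -> ExplanationCoefficients:
    """Closed-form order-2 attribution of a zero-noise pairwise surrogate.

    With delta = x - baseline and effective main weight
    w~_i = w_i + sum_j W_ij baseline_j, the coalition game is the degree-2
    multilinear polynomial sum w~_i delta_i 1_i + sum W_ij delta_i delta_j 1_i 1_j,
    so pair[i,j] = W_ij delta_i delta_j for either variant; mains are
    w~_i delta_i (lowest-order derivative) or, under ``shapley_interaction``,
    w~_i delta_i + 0.5 sum_j W_ij delta_i delta_j.
    """
    if model.form != "linear_pairwise" or model.rule is not None:
        raise ValueError("closed form requires a linear_pairwise surrogate; use explain_exact")
    if model.noise_sd != 0.0:
        raise ValueError("closed form requires zero noise")
    delta = x.values - x.baseline
    w_eff = model.main_weights + model.pair_weights @ x.baseline
    pair = model.pair_weights * np.outer(delta, delta)
    np.fill_diagonal(pair, 0.0)
    main = w_eff * delta
    if variant == "shapley_interaction":
        main = main + 0.5 * pair.sum(axis=1)
    elif variant != "sundararajan":
        raise ValueError(f"unknown variant {variant!r}")
    return ExplanationCoefficients(
        main=main,
        pair=pair,
        intercept=model.predict(x.baseline),
        variant=variant,
        meta={"method": "ground_truth"},
    )


def centered_pairwise_model(
    main_weights: np.ndarray,
    pair_weights: np.ndarray,
    reference: np.ndarray,
    intercept: float = 0.0,
) -> GroundTruthModel:
    """Surrogate specified around a reference input r:

        f(z) = c + sum w_i (z_i - r_i) + sum_{i<j} W_ij (z_i - r_i)(z_j - r_j)

    expanded to raw polynomial coefficients, so that for a patient whose
    baseline equals ``reference`` the closed-form attribution is exactly
    main = w delta and pair = W delta delta'.
    """
    w = np.asarray(main_weights, dtype=float)
    W = np.asarray(pair_weights, dtype=float)
    r = np.asarray(reference, dtype=float)
    w_raw = w - W @ r
    c_raw = intercept - float(w @ r) + 0.5 * float(r @ W @ r)
    return GroundTruthModel(main_weights=w_raw, pair_weights=W.copy(), intercept=c_raw)


def random_pairwise_model(
    d: int, seed: int = 0, pair_density: float = 0.5, scale: float = 1.0
) -> GroundTruthModel:
    """Random degree-2 surrogate for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, scale, size=d)
    W = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            if rng.random() < pair_density:
                W[i, j] = W[j, i] = rng.normal(0.0, scale)
    return GroundTruthModel(main_weights=w, pair_weights=W, intercept=rng.normal())


def _structured_weights(fs: FeatureSpace, seed: int):
    rng = np.random.default_rng(seed)
    d = fs.d
    w = np.zeros(d)
    W = np.zeros((d, d))
    bg_pres, ins = [], []
    for f in fs:
        if f.kind is FeatureKind.BG_RECORD:
            if f.is_prescribed_bg:
                bg_pres.append(f.index)
            w[f.index] = (0.35 if f.is_prescribed_bg else 0.06) * (1 + 0.1 * rng.normal())
        elif f.kind is FeatureKind.INSULIN_RECORD:
            ins.append(f.index)
            w[f.index] = -0.20 * (1 + 0.1 * rng.normal())
        elif f.kind is FeatureKind.MED_FLAG:
            w[f.index] = -0.8 if f.day_offset == 0 else -0.2
        elif f.kind is FeatureKind.DEMOGRAPHIC:
            w[f.index] = 0.01 * rng.normal()
        # missing indicators get zero weight: an indicator itself is not dosed on
    for i in ins:
        for j in bg_pres:
            W[i, j] = W[j, i] = 0.04 * (1 + 0.2 * rng.normal())
    return w, W, rng


def make_clinical_surrogate(
    fs: FeatureSpace, seed: int = 0, reference: Optional[np.ndarray] = None
) -> GroundTruthModel:
    """Surrogate with clinically sensible structure: high BG pushes the dose
    up (prescribed records most), recent insulin and added oral agents pull
    it down, with negative-feedback (insulin, BG) interactions.

    Weights act on deviations from ``reference`` (default: the all-zero
    vector, i.e. raw polynomial coefficients), so with reference set to the
    cohort baseline the designed weights are exactly the effective
    attribution weights.
    """
    w, W, _ = _structured_weights(fs, seed)
    if reference is None:
        reference = np.zeros(fs.d)
    return centered_pairwise_model(w, W, reference)


def make_adversarial_surrogate(
    fs: FeatureSpace,
    seed: int = 0,
    wrong_frac: float = 0.5,
    missing_weight: float = 0.5,
    reference: Optional[np.ndarray] = None,
) -> GroundTruthModel:
    """Clinical surrogate corrupted with knowledge-inconsistent structure.

    A fraction of the BG main weights is flipped negative (a BG rise then
    *lowers* the explained dose) and missing-indicator features receive
    spurious weight, producing the wrong-quadrant and missing-content
    attribution patterns the constraint layer is designed to remove.
    """
    w, W, rng = _structured_weights(fs, seed)
    rng = np.random.default_rng(seed + 1)
    bg_idx = [f.index for f in fs if f.kind is FeatureKind.BG_RECORD]
    n_flip = max(1, int(round(wrong_frac * len(bg_idx))))
    flip = rng.choice(bg_idx, size=n_flip, replace=False)
    w[flip] = -np.abs(w[flip]) * 2.0
    for f in fs.by_kind(FeatureKind.MISSING_INDICATOR):
        w[f.index] = missing_weight
    if reference is None:
        reference = np.zeros(fs.d)
    return centered_pairwise_model(w, W, reference)


def restrict_patient(x: PatientState, keep: Sequence[int]) -> PatientState:
    """Project a patient onto a feature subset (indices re-based to 0..k-1)."""
    keep = list(keep)
    feats = [
        replace(x.space[i], index=pos)
        for pos, i in enumerate(keep)
    ]
    return PatientState(
        space=FeatureSpace(feats),
        values=x.values[keep].copy(),
        missing_mask=x.missing_mask[keep].copy(),
        baseline=x.baseline[keep].copy(),
        regimen=x.regimen,
        base_dose=x.base_dose,
        patient_id=x.patient_id,
    )


def restrict_model(
    model: GroundTruthModel, keep: Sequence[int], pinned_values: np.ndarray
) -> GroundTruthModel:
    """Surrogate over a feature subset with dropped features pinned.

    Pinned coordinates fold into the intercept and into effective main
    weights, so the restricted model agrees with the full model on any
    input whose dropped coordinates equal ``pinned_values``.
    """
    keep = np.asarray(list(keep), dtype=int)
    drop = np.setdiff1d(np.arange(model.d), keep)
    zb = np.asarray(pinned_values, dtype=float)
    inter = (
        model.intercept
        + float(model.main_weights[drop] @ zb[drop])
        + 0.5 * float(zb[drop] @ model.pair_weights[np.ix_(drop, drop)] @ zb[drop])
    )
    w = model.main_weights[keep] + model.pair_weights[np.ix_(keep, drop)] @ zb[drop]
    W = model.pair_weights[np.ix_(keep, keep)].copy()
    return GroundTruthModel(main_weights=w, pair_weights=W, intercept=inter)


def make_fig3f_case(adversarial_pair_weight: float = 0.1):
    """Worked pre-lunch short-acting case with a dose-cut / BG-rise history.

    The patient's pre-lunch insulin was reduced from 6 U (two days ago) to
    3 U (yesterday) while the post-lunch BG rose from 11.7 to 14.8 mmol/L.
    The surrogate carries a pairwise term that scores this (insulin, BG)
    interaction *negative* — the knowledge-inconsistent explanation the
    BG-insulin interaction constraint exists to correct.

    Returns (patient, surrogate).  Deterministic; no randomness.
    """
    regimen = Regimen.PRELUNCH_SHORT
    feats = [
        FeatureMeta(0, "ins:T2:-2d", FeatureKind.INSULIN_RECORD, -2, Slot.T2,
                    Units.INSULIN_U, regimen),
        FeatureMeta(1, "ins:T2:-1d", FeatureKind.INSULIN_RECORD, -1, Slot.T2,
                    Units.INSULIN_U, regimen),
        FeatureMeta(2, "ins:T2:0d", FeatureKind.INSULIN_RECORD, 0, Slot.T2,
                    Units.INSULIN_U, regimen),
        FeatureMeta(3, "bg:T3:-2d", FeatureKind.BG_RECORD, -2, Slot.T3,
                    Units.MMOL_PER_L, None, True),
        FeatureMeta(4, "bg:T3:-1d", FeatureKind.BG_RECORD, -1, Slot.T3,
                    Units.MMOL_PER_L, None, True),
        FeatureMeta(5, "bg:T4:-1d", FeatureKind.BG_RECORD, -1, Slot.T4,
                    Units.MMOL_PER_L, None, True),
        FeatureMeta(6, "bg:T2:0d", FeatureKind.BG_RECORD, 0, Slot.T2,
                    Units.MMOL_PER_L),
        FeatureMeta(7, "demo:age", FeatureKind.DEMOGRAPHIC, units=Units.YEARS),
    ]
    fs = FeatureSpace(feats)
    values = np.array([6.0, 3.0, 3.0, 11.7, 14.8, 13.2, 9.6, 62.0])
    #               ins-2d ins-1d ins0d bgT3-2 bgT3-1 bgT4-1 bgT20 age
    baseline = np.array([6.0, 6.0, 4.0, 11.7, 11.7, 10.0, 10.0, 58.5])
    x = PatientState(
        space=fs,
        values=values,
        missing_mask=np.zeros(8, dtype=bool),
        baseline=baseline,
        regimen=regimen,
        base_dose=3.0,
        patient_id="fig3f",
    )
    w = np.array([-0.15, -0.20, -0.20, 0.35, 0.40, 0.35, 0.10, 0.01])
    W = np.zeros((8, 8))
    # adversarial negative-feedback term: with delta_ins = -3 and delta_bg = +3.1
    # a positive product weight yields a negative pair attribution
    W[1, 4] = W[4, 1] = adversarial_pair_weight
    model = GroundTruthModel(main_weights=w, pair_weights=W)
    return x, model
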