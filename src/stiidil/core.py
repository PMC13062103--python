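"""Feature universe, patient instances and the coalition value function.

Every explainer in this package is model-agnostic: it only ever queries an
opaque predictor ``f`` on modified copies of one patient's feature vector.
A *coalition* is the subset of features kept at their observed values; the
remaining coordinates are replaced by per-feature baseline (reference)
values, which defines the set function ``v(S) = f(mask(x, S))``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "FeatureKind",
    "Slot",
    "Regimen",
    "Units",
    "FeatureMeta",
    "FeatureSpace",
    "PatientState",
    "Coalition",
    "ValueFunction",
    "CoalitionError",
    "ModelEvaluationError",
    "mask_input",
    "coalition_value",
    "SLOT_LABELS",
]


class CoalitionError(ValueError):
    """A coalition references indices outside the feature space."""


class ModelEvaluationError(RuntimeError):
    """The black-box model returned a non-finite value."""


class FeatureKind(str, enum.Enum):
    BG_RECORD = "bg_record"
    INSULIN_RECORD = "insulin_record"
    MED_FLAG = "med_flag"
    DEMOGRAPHIC = "demographic"
    LAB = "lab"
    MISSING_INDICATOR = "missing_indicator"


class Slot(str, enum.Enum):
    """The seven daily measurement slots of the inpatient glucose grid."""

    T0 = "T0"
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"
    T5 = "T5"
    T6 = "T6"


SLOT_LABELS = {
    Slot.T0: "pre-breakfast",
    Slot.T1: "post-breakfast",
    Slot.T2: "pre-lunch",
    Slot.T3: "post-lunch",
    Slot.T4: "pre-dinner",
    Slot.T5: "post-dinner",
    Slot.T6: "before bedtime",
}


class Regimen(str, enum.Enum):
    """The six insulin dose regimens explained by the tool."""

    BEDTIME_LONG = "bedtime_long"
    PREBREAKFAST_PREMIX = "prebreakfast_premix"
    PREDINNER_PREMIX = "predinner_premix"
    PREBREAKFAST_SHORT = "prebreakfast_short"
    PRELUNCH_SHORT = "prelunch_short"
    PREDINNER_SHORT = "predinner_short"


class Units(str, enum.Enum):
    MMOL_PER_L = "mmol_per_L"
    INSULIN_U = "insulin_U"
    YEARS = "years"
    KG = "kg"
    DIMENSIONLESS = "dimensionless"


_GRID_KINDS = (FeatureKind.BG_RECORD, FeatureKind.INSULIN_RECORD)


@dataclass(frozen=True)
class FeatureMeta:
    """Clinical metadata for one feature; constraint rules key off it.

    ``day_offset`` is in days relative to the prediction day: -2 (two days
    ago), -1 (yesterday), 0 (the current day).  Grid features (BG and
    insulin records) must carry a day and slot; demographics must not.
    ``is_prescribed_bg`` marks the blood-glucose records most relevant to
    the explained insulin's action window.
    """

    index: int
    name: str
    kind: FeatureKind
    day_offset: Optional[int] = None
    slot: Optional[Slot] = None
    units: Units = Units.DIMENSIONLESS
    regimen_link: Optional[Regimen] = None
    is_prescribed_bg: bool = False

    def __post_init__(self) -> None:
        if self.kind in _GRID_KINDS:
            if self.day_offset is None or self.slot is None:
                raise ValueError(
                    f"feature {self.name!r}: {self.kind.value} requires day_offset and slot"
                )
            if self.day_offset not in (-2, -1, 0):
                raise ValueError(f"feature {self.name!r}: day_offset must be in {{-2,-1,0}}")
        if self.kind is FeatureKind.DEMOGRAPHIC and (
            self.day_offset is not None or self.slot is not None
        ):
            raise ValueError(f"feature {self.name!r}: demographics carry no day/slot")
        if self.is_prescribed_bg and self.kind is not FeatureKind.BG_RECORD:
            raise ValueError(f"feature {self.name!r}: only BG records can be prescribed BG")


@dataclass
class FeatureSpace:
    """The ordered feature universe N; indices are contiguous 0..d-1."""

    features: list[FeatureMeta]

    def __post_init__(self) -> None:
        for pos, f in enumerate(self.features):
            if f.index != pos:
                raise ValueError(
                    f"feature indices must be contiguous 0..d-1; got {f.index} at position {pos}"
                )

    @property
    def d(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i: int) -> FeatureMeta:
        return self.features[i]

    def index_of(self, name: str) -> int:
        for f in self.features:
            if f.name == name:
                return f.index
        raise KeyError(name)

    def by_kind(self, kind: FeatureKind) -> list[FeatureMeta]:
        return [f for f in self.features if f.kind is kind]

    def find(
        self,
        kind: FeatureKind,
        day_offset: Optional[int] = None,
        slot: Optional[Slot] = None,
    ) -> list[FeatureMeta]:
        out = []
        for f in self.features:
            if f.kind is not kind:
                continue
            if day_offset is not None and f.day_offset != day_offset:
                continue
            if slot is not None and f.slot is not slot:
                continue
            out.append(f)
        return out


@dataclass
class PatientState:
    """One explanation instance: observed values, missing mask, baselines.

    ``baseline`` holds the reference value each feature falls back to when
    excluded from a coalition, so the empty coalition is a fully specified
    model input and ``v(N) - v(emptyset)`` is the quantity attributed.
    """

    space: FeatureSpace
    values: np.ndarray
    missing_mask: np.ndarray
    baseline: np.ndarray
    regimen: Regimen
    base_dose: float = 0.0
    patient_id: str = "p0"

    def __post_init__(self) -> None:
        d = self.space.d
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.baseline = np.asarray(self.baseline, dtype=float)
        for nm, arr in (
            ("values", self.values),
            ("missing_mask", self.missing_mask),
            ("baseline", self.baseline),
        ):
            if arr.shape != (d,):
                raise ValueError(f"{nm} must have shape ({d},), got {arr.shape}")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("observed (non-missing) values must be finite")
        if not np.all(np.isfinite(self.baseline)):
            raise ValueError("baseline must be finite everywhere")
        self.regimen = Regimen(self.regimen)

    @property
    def d(self) -> int:
        return self.space.d


@dataclass(frozen=True)
class Coalition:
    """A subset S of feature indices kept at their observed values."""

    members: frozenset[int]

    def __init__(self, members: Iterable[int] = ()):  # accept any iterable
        object.__setattr__(self, "members", frozenset(int(i) for i in members))

    def validate(self, d: int) -> None:
        bad = [i for i in self.members if not (0 <= i < d)]
        if bad:
            raise CoalitionError(f"coalition indices {bad} out of range for d={d}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, i: int) -> bool:
        return i in self.members

    def __or__(self, other: "Coalition") -> "Coalition":
        return Coalition(self.members | other.members)


@dataclass
class ValueFunction:
    """Opaque predictor contract: a map R^d -> R (predicted dose change, U).

    ``gradient`` is optional; when present it enables analytic integrated
    gradients.  The predictor must be deterministic.
    """

    predict: Callable[[np.ndarray], float]
    gradient: Optional[Callable[[np.ndarray], np.ndarray]] = None
    name: str = "black_box"

    def __call__(self, z: np.ndarray) -> float:
        return float(self.predict(np.asarray(z, dtype=float)))


def mask_input(x: PatientState, S: Coalition | Iterable[int]) -> np.ndarray:
    """Return x.values on indices in S and x.baseline elsewhere.

    Pure function: neither input is modified.
    """
    if not isinstance(S, Coalition):
        S = Coalition(S)
    S.validate(x.d)
    z = x.baseline.copy()
    idx = list(S.members)
    if idx:
        z[idx] = x.values[idx]
    return z


def coalition_value(f: ValueFunction, x: PatientState, S: Coalition | Iterable[int]) -> float:
    """Evaluate v(S) = f(mask_input(x, S)); raises on non-finite output."""
    if not isinstance(S, Coalition):
        S = Coalition(S)
    y = f(mask_input(x, S))
    if not np.isfinite(y):
        raise ModelEvaluationError(
            f"model returned non-finite value {y!r} for coalition {sorted(S.members)}"
        )
    return y
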