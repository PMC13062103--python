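"""Evaluation metrics: expert alignment, correctness tiers, quadrant and
proportion statistics, dose accuracy, confidence benefit, and the faulty-
explanation generator used to probe over-reliance on explanations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import FeatureKind, FeatureSpace
from .exact import ExplanationCoefficients

__all__ = [
    "ExplanationItem",
    "ExpertAnnotation",
    "DosageRecord",
    "rank_items",
    "top_n_alignment_rate",
    "correctness_rates",
    "feature_contribution_correlation",
    "bg_quadrant_table",
    "prescribed_and_missing_proportions",
    "mae_dosage",
    "clinical_agreement",
    "benefit_score",
    "make_faulty_explanation",
    "DEFAULT_BENEFIT_MATRIX",
]

Target = Union[int, tuple[int, int]]


@dataclass(frozen=True)
class ExplanationItem:
    """One ranked explanation entry: a feature or feature pair with a signed
    effect split into direction and magnitude (U)."""

    target: Target
    direction: int
    magnitude: float
    rank: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    @property
    def is_pair(self) -> bool:
        return isinstance(self.target, tuple)


def _tie_key(target: Target, magnitude: float):
    # magnitude desc, mains before pairs, then lower feature index
    is_pair = isinstance(target, tuple)
    idx = tuple(target) if is_pair else (target,)
    return (-magnitude, is_pair, idx)


def rank_items(coeffs: ExplanationCoefficients, k: int = 10, min_magnitude: float = 0.0) -> list[ExplanationItem]:
    """Top-k explanation items from a coefficient set, ranked by |effect|.

    Ties break by (magnitude desc, main before pair, lower feature index).
    """
    entries: list[tuple[Target, float]] = []
    for i in range(coeffs.d):
        entries.append((i, float(coeffs.main[i])))
    for i in range(coeffs.d):
        for j in range(i + 1, coeffs.d):
            entries.append(((i, j), float(coeffs.pair[i, j])))
    entries = [(t, v) for t, v in entries if abs(v) > min_magnitude]
    entries.sort(key=lambda tv: _tie_key(tv[0], abs(tv[1])))
    items = []
    for r, (t, v) in enumerate(entries[:k], start=1):
        items.append(
            ExplanationItem(target=t, direction=1 if v >= 0 else -1, magnitude=abs(v), rank=r)
        )
    return items


@dataclass
class ExpertAnnotation:
    """Panel annotations for one explained case.

    ``top3`` holds each expert's (up to 3) most influential targets;
    ``verdicts`` is (n_items, n_experts, 3) booleans for the
    (feature, direction, size) correctness aspects of each displayed item.
    """

    top3: list[set]
    verdicts: np.ndarray

    def __post_init__(self) -> None:
        self.verdicts = np.asarray(self.verdicts, dtype=bool)
        if self.verdicts.ndim != 3 or self.verdicts.shape[2] != 3:
            raise ValueError("verdicts must have shape (n_items, n_experts, 3)")
        if self.verdicts.shape[1] % 2 == 0:
            raise ValueError("expert count must be odd so majority votes are decidable")
        for t3 in self.top3:
            if len(t3) > 3:
                raise ValueError("each expert picks at most 3 targets")


@dataclass
class DosageRecord:
    """One clinician decision vs the expert-panel reference."""

    clinician_dose: float
    expert_dose: float
    prior_dose: float
    confidence: int
    scenario: int = 1

    def __post_init__(self) -> None:
        if min(self.clinician_dose, self.expert_dose, self.prior_dose) < 0:
            raise ValueError("doses must be >= 0")
        if not 1 <= self.confidence <= 10:
            raise ValueError("confidence must be an integer 1..10")
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1..4")


def top_n_alignment_rate(
    items: Sequence[ExplanationItem],
    annotation: ExpertAnnotation,
    N: int = 10,
    pooling: str = "union",
) -> float:
    """Overlap between expert picks and the algorithm's top-N items, in %.

    alignment = |expert picks intersect top-N targets| / |expert picks| * 100.
    ``pooling='union'`` pools the panel's top-3 sets into one set;
    ``'per_expert_mean'`` averages the per-expert rates instead.
    """
    if N not in (3, 5, 10):
        raise ValueError("N must be one of 3, 5, 10")
    algo = {it.target for it in items if it.rank <= N}

    def rate(picks: set) -> float:
        if not picks:
            raise ValueError("expert picks are empty; alignment rate undefined")
        return 100.0 * len(picks & algo) / len(picks)

    if pooling == "union":
        pooled: set = set()
        for t3 in annotation.top3:
            pooled |= t3
        return rate(pooled)
    if pooling == "per_expert_mean":
        return float(np.mean([rate(t3) for t3 in annotation.top3]))
    raise ValueError(f"unknown pooling {pooling!r}")


def correctness_rates(annotation: ExpertAnnotation) -> dict:
    """Nested correctness tiers by per-item majority vote, in %.

    partial: feature correct; moderate: feature and direction; absolute:
    feature, direction and effect size.  Tiers are conjunctive per expert
    before voting, which guarantees partial >= moderate >= absolute.
    """
    v = annotation.verdicts
    n_items = v.shape[0]
    if n_items == 0:
        raise ValueError("no items to score")
    feat = v[:, :, 0]
    direc = feat & v[:, :, 1]
    size = direc & v[:, :, 2]

    def majority(bools: np.ndarray) -> np.ndarray:
        return bools.sum(axis=1) * 2 > bools.shape[1]

    return {
        "partial": 100.0 * majority(feat).mean(),
        "moderate": 100.0 * majority(direc).mean(),
        "absolute": 100.0 * majority(size).mean(),
    }


def feature_contribution_correlation(values: np.ndarray, contributions: np.ndarray) -> dict:
    """Pearson r (with two-sided p) of feature values vs their contributions."""
    values = np.asarray(values, dtype=float)
    contributions = np.asarray(contributions, dtype=float)
    if values.shape != contributions.shape or values.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    r, p = stats.pearsonr(values, contributions)
    return {"r": float(r), "p": float(p)}


def bg_quadrant_table(records: Sequence[dict], atol: float = 1e-6) -> dict:
    """Classify (delta BG, contribution) points into quadrants.

    Quadrants: I (rise, +), II (fall, +), III (fall, -), IV (rise, -);
    II and IV are the clinically inconsistent ones.  Points within ``atol``
    of an axis are excluded and counted separately.
    """
    counts = {"I": 0, "II": 0, "III": 0, "IV": 0, "excluded": 0}
    for rec in records:
        db, c = float(rec["delta_bg"]), float(rec["contribution"])
        if abs(db) <= atol or abs(c) <= atol:
            counts["excluded"] += 1
        elif db > 0 and c > 0:
            counts["I"] += 1
        elif db < 0 and c > 0:
            counts["II"] += 1
        elif db < 0 and c < 0:
            counts["III"] += 1
        else:
            counts["IV"] += 1
    total = counts["I"] + counts["II"] + counts["III"] + counts["IV"]
    counts["inconsistent_fraction"] = (
        (counts["II"] + counts["IV"]) / total if total else 0.0
    )
    return counts


def prescribed_and_missing_proportions(
    items: Sequence[ExplanationItem],
    fs: FeatureSpace,
    missing_mask: Optional[np.ndarray] = None,
) -> dict:
    """Share (%) of top-item magnitude mass on prescribed-BG and on missing
    features.  A pair item counts toward a class if either member is in it."""

    def touches(target: Target, pred) -> bool:
        idx = target if isinstance(target, tuple) else (target,)
        return any(pred(int(i)) for i in idx)

    total = sum(it.magnitude for it in items)
    if total == 0:
        return {"prescribed_share": 0.0, "missing_share": 0.0}
    pres = sum(
        it.magnitude for it in items if touches(it.target, lambda i: fs[i].is_prescribed_bg)
    )
    if missing_mask is None:
        miss = 0.0
    else:
        mm = np.asarray(missing_mask, dtype=bool)
        miss = sum(it.magnitude for it in items if touches(it.target, lambda i: bool(mm[i])))
    return {
        "prescribed_share": 100.0 * pres / total,
        "missing_share": 100.0 * miss / total,
    }


def mae_dosage(records: Sequence[DosageRecord]) -> float:
    """Mean absolute error between clinician and expert doses, U."""
    if not records:
        raise ValueError("no dosage records")
    return float(np.mean([abs(r.clinician_dose - r.expert_dose) for r in records]))


def clinical_agreement(record: DosageRecord) -> bool:
    """Same adjustment direction as the expert and dose within 20% (inclusive).

    Direction uses the change from the prior dose; a zero change matches
    only a zero change.  With an expert dose of 0, agreement additionally
    requires the clinician dose to be exactly 0.
    """
    c, e, p = record.clinician_dose, record.expert_dose, record.prior_dose
    if np.sign(c - p) != np.sign(e - p):
        return False
    if e == 0.0:
        return c == 0.0
    return abs(c - e) / e <= 0.20


#: accuracy-dominant default: rows = accuracy (better / unchanged / worse),
#: columns = confidence (up / same / down).  Misleading assistance (worse
#: accuracy with rising confidence) is penalized; the table is antisymmetric
#: under swapping the improved/worsened roles.
DEFAULT_BENEFIT_MATRIX = ((2, 1, 1), (1, 0, -1), (-1, -1, -2))


def benefit_score(
    pre: DosageRecord,
    post: DosageRecord,
    expert_dose: Optional[float] = None,
    matrix: Sequence[Sequence[int]] = DEFAULT_BENEFIT_MATRIX,
    accuracy_deadband: float = 0.25,
    confidence_deadband: int = 0,
) -> int:
    """Score an assistance step by (accuracy change) x (confidence change).

    Accuracy uses |dose - expert|; a change within ``accuracy_deadband`` U
    counts as unchanged.  The 3x3 score matrix is configurable.
    """
    e = expert_dose if expert_dose is not None else post.expert_dose
    err_pre = abs(pre.clinician_dose - e)
    err_post = abs(post.clinician_dose - e)
    derr = err_post - err_pre
    if derr < -accuracy_deadband:
        row = 0  # improved
    elif derr > accuracy_deadband:
        row = 2  # worsened
    else:
        row = 1
    dconf = post.confidence - pre.confidence
    if dconf > confidence_deadband:
        col = 0  # more confident
    elif dconf < -confidence_deadband:
        col = 2
    else:
        col = 1
    return int(matrix[row][col])


def make_faulty_explanation(
    items: Sequence[ExplanationItem], seed: int = 0
) -> list[ExplanationItem]:
    """Derange the (direction, magnitude) payloads across item targets.

    No item keeps its original payload; the multiset of targets and the
    multiset of payloads are both preserved.  Ranks are recomputed from the
    new magnitudes.  Deterministic per seed; pure function.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to derange")
    rng = np.random.default_rng(seed)
    # Sattolo's cyclic shuffle: produces a uniform single-cycle permutation,
    # which has no fixed points by construction
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i))
        perm[i], perm[j] = perm[j], perm[i]
    payloads = [(items[perm[k]].direction, items[perm[k]].magnitude) for k in range(n)]
    shuffled = [
        (items[k].target, payloads[k][0], payloads[k][1]) for k in range(n)
    ]
    shuffled.sort(key=lambda t: _tie_key(t[0], t[2]))
    return [
        ExplanationItem(target=t, direction=s, magnitude=m, rank=r)
        for r, (t, s, m) in enumerate(shuffled, start=1)
    ]
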