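"""Readers, writers and the top-10 explanation report.

Formats: patient records round-trip as CSV (one row per feature) and JSON
(grid features nested by day and slot); explanation reports and metric
outputs are JSON; expert annotations and dosage records are CSV with
documented headers.  Floats are serialized with their shortest lossless
decimal representation, so write-then-read is the identity.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import __version__
from .core import (
    FeatureKind,
    FeatureMeta,
    FeatureSpace,
    PatientState,
    Regimen,
    Slot,
    Units,
)
from .metrics import DosageRecord, ExpertAnnotation, ExplanationItem

__all__ = [
    "ExplanationReport",
    "ParseError",
    "write_patient_json",
    "read_patient_json",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_report",
    "read_report",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_dosage_csv",
    "write_json",
]

PATIENT_CSV_HEADER = [
    "patient_id",
    "regimen",
    "base_dose",
    "index",
    "name",
    "kind",
    "day_offset",
    "slot",
    "units",
    "regimen_link",
    "is_prescribed_bg",
    "value",
    "missing",
    "baseline",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and location."""


def _fmt(x: float) -> str:
    return repr(float(x))


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Patient records
# ---------------------------------------------------------------------------


def _feature_record(x: PatientState, f: FeatureMeta) -> dict:
    return {
        "index": f.index,
        "name": f.name,
        "kind": f.kind.value,
        "day_offset": f.day_offset,
        "slot": f.slot.value if f.slot else None,
        "units": f.units.value,
        "regimen_link": f.regimen_link.value if f.regimen_link else None,
        "is_prescribed_bg": f.is_prescribed_bg,
        "value": float(x.values[f.index]),
        "missing": bool(x.missing_mask[f.index]),
        "baseline": float(x.baseline[f.index]),
    }


def _meta_from_record(rec: dict) -> FeatureMeta:
    return FeatureMeta(
        index=int(rec["index"]),
        name=rec["name"],
        kind=FeatureKind(rec["kind"]),
        day_offset=None if rec.get("day_offset") is None else int(rec["day_offset"]),
        slot=None if rec.get("slot") is None else Slot(rec["slot"]),
        units=Units(rec.get("units", "dimensionless")),
        regimen_link=None if rec.get("regimen_link") is None else Regimen(rec["regimen_link"]),
        is_prescribed_bg=bool(rec.get("is_prescribed_bg", False)),
    )


def patient_to_dict(x: PatientState) -> dict:
    """JSON form: grid features nested day -> slot, the rest flat."""
    grid: dict = {}
    flat: list = []
    for f in x.space:
        rec = _feature_record(x, f)
        if f.day_offset is not None and f.slot is not None:
            grid.setdefault(str(f.day_offset), {}).setdefault(f.slot.value, []).append(rec)
        else:
            flat.append(rec)
    return {
        "patient_id": x.patient_id,
        "regimen": x.regimen.value,
        "base_dose": float(x.base_dose),
        "grid": grid,
        "flat": flat,
    }


def patient_from_dict(dd: dict, where: str = "<dict>") -> PatientState:
    try:
        recs: list[dict] = list(dd.get("flat", []))
        for day, slots in dd.get("grid", {}).items():
            for slot, rs in slots.items():
                recs.extend(rs)
        recs.sort(key=lambda r: int(r["index"]))
        feats = [_meta_from_record(r) for r in recs]
        space = FeatureSpace(feats)
        values = np.array([float(r["value"]) for r in recs])
        missing = np.array([bool(r["missing"]) for r in recs])
        baseline = np.array([float(r["baseline"]) for r in recs])
        return PatientState(
            space=space,
            values=values,
            missing_mask=missing,
            baseline=baseline,
            regimen=Regimen(dd["regimen"]),
            base_dose=float(dd.get("base_dose", 0.0)),
            patient_id=str(dd.get("patient_id", "p0")),
        )
    except (KeyError, ValueError, TypeError) as e:
        raise ParseError(f"{where}: invalid patient record: {e}") from e


def write_patient_json(x: PatientState, path: Union[str, Path]) -> None:
    write_json(patient_to_dict(x), path)


def read_patient_json(path: Union[str, Path]) -> PatientState:
    path = Path(path)
    try:
        dd = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}:{e.lineno}: invalid JSON: {e.msg}") from e
    return patient_from_dict(dd, where=str(path))


def write_cohort_csv(patients: Sequence[PatientState], path: Union[str, Path]) -> None:
    """One row per (patient, feature); UTF-8, comma separated, '.' decimal."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(PATIENT_CSV_HEADER)
        for x in patients:
            for f in x.space:
                rec = _feature_record(x, f)
                wr.writerow(
                    [
                        x.patient_id,
                        x.regimen.value,
                        _fmt(x.base_dose),
                        rec["index"],
                        rec["name"],
                        rec["kind"],
                        "" if rec["day_offset"] is None else rec["day_offset"],
                        rec["slot"] or "",
                        rec["units"],
                        rec["regimen_link"] or "",
                        int(rec["is_prescribed_bg"]),
                        _fmt(rec["value"]),
                        int(rec["missing"]),
                        _fmt(rec["baseline"]),
                    ]
                )


def read_cohort_csv(path: Union[str, Path]) -> list[PatientState]:
    path = Path(path)
    groups: dict[str, list[tuple[int, dict]]] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rd = csv.DictReader(fh)
        if rd.fieldnames is None or set(PATIENT_CSV_HEADER) - set(rd.fieldnames):
            raise ParseError(f"{path}:1: expected header {','.join(PATIENT_CSV_HEADER)}")
        n_rows = 0
        for lineno, row in enumerate(rd, start=2):
            n_rows += 1
            try:
                pid = row["patient_id"]
                rec = {
                    "index": int(row["index"]),
                    "name": row["name"],
                    "kind": row["kind"],
                    "day_offset": int(row["day_offset"]) if row["day_offset"] else None,
                    "slot": row["slot"] or None,
                    "units": row["units"],
                    "regimen_link": row["regimen_link"] or None,
                    "is_prescribed_bg": bool(int(row["is_prescribed_bg"])),
                    "value": float(row["value"]),
                    "missing": bool(int(row["missing"])),
                    "baseline": float(row["baseline"]),
                    "_regimen": row["regimen"],
                    "_base_dose": float(row["base_dose"]),
                }
            except (KeyError, ValueError) as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
            if pid not in groups:
                groups[pid] = []
                order.append(pid)
            groups[pid].append((lineno, rec))
    if n_rows == 0:
        raise ParseError(f"{path}: empty cohort file (no data rows)")
    patients = []
    for pid in order:
        recs = [r for _, r in sorted(groups[pid], key=lambda lr: lr[1]["index"])]
        lineno = groups[pid][0][0]
        dd = {
            "patient_id": pid,
            "regimen": recs[0]["_regimen"],
            "base_dose": recs[0]["_base_dose"],
            "grid": {},
            "flat": recs,
        }
        try:
            patients.append(patient_from_dict(dd, where=f"{path}:{lineno}"))
        except ParseError:
            raise
    return patients


# ---------------------------------------------------------------------------
# Explanation reports
# ---------------------------------------------------------------------------


@dataclass
class ExplanationReport:
    """Top-k explanation items plus everything needed to reproduce the run."""

    patient_id: str
    regimen: Regimen
    predicted_dose: float
    items: list[ExplanationItem]
    feature_names: dict[int, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def tgt(t):
            return list(t) if isinstance(t, tuple) else t

        def names(t):
            idx = t if isinstance(t, tuple) else (t,)
            return [self.feature_names.get(int(i), str(i)) for i in idx]

        meta = dict(self.metadata)
        meta.setdefault("tool_version", __version__)
        return {
            "patient_id": self.patient_id,
            "regimen": self.regimen.value,
            "predicted_dose": float(self.predicted_dose),
            "items": [
                {
                    "rank": it.rank,
                    "target": tgt(it.target),
                    "feature_names": names(it.target),
                    "direction": it.direction,
                    "magnitude": float(it.magnitude),
                }
                for it in self.items
            ],
            "metadata": meta,
        }

    @classmethod
    def from_dict(cls, dd: dict) -> "ExplanationReport":
        items = []
        names: dict[int, str] = {}
        for rec in dd["items"]:
            t = rec["target"]
            target = tuple(t) if isinstance(t, list) else int(t)
            idx = target if isinstance(target, tuple) else (target,)
            for i, nm in zip(idx, rec.get("feature_names", [])):
                names[int(i)] = nm
            items.append(
                ExplanationItem(
                    target=target,
                    direction=int(rec["direction"]),
                    magnitude=float(rec["magnitude"]),
                    rank=int(rec["rank"]),
                )
            )
        return cls(
            patient_id=dd["patient_id"],
            regimen=Regimen(dd["regimen"]),
            predicted_dose=float(dd["predicted_dose"]),
            items=items,
            feature_names=names,
            metadata=dict(dd.get("metadata", {})),
        )


def write_report(report: ExplanationReport, path: Union[str, Path]) -> None:
    write_json(report.to_dict(), path)


def read_report(path: Union[str, Path]) -> ExplanationReport:
    path = Path(path)
    try:
        return ExplanationReport.from_dict(json.loads(path.read_text()))
    except (json.JSONDecodeError, KeyError, ValueError) as e:
        raise ParseError(f"{path}: invalid report: {e}") from e


# ---------------------------------------------------------------------------
# Annotations and dosage records
# ---------------------------------------------------------------------------

ANNOTATION_HEADER = [
    "case_id",
    "expert_id",
    "record_type",  # 'top3' or 'verdict'
    "target",  # '3' for a feature, '2|5' for a pair
    "item_rank",  # verdict rows only
    "feature_correct",
    "direction_correct",
    "size_correct",
]


def _parse_target(s: str):
    if "|" in s:
        i, j = s.split("|")
        return (int(i), int(j))
    return int(s)


def _fmt_target(t) -> str:
    return f"{t[0]}|{t[1]}" if isinstance(t, tuple) else str(t)


def write_annotations_csv(
    annotations: dict[str, ExpertAnnotation], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(ANNOTATION_HEADER)
        for case_id, ann in annotations.items():
            for e, t3 in enumerate(ann.top3):
                for t in sorted(t3, key=_fmt_target):
                    wr.writerow([case_id, e, "top3", _fmt_target(t), "", "", "", ""])
            n_items, n_experts, _ = ann.verdicts.shape
            for r in range(n_items):
                for e in range(n_experts):
                    fc, dc, sc = ann.verdicts[r, e]
                    wr.writerow(
                        [case_id, e, "verdict", "", r + 1, int(fc), int(dc), int(sc)]
                    )


def read_annotations_csv(path: Union[str, Path]) -> dict[str, ExpertAnnotation]:
    path = Path(path)
    top3: dict[str, dict[int, set]] = {}
    verdicts: dict[str, dict[tuple[int, int], tuple[bool, bool, bool]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rd = csv.DictReader(fh)
        if rd.fieldnames is None or set(ANNOTATION_HEADER) - set(rd.fieldnames):
            raise ParseError(f"{path}:1: expected header {','.join(ANNOTATION_HEADER)}")
        for lineno, row in enumerate(rd, start=2):
            try:
                cid = row["case_id"]
                eid = int(row["expert_id"])
                if row["record_type"] == "top3":
                    top3.setdefault(cid, {}).setdefault(eid, set()).add(
                        _parse_target(row["target"])
                    )
                elif row["record_type"] == "verdict":
                    verdicts.setdefault(cid, {})[(int(row["item_rank"]) - 1, eid)] = (
                        bool(int(row["feature_correct"])),
                        bool(int(row["direction_correct"])),
                        bool(int(row["size_correct"])),
                    )
                else:
                    raise ValueError(f"unknown record_type {row['record_type']!r}")
            except (KeyError, ValueError) as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    out: dict[str, ExpertAnnotation] = {}
    for cid in sorted(set(top3) | set(verdicts)):
        t3map = top3.get(cid, {})
        vmap = verdicts.get(cid, {})
        experts = sorted({e for _, e in vmap} | set(t3map))
        n_items = 1 + max((r for r, _ in vmap), default=-1)
        v = np.zeros((n_items, len(experts), 3), dtype=bool)
        for (r, e), tri in vmap.items():
            v[r, experts.index(e)] = tri
        out[cid] = ExpertAnnotation(
            top3=[t3map.get(e, set()) for e in experts], verdicts=v
        )
    return out


DOSAGE_HEADER = ["case_id", "scenario", "clinician_dose", "expert_dose", "prior_dose", "confidence"]


def read_dosage_csv(path: Union[str, Path]) -> list[dict]:
    """Rows of {case_id, record}; record is a DosageRecord."""
    path = Path(path)
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        rd = csv.DictReader(fh)
        if rd.fieldnames is None or set(DOSAGE_HEADER) - set(rd.fieldnames):
            raise ParseError(f"{path}:1: expected header {','.join(DOSAGE_HEADER)}")
        for lineno, row in enumerate(rd, start=2):
            try:
                out.append(
                    {
                        "case_id": row["case_id"],
                        "record": DosageRecord(
                            clinician_dose=float(row["clinician_dose"]),
                            expert_dose=float(row["expert_dose"]),
                            prior_dose=float(row["prior_dose"]),
                            confidence=int(row["confidence"]),
                            scenario=int(row["scenario"]),
                        ),
                    }
                )
            except (KeyError, ValueError) as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return out
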