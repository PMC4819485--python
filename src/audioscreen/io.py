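"""Readers and writers: cohort CSV, single-patient JSON, report documents.

The batch format is a plain CSV with one row per patient: columns ``id``,
``age``, ``sex``, then one threshold column per role and frequency named
``<role>_<freq>kHz`` with role in {acute, prev, contra} (e.g. ``acute_0.5kHz``,
``prev_1kHz``, ``contra_4kHz``). An empty cell means "not measured"; the
literal ``NR`` (case-insensitive) means "no response" and is dummy coded to
120 dB HL on ingestion. Malformed rows are collected into a rejects list
with their line numbers, never silently dropped.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .core import (
    Audiogram,
    AudiogramRole,
    AudiometryError,
    Ear,
    NO_RESPONSE,
    PatientRecord,
    Sex,
    format_frequency,
)
from .eligibility import (
    BaselineComparison,
    BaselineKind,
    EligibilityReport,
    InclusionCriteria,
    Recommendation,
    RecruitmentRate,
    WindowResult,
)

_COLUMN_RE = re.compile(r"^(acute|prev|contra)_([0-9.]+)kHz$")

_ROLE_BY_PREFIX = {
    "acute": (AudiogramRole.ACUTE, Ear.AFFECTED),
    "prev": (AudiogramRole.BASELINE_PREVIOUS, Ear.AFFECTED),
    "contra": (AudiogramRole.BASELINE_CONTRALATERAL, Ear.CONTRALATERAL),
}


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    patient_id: str | None
    reason: str


@dataclass
class CohortReadResult:
    records: list[PatientRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)


def _parse_threshold(raw) -> float | None:
    """Cell -> threshold, NO_RESPONSE, or None for an empty cell."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    if isinstance(raw, str):
        s = raw.strip()
        if not s:
            return None
        if s.upper() == "NR":
            return NO_RESPONSE
        return float(s)
    return float(raw)


def _parse_sex(raw) -> Sex:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return Sex.UNSPECIFIED
    s = str(raw).strip().lower()
    if not s:
        return Sex.UNSPECIFIED
    aliases = {"f": Sex.FEMALE, "female": Sex.FEMALE, "m": Sex.MALE, "male": Sex.MALE,
               "unspecified": Sex.UNSPECIFIED, "u": Sex.UNSPECIFIED}
    if s not in aliases:
        raise AudiometryError(f"unknown sex value {raw!r}")
    return aliases[s]


def read_cohort_csv(path: str | Path) -> CohortReadResult:
    """Read a batch cohort CSV; dummy coding is applied on ingestion."""
    df = pd.read_csv(path, dtype=str)
    threshold_cols: dict[str, tuple[str, float]] = {}
    for col in df.columns:
        if col in ("id", "age", "sex"):
            continue
        m = _COLUMN_RE.match(col)
        if not m:
            raise AudiometryError(f"unknown column {col!r} in {path}")
        threshold_cols[col] = (m.group(1), float(m.group(2)))

    result = CohortReadResult()
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        pid = None if pd.isna(row.get("id")) else str(row["id"]).strip()
        try:
            by_role: dict[str, dict[float, float]] = {p: {} for p in _ROLE_BY_PREFIX}
            for col, (prefix, freq) in threshold_cols.items():
                value = _parse_threshold(row[col])
                if value is None:
                    continue
                if freq in by_role[prefix]:
                    raise AudiometryError(
                        f"duplicate threshold for {prefix} at {format_frequency(freq)} kHz"
                    )
                by_role[prefix][freq] = value
            if not by_role["acute"]:
                raise AudiometryError("no acute thresholds in row")
            age = None
            if "age" in row and not pd.isna(row["age"]) and str(row["age"]).strip():
                age = int(float(row["age"]))
            audiograms = {
                prefix: Audiogram(thresholds, ear=ear, role=role)
                for prefix, thresholds in by_role.items()
                if thresholds
                for role, ear in [_ROLE_BY_PREFIX[prefix]]
            }
            result.records.append(
                PatientRecord(
                    acute=audiograms["acute"],
                    id=pid,
                    age=age,
                    sex=_parse_sex(row.get("sex")),
                    baseline_previous=audiograms.get("prev"),
                    baseline_contralateral=audiograms.get("contra"),
                )
            )
        except (AudiometryError, ValueError) as exc:
            result.rejects.append(RejectedRow(line_number=line, patient_id=pid, reason=str(exc)))
    return result


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    """Write records in the batch CSV layout (inverse of :func:`read_cohort_csv`)."""
    prefixes = {
        "acute": lambda r: r.acute,
        "prev": lambda r: r.baseline_previous,
        "contra": lambda r: r.baseline_contralateral,
    }
    freq_cols: list[str] = []
    for prefix, get in prefixes.items():
        freqs = sorted({f for r in records if get(r) is not None for f in get(r).frequencies})
        freq_cols.extend(f"{prefix}_{format_frequency(f)}kHz" for f in freqs)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id or "",
            "age": "" if r.age is None else r.age,
            "sex": r.sex.value,
        }
        for col in freq_cols:
            prefix, freq = _COLUMN_RE.match(col).group(1), float(_COLUMN_RE.match(col).group(2))
            ag = prefixes[prefix](r)
            row[col] = "" if ag is None or freq not in ag else ag[freq]
        rows.append(row)
    pd.DataFrame(rows, columns=["id", "age", "sex", *freq_cols]).to_csv(path, index=False)


def read_patient_json(path: str | Path) -> PatientRecord:
    """Read a single-patient JSON record.

    Layout: ``{"id": ..., "age": ..., "sex": ...,
    "audiograms": [{"role": "acute", "ear": "affected",
    "thresholds": {"0.5": 50, ...}}, ...]}`` with frequencies as object keys
    in kHz and thresholds in dB HL (or ``"NR"``).
    """
    with open(path) as fh:
        doc = json.load(fh)
    by_role: dict[AudiogramRole, Audiogram] = {}
    for entry in doc.get("audiograms", []):
        role = AudiogramRole(entry["role"])
        thresholds = {
            float(f): (NO_RESPONSE if isinstance(t, str) and t.strip().upper() == "NR" else float(t))
            for f, t in entry["thresholds"].items()
        }
        by_role[role] = Audiogram(thresholds, ear=Ear(entry.get("ear", "unspecified")), role=role)
    if AudiogramRole.ACUTE not in by_role:
        raise AudiometryError(f"{path}: no acute audiogram")
    return PatientRecord(
        acute=by_role[AudiogramRole.ACUTE],
        id=doc.get("id"),
        age=doc.get("age"),
        sex=_parse_sex(doc.get("sex")),
        baseline_previous=by_role.get(AudiogramRole.BASELINE_PREVIOUS),
        baseline_contralateral=by_role.get(AudiogramRole.BASELINE_CONTRALATERAL),
    )


# ---------------------------------------------------------------------------
# Report document serialization


def _window_to_dict(w: WindowResult | None):
    if w is None:
        return None
    return {
        "frequencies_khz": list(w.frequencies),
        "complete": w.complete,
        "mean_difference_db": w.mean_difference,
        "label": w.label,
    }


def _window_from_dict(d) -> WindowResult | None:
    if d is None:
        return None
    return WindowResult(
        frequencies=tuple(d["frequencies_khz"]),
        complete=d["complete"],
        mean_difference=d["mean_difference_db"],
    )


def report_to_dict(report: EligibilityReport) -> dict:
    return {
        "patient_id": report.patient_id,
        "data_check": {"valid": report.data_check.valid, "reasons": list(report.data_check.reasons)},
        "severity_4pta_db": report.severity_4pta,
        "severity_criterion_met": report.severity_criterion_met,
        "grades": {
            scale: {role: {"grade_index": g[0], "label": g[1]} for role, g in per.items()}
            for scale, per in report.grades.items()
        },
        "comparisons": [
            {
                "baseline_kind": c.baseline_kind.value,
                "computable": c.computable,
                "reason": c.reason,
                "windows": [_window_to_dict(w) for w in c.windows],
                "max_window": _window_to_dict(c.max_window),
                "qualifying_windows": [_window_to_dict(w) for w in c.qualifying_windows],
                "difference_criterion_met": c.difference_criterion_met,
            }
            for c in report.comparisons
        ],
        "recommendations": {k.value: v.value for k, v in report.recommendations.items()},
    }


def report_from_dict(d: dict) -> EligibilityReport:
    from .core import DataCheckResult

    return EligibilityReport(
        patient_id=d["patient_id"],
        data_check=DataCheckResult(tuple(d["data_check"]["reasons"])),
        severity_4pta=d["severity_4pta_db"],
        severity_criterion_met=d["severity_criterion_met"],
        grades={
            scale: {role: (g["grade_index"], g["label"]) for role, g in per.items()}
            for scale, per in d["grades"].items()
        },
        comparisons=tuple(
            BaselineComparison(
                baseline_kind=BaselineKind(c["baseline_kind"]),
                computable=c["computable"],
                reason=c["reason"],
                windows=tuple(_window_from_dict(w) for w in c["windows"]),
                max_window=_window_from_dict(c["max_window"]),
                qualifying_windows=tuple(_window_from_dict(w) for w in c["qualifying_windows"]),
                difference_criterion_met=c["difference_criterion_met"],
            )
            for c in d["comparisons"]
        ),
        recommendations={
            BaselineKind(k): Recommendation(v) for k, v in d["recommendations"].items()
        },
    )


@dataclass
class ReportDocument:
    """Archivable cohort report: per-patient reports, summary, provenance."""

    reports: list[EligibilityReport]
    summary: RecruitmentRate
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "provenance": self.provenance,
            "summary": {
                "eligible_count": self.summary.eligible_count,
                "total": self.summary.total,
                "rate": self.summary.rate,
            },
            "reports": [report_to_dict(r) for r in self.reports],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportDocument":
        return cls(
            reports=[report_from_dict(r) for r in d["reports"]],
            summary=RecruitmentRate(
                eligible_count=d["summary"]["eligible_count"], total=d["summary"]["total"]
            ),
            provenance=d["provenance"],
        )

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "ReportDocument":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_provenance(criteria: InclusionCriteria, *, iso_edition: str, seed: int | None = None) -> dict:
    return {
        "criteria": criteria.to_dict(),
        "iso7029_edition": iso_edition,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def summary_tsv(doc: ReportDocument) -> str:
    """Human-readable per-patient TSV summary of a report document."""
    lines = ["id\tseverity_4pta_db\tseverity_met\tprevious\tcontralateral\tnormative"]
    for r in doc.reports:
        recs = {k.value: v.value for k, v in r.recommendations.items()}
        sev = "" if r.severity_4pta is None else f"{r.severity_4pta:.2f}"
        lines.append(
            "\t".join(
                [
                    r.patient_id or "",
                    sev,
                    str(r.severity_criterion_met).lower(),
                    recs.get("previous", ""),
                    recs.get("contralateral", ""),
                    recs.get("normative", ""),
                ]
            )
        )
    rate = doc.summary.rate
    lines.append(
        f"# eligible {doc.summary.eligible_count}/{doc.summary.total}"
        + (f" rate {rate:.2f}" if rate is not None else " rate undefined")
    )
    return "\n".join(lines) + "\n"
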