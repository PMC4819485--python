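"""Trial-eligibility decision engine.

Two audiological inclusion criteria are evaluated per patient:

* **Minimum severity** — the four-frequency pure-tone average (4PTA, default
  0.5/1/2/4 kHz) of the acute audiogram must reach a configured level.
* **Minimum hearing-loss difference** — the maximum mean difference between
  acute and baseline thresholds over any window of three (configurable)
  consecutive grid frequencies must reach a configured level.

Setting a criterion's value to zero disables it. Each available baseline
variant — a previous audiogram of the affected ear, the contralateral ear,
or the ISO 7029 age/sex normative audiogram — yields its own comparison and
recommendation. WHO/EU impairment grading is attached for qualitative
information only (it formally applies to the better ear).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import (
    Audiogram,
    AudiometryError,
    CANONICAL_GRID,
    DataCheckResult,
    PatientRecord,
    PTA4_FREQUENCIES,
    Sex,
    data_check,
    format_frequency,
    grid_windows,
    pure_tone_average,
)
from .iso7029 import Iso7029CoefficientTable, load_default_table, normative_audiogram


class BaselineKind(str, Enum):
    PREVIOUS = "previous"
    CONTRALATERAL = "contralateral"
    NORMATIVE = "normative"


class Recommendation(str, Enum):
    INCLUDE = "include"
    EXCLUDE = "exclude"
    NOT_COMPUTABLE = "not_computable"


#: Baseline preference order used for cohort recruitment estimates: a prior
#: audiogram of the affected ear is the best reference, then the
#: contralateral ear, then the normative audiogram.
DEFAULT_BASELINE_POLICY: tuple[BaselineKind, ...] = (
    BaselineKind.PREVIOUS,
    BaselineKind.CONTRALATERAL,
    BaselineKind.NORMATIVE,
)


@dataclass(frozen=True)
class InclusionCriteria:
    """The two audiological inclusion thresholds plus PTA/window configuration.

    ``min_severity_db`` and ``min_window_mean_difference_db`` are in dB HL /
    dB; zero disables the respective criterion. Variant designs (a single
    most affected frequency, a 3PTA, other frequency ranges) are expressed
    through ``window_size`` and ``pta_frequencies`` rather than separate
    code paths.
    """

    min_severity_db: float = 50.0
    min_window_mean_difference_db: float = 30.0
    pta_frequencies: tuple[float, ...] = PTA4_FREQUENCIES
    window_size: int = 3

    def __post_init__(self) -> None:
        if self.min_severity_db < 0 or self.min_window_mean_difference_db < 0:
            raise AudiometryError("criteria values must be >= 0 (0 disables)")
        if self.window_size < 1:
            raise AudiometryError("window_size must be >= 1")
        freqs = tuple(float(f) for f in self.pta_frequencies)
        if not freqs:
            raise AudiometryError("pta_frequencies must be non-empty")
        object.__setattr__(self, "pta_frequencies", freqs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "InclusionCriteria":
        return cls(
            min_severity_db=float(d.get("min_severity_db", 50.0)),
            min_window_mean_difference_db=float(d.get("min_window_mean_difference_db", 30.0)),
            pta_frequencies=tuple(float(f) for f in d.get("pta_frequencies_khz", PTA4_FREQUENCIES)),
            window_size=int(d.get("window_size", 3)),
        )

    def to_dict(self) -> dict:
        return {
            "min_severity_db": self.min_severity_db,
            "min_window_mean_difference_db": self.min_window_mean_difference_db,
            "pta_frequencies_khz": list(self.pta_frequencies),
            "window_size": self.window_size,
        }


@dataclass(frozen=True)
class GradingBand:
    grade_index: int
    label: str
    lower_db: float
    upper_db: float


@dataclass(frozen=True)
class GradingScale:
    """Named ordered list of PTA bands mapping severity to an impairment grade.

    Bands are ordered by their lower edge and jointly cover [-10, 120] dB HL.
    Because band edges are integers while PTAs are real, membership of a PTA
    is decided by the largest lower edge not exceeding it.
    """

    name: str
    bands: tuple[GradingBand, ...]

    def __post_init__(self) -> None:
        bands = tuple(sorted(self.bands, key=lambda b: b.lower_db))
        if not bands:
            raise AudiometryError(f"grading scale {self.name!r} has no bands")
        for a, b in zip(bands, bands[1:]):
            if b.lower_db <= a.lower_db or b.lower_db <= a.upper_db:
                raise AudiometryError(f"grading scale {self.name!r}: bands overlap or unordered")
        object.__setattr__(self, "bands", bands)

    def grade(self, pta_db: float) -> tuple[int, str]:
        """The (grade_index, label) of the band containing ``pta_db``."""
        if pta_db < -10.0 or pta_db > 120.0:
            raise AudiometryError(f"PTA {pta_db} dB HL outside [-10, 120]")
        chosen = self.bands[0]
        for band in self.bands:
            if pta_db >= band.lower_db:
                chosen = band
        return chosen.grade_index, chosen.label


def load_grading_scales(path: str | Path | None = None) -> dict[str, GradingScale]:
    """Load grading scales from a CSV resource (packaged WHO/EU by default)."""
    if path is None:
        ref = resources.files("audioscreen.data") / "grading_scales.csv"
        with resources.as_file(ref) as p:
            return load_grading_scales(p)
    by_scale: dict[str, list[GradingBand]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(line for line in fh if not line.lstrip().startswith("#"))
        for row in reader:
            by_scale.setdefault(row["scale"], []).append(
                GradingBand(
                    grade_index=int(row["grade_index"]),
                    label=row["label"],
                    lower_db=float(row["lower_db"]),
                    upper_db=float(row["upper_db"]),
                )
            )
    return {name: GradingScale(name, tuple(bands)) for name, bands in by_scale.items()}


def grade(pta_db: float, scale: GradingScale) -> tuple[int, str]:
    """Impairment grade of a pure-tone average under ``scale``."""
    return scale.grade(pta_db)


@dataclass(frozen=True)
class WindowResult:
    """Mean acute-minus-baseline difference over one consecutive-frequency window."""

    frequencies: tuple[float, ...]
    complete: bool
    mean_difference: float | None = None

    @property
    def window(self) -> tuple[float, float]:
        return (self.frequencies[0], self.frequencies[-1])

    @property
    def label(self) -> str:
        lo, hi = self.window
        return f"{format_frequency(lo)}-{format_frequency(hi)} kHz"


@dataclass(frozen=True)
class BaselineComparison:
    """Acute-vs-one-baseline evaluation of the difference criterion."""

    baseline_kind: BaselineKind
    computable: bool
    windows: tuple[WindowResult, ...] = ()
    max_window: WindowResult | None = None
    qualifying_windows: tuple[WindowResult, ...] = ()
    difference_criterion_met: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class EligibilityReport:
    """Per-patient evaluation: severity, grading, per-baseline comparisons."""

    patient_id: str | None
    data_check: DataCheckResult
    severity_4pta: float | None
    severity_criterion_met: bool
    grades: Mapping[str, Mapping[str, tuple[int, str]]]
    comparisons: tuple[BaselineComparison, ...]
    recommendations: Mapping[BaselineKind, Recommendation]


def difference_series(acute: Audiogram, baseline: Audiogram) -> dict[float, float]:
    """Per-frequency acute minus baseline threshold, on shared frequencies.

    Positive values mean incident-related worsening. An empty intersection
    yields an empty dict (flagged not-computable downstream, never raised).
    """
    shared = sorted(set(acute.thresholds) & set(baseline.thresholds))
    return {f: acute.thresholds[f] - baseline.thresholds[f] for f in shared}


def window_means(
    series: Mapping[float, float],
    grid: Sequence[float] = CANONICAL_GRID,
    window_size: int = 3,
) -> list[WindowResult]:
    """One :class:`WindowResult` per run of consecutive grid frequencies.

    A window is complete (and has a mean) iff every member frequency is
    present in ``series``. A window size exceeding the grid yields an empty
    list.
    """
    out: list[WindowResult] = []
    for freqs in grid_windows(grid, window_size):
        if all(f in series for f in freqs):
            mean = sum(series[f] for f in freqs) / len(freqs)
            out.append(WindowResult(freqs, complete=True, mean_difference=mean))
        else:
            out.append(WindowResult(freqs, complete=False))
    return out


def max_window(windows: Iterable[WindowResult]) -> WindowResult | None:
    """The complete window with the largest mean difference.

    Ties break toward the window with the lowest first frequency; ``None``
    if no window is complete.
    """
    best: WindowResult | None = None
    for w in windows:
        if not w.complete:
            continue
        if best is None or w.mean_difference > best.mean_difference:
            best = w
    return best


def _compare_baseline(
    kind: BaselineKind,
    acute: Audiogram,
    baseline: Audiogram | None,
    criteria: InclusionCriteria,
    reason_if_missing: str,
) -> BaselineComparison:
    disabled = criteria.min_window_mean_difference_db == 0
    if baseline is None:
        return BaselineComparison(
            kind, computable=False, difference_criterion_met=disabled, reason=reason_if_missing
        )
    series = difference_series(acute, baseline)
    windows = tuple(window_means(series, CANONICAL_GRID, criteria.window_size))
    best = max_window(windows)
    if best is None:
        return BaselineComparison(
            kind,
            computable=False,
            windows=windows,
            difference_criterion_met=disabled,
            reason="no complete window of shared frequencies",
        )
    qualifying = tuple(
        w
        for w in windows
        if w.complete and w.mean_difference >= criteria.min_window_mean_difference_db
    )
    met = disabled or best.mean_difference >= criteria.min_window_mean_difference_db
    return BaselineComparison(
        kind,
        computable=True,
        windows=windows,
        max_window=best,
        qualifying_windows=qualifying,
        difference_criterion_met=met,
    )


def evaluate(
    record: PatientRecord,
    criteria: InclusionCriteria | None = None,
    scales: Mapping[str, GradingScale] | None = None,
    table: Iso7029CoefficientTable | None = None,
) -> EligibilityReport:
    """Evaluate both inclusion criteria for one patient.

    A positive recommendation for a baseline requires the severity criterion
    and that baseline's difference criterion to both be met; a criterion set
    to zero always passes. Baselines that cannot be compared (missing
    audiogram, unspecified sex for the normative variant, no shared window)
    are labelled not computable rather than raising.
    """
    if criteria is None:
        criteria = InclusionCriteria()
    if scales is None:
        scales = load_grading_scales()
    if table is None:
        table = load_default_table()

    check = data_check(record, criteria)

    severity: float | None = None
    try:
        severity = pure_tone_average(record.acute, criteria.pta_frequencies)
    except AudiometryError:
        severity = None
    severity_met = severity is not None and (
        criteria.min_severity_db == 0 or severity >= criteria.min_severity_db
    )

    normative: Audiogram | None = None
    normative_reason = "normative baseline not requested"
    if record.sex in (Sex.FEMALE, Sex.MALE) and record.age is not None:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            normative = normative_audiogram(record.age, record.sex, CANONICAL_GRID, table)
    else:
        normative_reason = "age and sex required for the normative baseline"

    comparisons = (
        _compare_baseline(
            BaselineKind.PREVIOUS,
            record.acute,
            record.baseline_previous,
            criteria,
            "no previous audiogram of the affected ear",
        ),
        _compare_baseline(
            BaselineKind.CONTRALATERAL,
            record.acute,
            record.baseline_contralateral,
            criteria,
            "no contralateral-ear audiogram",
        ),
        _compare_baseline(
            BaselineKind.NORMATIVE, record.acute, normative, criteria, normative_reason
        ),
    )

    # Advisory grading of every available audiogram's own PTA (better-ear
    # assumption may not hold for the affected ear).
    audiograms: dict[str, Audiogram] = {"acute": record.acute}
    if record.baseline_previous is not None:
        audiograms["baseline_previous"] = record.baseline_previous
    if record.baseline_contralateral is not None:
        audiograms["baseline_contralateral"] = record.baseline_contralateral
    if normative is not None:
        audiograms["normative"] = normative
    grades: dict[str, dict[str, tuple[int, str]]] = {}
    for scale_name, scale in scales.items():
        per_audiogram: dict[str, tuple[int, str]] = {}
        for role, ag in audiograms.items():
            try:
                per_audiogram[role] = scale.grade(pure_tone_average(ag, criteria.pta_frequencies))
            except AudiometryError:
                continue
        grades[scale_name] = per_audiogram

    recommendations: dict[BaselineKind, Recommendation] = {}
    for comp in comparisons:
        if not check.valid or severity is None or not comp.computable:
            recommendations[comp.baseline_kind] = Recommendation.NOT_COMPUTABLE
        elif severity_met and comp.difference_criterion_met:
            recommendations[comp.baseline_kind] = Recommendation.INCLUDE
        else:
            recommendations[comp.baseline_kind] = Recommendation.EXCLUDE

    return EligibilityReport(
        patient_id=record.id,
        data_check=check,
        severity_4pta=severity,
        severity_criterion_met=severity_met,
        grades=grades,
        comparisons=comparisons,
        recommendations=recommendations,
    )


@dataclass(frozen=True)
class RecruitmentRate:
    eligible_count: int
    total: int

    @property
    def rate(self) -> float | None:
        """Eligible fraction; ``None`` (undefined) for an empty cohort."""
        return self.eligible_count / self.total if self.total else None


def is_eligible(
    report: EligibilityReport,
    baseline_policy: Sequence[BaselineKind] = DEFAULT_BASELINE_POLICY,
) -> bool:
    """Eligibility under a baseline preference order.

    The decision of the first baseline in ``baseline_policy`` whose
    comparison is computable is taken; a patient with no computable baseline
    is not eligible.
    """
    by_kind = {c.baseline_kind: c for c in report.comparisons}
    for kind in baseline_policy:
        comp = by_kind.get(BaselineKind(kind))
        if comp is not None and comp.computable:
            return report.recommendations[comp.baseline_kind] is Recommendation.INCLUDE
    return False


def recruitment_rate(
    reports: Sequence[EligibilityReport],
    baseline_policy: Sequence[BaselineKind] = DEFAULT_BASELINE_POLICY,
) -> RecruitmentRate:
    """Cohort recruitment estimate: eligible count, total, eligible fraction."""
    eligible = sum(is_eligible(r, baseline_policy) for r in reports)
    return RecruitmentRate(eligible_count=eligible, total=len(reports))
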