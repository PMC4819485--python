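"""Synthetic cohort generation with ground-truth eligibility labels.

Emulates a screening population for sudden-hearing-loss trials: each patient
gets a pre-incident baseline audiogram near their ISO 7029 age/sex norm
(plus Gaussian measurement noise), and an acute audiogram built by adding an
incident hearing loss of configurable magnitude over a contiguous frequency
region. The contralateral ear carries the same pre-incident baseline
(symmetric hearing before the incident), and a configurable fraction of
patients additionally have a previous audiogram of the affected ear.

When a target eligible fraction is set, incident magnitudes are placed on
the correct side of the inclusion criteria so every record's eligibility
label is exact by construction — the decision engine must agree patient by
patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    Audiogram,
    AudiogramRole,
    AudiometryError,
    CANONICAL_GRID,
    DB_MIN,
    DUMMY_CUTOFF,
    Ear,
    PatientRecord,
    Sex,
)
from .eligibility import InclusionCriteria
from .iso7029 import Iso7029CoefficientTable, load_default_table, normative_audiogram


class InfeasibleTargetError(AudiometryError):
    """The requested eligible fraction cannot be realised under the criteria."""


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-condition parameters of the generator.

    ``incident_region`` is a contiguous (low, high) kHz span of the canonical
    grid over which the incident loss is applied; ``baseline_noise_sd`` is
    the per-frequency Gaussian measurement noise (dB) of measured baselines
    around the ISO 7029 norm. Identical spec + seed yields an identical
    cohort.
    """

    n: int = 100
    seed: int = 0
    age_range: tuple[int, int] = (18, 80)
    sex_mix: float = 0.5
    baseline_noise_sd: float = 5.0
    incident_magnitude_range: tuple[float, float] = (10.0, 80.0)
    incident_region: tuple[float, float] = (0.5, 4.0)
    fraction_with_previous_audiogram: float = 0.3
    target_eligible_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise AudiometryError("n must be >= 0")
        if not 0 <= self.sex_mix <= 1:
            raise AudiometryError("sex_mix must be a fraction in [0, 1]")
        if not 0 <= self.fraction_with_previous_audiogram <= 1:
            raise AudiometryError("fraction_with_previous_audiogram must be in [0, 1]")
        if self.baseline_noise_sd < 0:
            raise AudiometryError("baseline_noise_sd must be >= 0")
        if self.target_eligible_fraction is not None and not (
            0 <= self.target_eligible_fraction <= 1
        ):
            raise AudiometryError("target_eligible_fraction must be in [0, 1]")

    @property
    def region_frequencies(self) -> tuple[float, ...]:
        lo, hi = self.incident_region
        freqs = tuple(f for f in CANONICAL_GRID if lo <= f <= hi)
        if not freqs:
            raise AudiometryError(
                f"incident_region {self.incident_region} covers no canonical frequency"
            )
        return freqs


def _clip(value: float) -> float:
    # keep generated thresholds out of the (115, 120) dummy gap
    return float(min(max(value, DB_MIN), DUMMY_CUTOFF))


def _constructed_label(
    acute: dict[float, float], baseline: dict[float, float], criteria: InclusionCriteria
) -> bool:
    """Ground-truth eligibility computed directly from the generated thresholds."""
    pta = sum(acute[f] for f in criteria.pta_frequencies) / len(criteria.pta_frequencies)
    sev_ok = criteria.min_severity_db == 0 or pta >= criteria.min_severity_db
    if criteria.min_window_mean_difference_db == 0:
        return bool(sev_ok)
    diffs = [acute[f] - baseline[f] for f in CANONICAL_GRID]
    k = criteria.window_size
    best = max(
        (sum(diffs[j : j + k]) / k for j in range(len(diffs) - k + 1)), default=None
    )
    return bool(sev_ok and best is not None and best >= criteria.min_window_mean_difference_db)


def generate_synthetic_cohort(
    spec: SyntheticCohortSpec,
    criteria: InclusionCriteria | None = None,
    table: Iso7029CoefficientTable | None = None,
) -> tuple[list[PatientRecord], list[bool]]:
    """Generate patient records plus ground-truth eligibility labels.

    Without a target fraction, incident magnitudes are drawn uniformly from
    ``incident_magnitude_range`` and labels are derived from the construction
    (the magnitude relative to the criteria). With a target fraction set,
    exactly ``round(n * target)`` records are made eligible by choosing
    magnitudes that satisfy (or fail) both criteria with certainty.
    """
    if criteria is None:
        criteria = InclusionCriteria()
    if table is None:
        table = load_default_table()

    region = spec.region_frequencies
    if spec.target_eligible_fraction is not None:
        if criteria.min_severity_db == 0 and criteria.min_window_mean_difference_db == 0:
            if spec.target_eligible_fraction < 1:
                raise InfeasibleTargetError(
                    "both criteria disabled: every valid record is eligible, "
                    f"target {spec.target_eligible_fraction} < 1 is infeasible"
                )
        missing_pta = [f for f in criteria.pta_frequencies if f not in region]
        if criteria.min_severity_db > 0 and missing_pta:
            raise InfeasibleTargetError(
                "incident_region must cover every PTA frequency to control severity; "
                f"missing {missing_pta}"
            )
        if criteria.min_window_mean_difference_db > 0 and len(region) < criteria.window_size:
            raise InfeasibleTargetError(
                f"incident_region spans {len(region)} grid frequencies; "
                f"window_size {criteria.window_size} cannot fit"
            )

    # Worst-case incident magnitude an eligible record may need: the window
    # criterion, or lifting the lowest possible PTA (-10 dB HL) to the
    # severity minimum. Capping region baselines at DUMMY_CUTOFF - need_bound
    # guarantees the incident is never truncated by the ceiling, which keeps
    # target-mode labels exact.
    need_bound = max(
        criteria.min_window_mean_difference_db, criteria.min_severity_db - DB_MIN, 0.0
    )
    if spec.target_eligible_fraction is not None and DUMMY_CUTOFF - need_bound < DB_MIN:
        raise InfeasibleTargetError(
            f"criteria {criteria.min_severity_db}/{criteria.min_window_mean_difference_db} "
            "dB cannot be satisfied within the measurable threshold range"
        )

    rng = np.random.default_rng(spec.seed)
    n = spec.n

    eligible_flags = np.zeros(n, dtype=bool)
    if spec.target_eligible_fraction is not None:
        n_eligible = int(round(n * spec.target_eligible_fraction))
        idx = rng.permutation(n)[:n_eligible]
        eligible_flags[idx] = True

    records: list[PatientRecord] = []
    labels: list[bool] = []
    lo_mag, hi_mag = spec.incident_magnitude_range
    for i in range(n):
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        sex = Sex.FEMALE if rng.random() < spec.sex_mix else Sex.MALE
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = normative_audiogram(age, sex, CANONICAL_GRID, table)
        noise = rng.normal(0.0, spec.baseline_noise_sd, size=len(CANONICAL_GRID))
        baseline = {
            f: _clip(norm.thresholds[f] + e) for f, e in zip(CANONICAL_GRID, noise)
        }

        if spec.target_eligible_fraction is None:
            magnitude = float(rng.uniform(lo_mag, hi_mag))
        elif eligible_flags[i]:
            # Both criteria must hold with certainty: window means fully inside
            # the region equal the magnitude, and the acute PTA is the baseline
            # PTA plus the magnitude (no ceiling truncation after the cap).
            cap = DUMMY_CUTOFF - need_bound
            for f in region:
                baseline[f] = min(baseline[f], cap)
            base_pta = float(np.mean([baseline[f] for f in criteria.pta_frequencies]))
            need = max(
                criteria.min_window_mean_difference_db,
                criteria.min_severity_db - base_pta,
                0.0,
            )
            headroom = DUMMY_CUTOFF - max(baseline[f] for f in region) - need
            magnitude = need + float(rng.uniform(0.0, max(min(20.0, headroom), 0.0)))
        else:
            # Fail with certainty: undershoot the difference criterion if it is
            # active, otherwise keep the acute PTA below the severity minimum.
            if criteria.min_window_mean_difference_db > 0:
                magnitude = float(
                    rng.uniform(0.0, max(criteria.min_window_mean_difference_db - 1.0, 0.0))
                )
            else:
                for f in criteria.pta_frequencies:
                    baseline[f] = min(baseline[f], criteria.min_severity_db - 10.0)
                base_pta = float(np.mean([baseline[f] for f in criteria.pta_frequencies]))
                gap = criteria.min_severity_db - base_pta
                magnitude = float(rng.uniform(0.0, max(gap - 1.0, 0.0)))

        acute = dict(baseline)
        for f in region:
            acute[f] = _clip(baseline[f] + magnitude)

        acute_ag = Audiogram(acute, ear=Ear.AFFECTED, role=AudiogramRole.ACUTE)
        contra_ag = Audiogram(
            baseline, ear=Ear.CONTRALATERAL, role=AudiogramRole.BASELINE_CONTRALATERAL
        )
        prev_ag = None
        if rng.random() < spec.fraction_with_previous_audiogram:
            prev_ag = Audiogram(
                baseline, ear=Ear.AFFECTED, role=AudiogramRole.BASELINE_PREVIOUS
            )

        records.append(
            PatientRecord(
                acute=acute_ag,
                id=f"SYN{i:04d}",
                age=age,
                sex=sex,
                baseline_previous=prev_ag,
                baseline_contralateral=contra_ag,
            )
        )

        if spec.target_eligible_fraction is not None:
            labels.append(bool(eligible_flags[i]))
        else:
            labels.append(_constructed_label(acute, baseline, criteria))

    return records, labels
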