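"""Audiogram data model, validity checking, dummy coding and pure-tone averages.

Thresholds are air-conduction hearing levels in dB HL (decibels relative to the
median threshold of otologically normal young adults). An audiogram is an
ordered map from test frequency (kHz) to threshold. Thresholds that could not
be measured because the audiometer's output limit was reached ("no response")
are dummy coded with a fixed ceiling value so that averages and differences
remain computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

#: Canonical audiometric frequency grid in kHz. Window construction for the
#: consecutive-frequency criterion runs over this grid; off-grid frequencies
#: are accepted in input but excluded from windows.
CANONICAL_GRID: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)

#: Default frequencies of the four-frequency pure-tone average (4PTA).
PTA4_FREQUENCIES: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)

#: Plausible threshold range in dB HL.
DB_MIN: float = -10.0
DB_MAX: float = 120.0

#: Thresholds strictly above this value are dummy coded.
DUMMY_CUTOFF: float = 115.0
#: Replacement value for unmeasurable / no-response thresholds.
DUMMY_VALUE: float = 120.0

#: Sentinel for "no response at the audiometer's limit". Maps to DUMMY_VALUE.
NO_RESPONSE: float = math.inf


class Ear(str, Enum):
    AFFECTED = "affected"
    CONTRALATERAL = "contralateral"
    UNSPECIFIED = "unspecified"


class AudiogramRole(str, Enum):
    ACUTE = "acute"
    BASELINE_PREVIOUS = "baseline_previous"
    BASELINE_CONTRALATERAL = "baseline_contralateral"
    NORMATIVE = "normative"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNSPECIFIED = "unspecified"


class AudiometryError(ValueError):
    """Base class for validation errors raised by this package."""


class ThresholdRangeError(AudiometryError):
    """A threshold lies outside the plausible [-10, 120] dB HL range."""

    def __init__(self, frequency_khz: float, value: float):
        self.frequency_khz = frequency_khz
        self.value = value
        super().__init__(
            f"threshold {value} dB HL at {frequency_khz} kHz outside "
            f"[{DB_MIN}, {DB_MAX}] dB HL"
        )


class MissingFrequencyError(AudiometryError):
    """A required frequency is not measured in the audiogram."""

    def __init__(self, frequencies_khz: Sequence[float]):
        self.frequencies_khz = tuple(frequencies_khz)
        pretty = ", ".join(format_frequency(f) for f in self.frequencies_khz)
        super().__init__(f"frequencies not measured: {pretty} kHz")


def format_frequency(freq_khz: float) -> str:
    """Render a kHz frequency the way audiologists write it (0.5, 1, 8 ...)."""
    return f"{freq_khz:g}"


def is_canonical(freq_khz: float, *, tol: float = 1e-9) -> bool:
    """True if ``freq_khz`` lies on the canonical audiometric grid."""
    return any(abs(freq_khz - g) <= tol for g in CANONICAL_GRID)


def dummy_code(threshold: float, *, frequency_khz: float | None = None) -> float:
    """Apply the ceiling coding rule to one threshold.

    Thresholds above 115 dB HL, and the no-response sentinel, are replaced by
    120 dB HL; everything else passes through unchanged. Idempotent.

    Parameters
    ----------
    threshold
        Threshold in dB HL, or :data:`NO_RESPONSE`.
    frequency_khz
        Optional frequency used only to label validation errors.

    Raises
    ------
    ThresholdRangeError
        If the threshold is below -10 dB HL or above 120 dB HL (implausible).
    """
    if threshold is NO_RESPONSE or math.isinf(threshold):
        return DUMMY_VALUE
    if math.isnan(threshold):
        raise ThresholdRangeError(frequency_khz if frequency_khz is not None else math.nan, threshold)
    if threshold < DB_MIN or threshold > DB_MAX:
        raise ThresholdRangeError(frequency_khz if frequency_khz is not None else math.nan, threshold)
    if threshold > DUMMY_CUTOFF:
        return DUMMY_VALUE
    return float(threshold)


@dataclass(frozen=True)
class Audiogram:
    """One ear's pure-tone audiogram.

    Thresholds are dummy coded at construction, so a stored value never lies
    in the open interval (115, 120) dB HL. Frequencies are kept sorted
    ascending; duplicates are rejected.
    """

    thresholds: Mapping[float, float]
    ear: Ear = Ear.UNSPECIFIED
    role: AudiogramRole = AudiogramRole.ACUTE

    def __post_init__(self) -> None:
        coded: dict[float, float] = {}
        for freq in sorted(self.thresholds):
            f = float(freq)
            if f <= 0:
                raise AudiometryError(f"frequency must be positive, got {freq} kHz")
            if f in coded:
                raise AudiometryError(f"duplicate frequency {format_frequency(f)} kHz")
            coded[f] = dummy_code(float(self.thresholds[freq]), frequency_khz=f)
        object.__setattr__(self, "thresholds", coded)
        if not isinstance(self.ear, Ear):
            object.__setattr__(self, "ear", Ear(self.ear))
        if not isinstance(self.role, AudiogramRole):
            object.__setattr__(self, "role", AudiogramRole(self.role))

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(self.thresholds)

    @property
    def off_grid_frequencies(self) -> tuple[float, ...]:
        """Measured frequencies that are not on the canonical grid."""
        return tuple(f for f in self.thresholds if not is_canonical(f))

    def __contains__(self, freq_khz: float) -> bool:
        return float(freq_khz) in self.thresholds

    def __getitem__(self, freq_khz: float) -> float:
        return self.thresholds[float(freq_khz)]

    def shifted(self, delta_db: float) -> "Audiogram":
        """A copy with ``delta_db`` added to every threshold (re-coded)."""
        return Audiogram(
            {f: min(max(t + delta_db, DB_MIN), DB_MAX) for f, t in self.thresholds.items()},
            ear=self.ear,
            role=self.role,
        )


@dataclass(frozen=True)
class PatientRecord:
    """Demographics plus the acute audiogram and optional measured baselines."""

    acute: Audiogram
    id: str | None = None
    age: int | None = None
    sex: Sex = Sex.UNSPECIFIED
    baseline_previous: Audiogram | None = None
    baseline_contralateral: Audiogram | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex(self.sex))
        if self.age is not None and self.age < 0:
            raise AudiometryError(f"age must be non-negative, got {self.age}")

    @property
    def measured_baselines(self) -> dict[str, Audiogram]:
        out: dict[str, Audiogram] = {}
        if self.baseline_previous is not None:
            out["previous"] = self.baseline_previous
        if self.baseline_contralateral is not None:
            out["contralateral"] = self.baseline_contralateral
        return out


@dataclass(frozen=True)
class DataCheckResult:
    """Outcome of the minimum-data validity check. valid iff no reasons."""

    reasons: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.reasons


def grid_windows(grid: Sequence[float], window_size: int) -> list[tuple[float, ...]]:
    """All runs of ``window_size`` consecutive frequencies on ``grid``."""
    if window_size < 1:
        raise AudiometryError(f"window_size must be >= 1, got {window_size}")
    g = list(grid)
    return [tuple(g[i : i + window_size]) for i in range(len(g) - window_size + 1)]


def pure_tone_average(
    audiogram: Audiogram, pta_frequencies: Iterable[float] = PTA4_FREQUENCIES
) -> float:
    """Arithmetic mean of the (dummy-coded) thresholds at the given frequencies.

    Raises :class:`MissingFrequencyError` naming every absent frequency.
    """
    freqs = [float(f) for f in pta_frequencies]
    if not freqs:
        raise AudiometryError("pta_frequencies must be non-empty")
    missing = [f for f in freqs if f not in audiogram.thresholds]
    if missing:
        raise MissingFrequencyError(missing)
    return sum(audiogram.thresholds[f] for f in freqs) / len(freqs)


def data_check(record: PatientRecord, criteria) -> DataCheckResult:
    """Check that enough valid data points exist to evaluate both criteria.

    Valid requires (a) every PTA frequency named by the criteria is measured
    in the acute audiogram, and (b) for each measured baseline at least one
    full window of ``window_size`` consecutive canonical frequencies is
    measured in both the acute audiogram and that baseline. Failures are
    reported as human-readable reasons, never raised.
    """
    reasons: list[str] = []
    missing_pta = [f for f in criteria.pta_frequencies if float(f) not in record.acute.thresholds]
    if missing_pta:
        pretty = ", ".join(format_frequency(float(f)) for f in missing_pta)
        reasons.append(f"acute audiogram missing PTA frequencies: {pretty} kHz")

    windows = grid_windows(CANONICAL_GRID, criteria.window_size)
    for kind, baseline in record.measured_baselines.items():
        shared = set(record.acute.thresholds) & set(baseline.thresholds)
        if not any(all(f in shared for f in w) for w in windows):
            reasons.append(
                f"no complete window of {criteria.window_size} consecutive "
                f"frequencies measured in both acute and {kind} baseline"
            )
    return DataCheckResult(tuple(reasons))
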