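"""Age- and sex-related normative (median) audiograms after ISO 7029.

ISO 7029 models the median hearing threshold of otologically normal persons
as a quadratic function of age: the median shift at a given frequency is

    shift(age, sex, f) = alpha(sex, f) * (age - 18)^2     for age >= 18,

where alpha is a per-sex, per-frequency coefficient in dB/year^2 and the
median threshold of 18-year-olds is 0 dB HL by definition of the dB HL
scale — so the shift *is* the normative median audiogram. Only the median
(50th percentile) is implemented; the standard's quantile spread is out of
scope here.

The coefficient table ships as a plain CSV resource inside the package and
can be overridden with a user-supplied file of the same layout.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .core import Audiogram, AudiogramRole, AudiometryError, CANONICAL_GRID, Ear, Sex, format_frequency

#: Reference age of the quadratic model (median shift is zero here).
REFERENCE_AGE: int = 18
#: Upper age bound of the standard's stated applicability; beyond it the
#: quadratic formula is extrapolated with a warning.
STANDARD_AGE_LIMIT: int = 70


class CoefficientMissingError(AudiometryError):
    """The coefficient table has no row for a requested (sex, frequency)."""

    def __init__(self, sex: Sex, frequencies_khz: Iterable[float]):
        self.sex = sex
        self.frequencies_khz = tuple(frequencies_khz)
        pretty = ", ".join(format_frequency(f) for f in self.frequencies_khz)
        super().__init__(f"no ISO 7029 coefficient for sex={sex.value} at {pretty} kHz")


class NormativeAgeWarning(UserWarning):
    """Requested age is outside the standard's stated applicability range."""


@dataclass(frozen=True)
class Iso7029CoefficientTable:
    """Map (sex, frequency kHz) -> alpha in dB/year^2, with provenance."""

    rows: dict[tuple[Sex, float], float]
    edition_label: str
    source: str

    def __post_init__(self) -> None:
        for (sex, freq), alpha in self.rows.items():
            if alpha < 0:
                raise AudiometryError(
                    f"alpha must be non-negative, got {alpha} for {sex.value} @ {freq} kHz"
                )

    def alpha(self, sex: Sex, frequency_khz: float) -> float:
        try:
            return self.rows[(sex, float(frequency_khz))]
        except KeyError:
            raise CoefficientMissingError(sex, [float(frequency_khz)]) from None

    def frequencies(self, sex: Sex) -> tuple[float, ...]:
        return tuple(sorted(f for (s, f) in self.rows if s == sex))

    @classmethod
    def from_csv(cls, path: str | Path, *, source: str | None = None) -> "Iso7029CoefficientTable":
        rows: dict[tuple[Sex, float], float] = {}
        edition = ""
        with open(path, newline="") as fh:
            reader = csv.DictReader(line for line in fh if not line.lstrip().startswith("#"))
            for row in reader:
                sex = Sex(row["sex"].strip().lower())
                freq = float(row["frequency_khz"])
                rows[(sex, freq)] = float(row["alpha"])
                edition = row.get("edition_label", edition) or edition
        if not rows:
            raise AudiometryError(f"empty coefficient table: {path}")
        return cls(rows=rows, edition_label=edition, source=source or str(path))


def load_default_table() -> Iso7029CoefficientTable:
    """The coefficient table shipped with the package."""
    ref = resources.files("audioscreen.data") / "iso7029_median.csv"
    with resources.as_file(ref) as path:
        return Iso7029CoefficientTable.from_csv(path, source="packaged iso7029_median.csv")


def median_threshold_shift(
    age: float,
    sex: Sex | str,
    frequency_khz: float,
    table: Iso7029CoefficientTable | None = None,
) -> float:
    """Median age-related threshold shift in dB HL for one frequency.

    Returns ``alpha * (age - 18)^2`` for ages >= 18. Ages below 18 return 0
    with a :class:`NormativeAgeWarning`; ages above 70 extrapolate the
    quadratic, also with a warning. A missing coefficient raises
    :class:`CoefficientMissingError`, never a silent zero.
    """
    sex = Sex(sex)
    if sex is Sex.UNSPECIFIED:
        raise CoefficientMissingError(sex, [frequency_khz])
    if table is None:
        table = load_default_table()
    a = table.alpha(sex, frequency_khz)
    if age < REFERENCE_AGE:
        warnings.warn(
            f"age {age} below the reference age {REFERENCE_AGE}; normative shift set to 0",
            NormativeAgeWarning,
            stacklevel=2,
        )
        return 0.0
    if age > STANDARD_AGE_LIMIT:
        warnings.warn(
            f"age {age} above the standard's stated limit of {STANDARD_AGE_LIMIT}; "
            "quadratic model extrapolated",
            NormativeAgeWarning,
            stacklevel=2,
        )
    return a * (age - REFERENCE_AGE) ** 2


def normative_audiogram(
    age: float,
    sex: Sex | str,
    frequencies: Iterable[float] = CANONICAL_GRID,
    table: Iso7029CoefficientTable | None = None,
) -> Audiogram:
    """The normative median audiogram for the given age and sex.

    The threshold at each requested frequency is the median shift (the
    normative median for 18-year-olds being 0 dB HL); dummy coding is applied
    afterwards by the :class:`~audioscreen.core.Audiogram` constructor. A
    coefficient missing for any requested frequency raises a single error
    listing every uncovered frequency.
    """
    sex = Sex(sex)
    if table is None:
        table = load_default_table()
    freqs = [float(f) for f in frequencies]
    if sex is Sex.UNSPECIFIED:
        raise CoefficientMissingError(sex, freqs)
    covered = set(table.frequencies(sex))
    missing = [f for f in freqs if f not in covered]
    if missing:
        raise CoefficientMissingError(sex, missing)
    thresholds = {f: median_threshold_shift(age, sex, f, table) for f in freqs}
    return Audiogram(thresholds, ear=Ear.UNSPECIFIED, role=AudiogramRole.NORMATIVE)
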