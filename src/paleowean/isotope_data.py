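"""Collagen isotope data model: parsing, quality screening, age grouping, summaries.

The atom of every downstream analysis is a single individual's bone-collagen
measurement record: carbon and nitrogen isotope ratios (δ13C ‰ VPDB, δ15N ‰ AIR)
together with the elemental indicators (%C, %N, C/N atomic ratio, collagen
yield) used to screen for diagenetic alteration.  Juveniles carry a printed
age-at-death estimate ("1.5–3 months", "Perinatal", ...) which is parsed into a
decimal-year interval and binned into four age groups for the mixing analysis.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AgeInterval",
    "CollagenSample",
    "GroupSummary",
    "AgeParseError",
    "NonJuvenileAgeError",
    "QC_MIN_PCT_N",
    "QC_MIN_PCT_C",
    "QC_CN_RANGE",
    "AGE_GROUP_EDGES",
    "GROUP_LABELS",
    "parse_age_estimate",
    "age_midpoint",
    "qc_pass",
    "assign_age_group",
    "summarize_group",
    "summarize_values",
    "load_samples",
    "bundled_samples_path",
    "group_juveniles",
    "round_half_away",
]

# Collagen-preservation screen: minimum elemental concentrations and the
# accepted atomic C/N window for unaltered collagen.
QC_MIN_PCT_N = 4.8
QC_MIN_PCT_C = 13.0
QC_CN_RANGE = (2.9, 3.6)

# Age-group boundaries in years.  Bins are right-closed, (a, b], with age 0
# belonging to the first group: an individual aged exactly 1 year is counted
# with the 0.5–1-year group, matching the published group membership.
AGE_GROUP_EDGES = (0.0, 0.5, 1.0, 2.0, 6.0)
GROUP_LABELS = ("G1", "G2", "G3", "G4")
GROUP_DISPLAY = {
    "G1": "Group 1 (0-0.5 y)",
    "G2": "Group 2 (0.5-1 y)",
    "G3": "Group 3 (1-2 y)",
    "G4": "Group 4 (2-6 y)",
    "females": "Adult females",
}

REQUIRED_COLUMNS = (
    "sample_id",
    "cemetery",
    "cohort",
    "age_estimate",
    "age_low_years",
    "age_high_years",
    "d13C",
    "d15N",
    "pctC",
    "pctN",
    "cn_ratio",
    "collagen_yield",
)

_ADULT_LABELS = re.compile(
    r"^(young|full|mature|old)?\s*adult", re.IGNORECASE
)


class AgeParseError(ValueError):
    """Age-estimate string does not match any recognised pattern."""


class NonJuvenileAgeError(AgeParseError):
    """Age-estimate string is an adult life-stage label, not a juvenile age."""


@dataclass(frozen=True)
class AgeInterval:
    """Closed age interval in decimal years."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high):
            raise ValueError(f"invalid age interval [{self.low}, {self.high}]")

    @property
    def midpoint(self) -> float:
        return (self.low + self.high) / 2.0


@dataclass
class CollagenSample:
    """One individual's bone-collagen measurements plus age metadata."""

    sample_id: str
    cemetery: str  # "OC" (old cemetery) or "YC" (young cemetery)
    cohort: str  # "juvenile" or "adult_female"
    age_estimate: str
    d13C: float
    d15N: float
    pctC: float
    pctN: float
    cn_ratio: float
    collagen_yield: float
    age: AgeInterval | None = None

    def __post_init__(self) -> None:
        if self.cemetery not in ("OC", "YC"):
            raise ValueError(f"unknown cemetery {self.cemetery!r}")
        if self.cohort not in ("juvenile", "adult_female"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        for name in ("pctC", "pctN", "collagen_yield"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not self.cn_ratio > 0:
            raise ValueError(f"cn_ratio={self.cn_ratio} must be positive")


@dataclass
class GroupSummary:
    """Per-group descriptive statistics for both isotopes.

    ``sd_*`` is the sample standard deviation (n − 1 denominator) and is
    ``None`` for singleton groups, where it is undefined.
    """

    group_label: str
    n: int
    mean_d15N: float
    sd_d15N: float | None
    min_d15N: float
    max_d15N: float
    mean_d13C: float
    sd_d13C: float | None
    min_d13C: float
    max_d13C: float

    def rounded(self, ndigits: int = 2) -> "GroupSummary":
        """Copy with every statistic rounded half away from zero."""
        def r(v):
            return None if v is None else round_half_away(v, ndigits)

        return GroupSummary(
            self.group_label, self.n,
            r(self.mean_d15N), r(self.sd_d15N), r(self.min_d15N), r(self.max_d15N),
            r(self.mean_d13C), r(self.sd_d13C), r(self.min_d13C), r(self.max_d13C),
        )


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


_DASH = re.compile(r"[–—-]")  # en/em dash or hyphen
_UNIT = r"(months?|mo\.?|years?|yrs?\.?|y)"


def _unit_years(token: str) -> float:
    return 1.0 / 12.0 if token.lower().startswith(("month", "mo")) else 1.0


def parse_age_estimate(text: str) -> AgeInterval:
    """Parse a printed juvenile age estimate into an interval of decimal years.

    Recognised forms: ranges with a trailing unit ("1.5–3 months",
    "3–3.5 years"), mixed-unit ranges ("10 months–1 year"), single values
    ("1 year", "3.5 years"), "Birth-X months/years" and "Perinatal".
    "Birth" and "Perinatal" map to age 0 (degenerate interval for the latter).

    Raises :class:`NonJuvenileAgeError` for adult life-stage labels and
    :class:`AgeParseError` for anything else unrecognised.
    """
    s = text.strip()
    if _ADULT_LABELS.match(s):
        raise NonJuvenileAgeError(f"adult life-stage label, not a juvenile age: {text!r}")
    if s.lower() in ("perinatal", "birth"):
        return AgeInterval(0.0, 0.0)

    parts = [p.strip() for p in _DASH.split(s)]
    num = r"(\d+(?:\.\d+)?)"

    if len(parts) == 2:
        lo_txt, hi_txt = parts
        m_hi = re.match(rf"^{num}\s*{_UNIT}$", hi_txt, re.IGNORECASE)
        if m_hi is None:
            raise AgeParseError(f"unparseable age estimate: {text!r}")
        hi = float(m_hi.group(1)) * _unit_years(m_hi.group(2))
        if lo_txt.lower() == "birth":
            lo = 0.0
        else:
            m_lo = re.match(rf"^{num}\s*{_UNIT}?$", lo_txt, re.IGNORECASE)
            if m_lo is None:
                raise AgeParseError(f"unparseable age estimate: {text!r}")
            unit = m_lo.group(2) or m_hi.group(2)  # bare lower bound shares the upper unit
            lo = float(m_lo.group(1)) * _unit_years(unit)
        if lo > hi:
            raise AgeParseError(f"inverted age range: {text!r}")
        return AgeInterval(lo, hi)

    if len(parts) == 1:
        m = re.match(rf"^{num}\s*{_UNIT}$", parts[0], re.IGNORECASE)
        if m is not None:
            v = float(m.group(1)) * _unit_years(m.group(2))
            return AgeInterval(v, v)

    raise AgeParseError(f"unparseable age estimate: {text!r}")


def age_midpoint(interval: AgeInterval) -> float:
    """Midpoint of an age interval, used to place individuals on the age axis."""
    return interval.midpoint


def qc_pass(sample: CollagenSample) -> tuple[bool, list[str]]:
    """Collagen-preservation screen.

    Passes iff %N ≥ 4.8, %C ≥ 13 and the atomic C/N ratio lies in [2.9, 3.6]
    (bounds inclusive).  Returns the verdict together with the list of
    violated rules so failures can be reported or overridden individually.
    """
    violations: list[str] = []
    if sample.pctN < QC_MIN_PCT_N:
        violations.append(f"pctN {sample.pctN} < {QC_MIN_PCT_N}")
    if sample.pctC < QC_MIN_PCT_C:
        violations.append(f"pctC {sample.pctC} < {QC_MIN_PCT_C}")
    lo, hi = QC_CN_RANGE
    if not (lo <= sample.cn_ratio <= hi):
        violations.append(f"cn_ratio {sample.cn_ratio} outside [{lo}, {hi}]")
    return (not violations, violations)


def assign_age_group(interval: AgeInterval) -> str:
    """Assign a juvenile to one of the four age groups by interval midpoint.

    Bins are right-closed, (0, 0.5], (0.5, 1], (1, 2], (2, 6], with age 0 in
    the first group, so a midpoint of exactly 1 year falls in the 0.5–1-year
    group — the convention implied by the published group membership.
    """
    mid = interval.midpoint
    if mid > AGE_GROUP_EDGES[-1]:
        raise ValueError(f"age midpoint {mid} y outside the 0-6 y study range")
    for label, hi in zip(GROUP_LABELS, AGE_GROUP_EDGES[1:]):
        if mid <= hi:
            return label
    raise AssertionError("unreachable")


def summarize_values(values: Sequence[float]) -> tuple[float, float | None, float, float]:
    """(mean, sample SD or None if n < 2, min, max) of a nonempty sequence."""
    if len(values) == 0:
        raise ValueError("cannot summarize an empty sequence")
    s = pd.Series(list(values), dtype=float)
    sd = float(s.std(ddof=1)) if len(s) >= 2 else None
    return float(s.mean()), sd, float(s.min()), float(s.max())


def summarize_group(samples: Sequence[CollagenSample], group_label: str = "") -> GroupSummary:
    """Descriptive isotope statistics for one group of individuals."""
    if not samples:
        raise ValueError("cannot summarize an empty group")
    m_n, s_n, lo_n, hi_n = summarize_values([s.d15N for s in samples])
    m_c, s_c, lo_c, hi_c = summarize_values([s.d13C for s in samples])
    return GroupSummary(group_label, len(samples), m_n, s_n, lo_n, hi_n, m_c, s_c, lo_c, hi_c)


def bundled_samples_path() -> Path:
    """Path to the bundled Canímar Abajo collagen table (49 individuals)."""
    return Path(str(resources.files("paleowean").joinpath("data/canimar_abajo_collagen.tsv")))


def load_samples(path: str | Path, sep: str = "\t") -> list[CollagenSample]:
    """Load collagen samples from a delimiter-separated table.

    Juvenile rows with blank ``age_low_years``/``age_high_years`` get their age
    interval parsed from the printed ``age_estimate`` string.  Malformed rows
    are skipped with a warning naming the row number; missing required columns
    raise immediately.
    """
    df = pd.read_csv(path, sep=sep, dtype={"age_estimate": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []

    samples: list[CollagenSample] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based file line, after the header
        try:
            age: AgeInterval | None = None
            if row["cohort"] == "juvenile":
                if pd.notna(row["age_low_years"]) and pd.notna(row["age_high_years"]):
                    age = AgeInterval(float(row["age_low_years"]), float(row["age_high_years"]))
                else:
                    age = parse_age_estimate(str(row["age_estimate"]))
            samples.append(
                CollagenSample(
                    sample_id=str(row["sample_id"]),
                    cemetery=str(row["cemetery"]),
                    cohort=str(row["cohort"]),
                    age_estimate=str(row["age_estimate"]),
                    d13C=float(row["d13C"]),
                    d15N=float(row["d15N"]),
                    pctC=float(row["pctC"]),
                    pctN=float(row["pctN"]),
                    cn_ratio=float(row["cn_ratio"]),
                    collagen_yield=float(row["collagen_yield"]),
                    age=age,
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path}: skipping malformed row {rowno}: {exc}", stacklevel=2)
    return samples


def group_juveniles(samples: Iterable[CollagenSample]) -> dict[str, list[CollagenSample]]:
    """Partition samples into the four juvenile age groups plus ``females``."""
    groups: dict[str, list[CollagenSample]] = {g: [] for g in GROUP_LABELS}
    groups["females"] = []
    for s in samples:
        if s.cohort == "adult_female":
            groups["females"].append(s)
        else:
            if s.age is None:
                raise ValueError(f"juvenile {s.sample_id} has no age interval")
            groups[assign_age_group(s.age)].append(s)
    return groups
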