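"""Raw performance records and the per-age top-performance envelope.

Raw data are (age, performance) observations — many individuals per age —
recorded in the native time discretization of the species (years for
humans, months for thoroughbreds and greyhounds, weeks for mice and mouse
lemurs).  The object every model is fitted to is the *envelope*: the best
performance in each age bin, with all ages converted to years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "WEEKS_PER_YEAR",
    "MONTHS_PER_YEAR",
    "AGE_UNITS",
    "PerformanceRecord",
    "PerformanceSeries",
    "EnvelopeSeries",
    "convert_ages",
    "top_envelope",
    "upper_concave_hull",
    "read_series_csv",
    "read_envelope_csv",
]

#: Mean calendar year in weeks (365.25 / 7); the weeks-to-years divisor.
WEEKS_PER_YEAR = 52.1775
MONTHS_PER_YEAR = 12.0

AGE_UNITS = ("years", "months", "weeks")

_UNIT_TO_YEARS = {
    "years": 1.0,
    "months": 1.0 / MONTHS_PER_YEAR,
    "weeks": 1.0 / WEEKS_PER_YEAR,
}


@dataclass(frozen=True)
class PerformanceRecord:
    """One measured performance: age in the series' native unit, value in
    the series' native performance unit."""

    age: float
    value: float
    subject_id: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError(f"age must be finite and >= 0, got {self.age!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value!r}")


@dataclass
class PerformanceSeries:
    """A collection of records sharing one age unit and one value unit."""

    records: list[PerformanceRecord]
    age_unit: str = "years"
    value_unit: str = ""
    species: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a PerformanceSeries must contain at least one record")
        if self.age_unit not in AGE_UNITS:
            raise ValueError(f"unknown age unit {self.age_unit!r}; expected one of {AGE_UNITS}")

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=float)

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages(),
                "value": self.values(),
                "subject_id": [r.subject_id for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EnvelopeSeries:
    """Top performance per age bin — the fitting target.

    ``ages`` are bin centers converted to years, strictly increasing;
    ``values`` the per-bin maxima; ``n_per_bin`` the record counts behind
    each maximum.  ``provenance`` carries source-series metadata (units,
    species, bin width, simulation parameters...).
    """

    ages: np.ndarray
    values: np.ndarray
    n_per_bin: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_per_bin = np.asarray(self.n_per_bin, dtype=int)
        if self.ages.size == 0:
            raise ValueError("envelope must contain at least one bin")
        if not (self.ages.shape == self.values.shape == self.n_per_bin.shape):
            raise ValueError("ages, values and n_per_bin must have equal shapes")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("envelope ages must be strictly increasing")

    def __len__(self) -> int:
        return int(self.ages.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "value": self.values, "n_per_bin": self.n_per_bin}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def convert_ages(series: PerformanceSeries) -> PerformanceSeries:
    """Convert all record ages to years; performance values are untouched.

    Weeks divide by 52.1775 (365.25/7), months by 12.
    """
    if series.age_unit == "years":
        return series
    factor = _UNIT_TO_YEARS[series.age_unit]
    records = [replace(r, age=r.age * factor) for r in series.records]
    return PerformanceSeries(
        records=records,
        age_unit="years",
        value_unit=series.value_unit,
        species=series.species,
        trait=series.trait,
    )


def top_envelope(series: PerformanceSeries, bin_width: float = 1.0) -> EnvelopeSeries:
    """Per-age-bin maximum performance of a series.

    Records are grouped into half-open bins ``[k*w, (k+1)*w)`` of the
    series' native age unit (default width: one native unit — 1 year /
    1 month / 1 week).  Empty bins are omitted; each bin is reported at its
    center, converted to years.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ages = series.ages()
    values = series.values()
    bin_index = np.floor(ages / bin_width).astype(int)
    order = np.argsort(bin_index, kind="stable")
    bin_index, values_sorted = bin_index[order], values[order]
    uniq, start = np.unique(bin_index, return_index=True)
    tops = np.maximum.reduceat(values_sorted, start)
    counts = np.diff(np.concatenate([start, [bin_index.size]]))
    centers_native = (uniq + 0.5) * bin_width
    centers_years = centers_native * _UNIT_TO_YEARS[series.age_unit]
    return EnvelopeSeries(
        ages=centers_years,
        values=tops,
        n_per_bin=counts,
        provenance={
            "age_unit": series.age_unit,
            "value_unit": series.value_unit,
            "species": series.species,
            "trait": series.trait,
            "bin_width": bin_width,
        },
    )


def upper_concave_hull(env: EnvelopeSeries) -> EnvelopeSeries:
    """Optional post-process: restrict an envelope to its upper concave hull.

    Keeps only the bins lying on the upper convex hull of the (age, value)
    point set (Andrew's monotone chain).  Off by default in the pipeline —
    the fitting target is the plain per-bin maximum.
    """
    pts = list(zip(env.ages, env.values, env.n_per_bin, strict=True))
    hull: list[tuple[float, float, int]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1, _), (x2, y2, _) = hull[-2], hull[-1]
            if (x2 - x1) * (p[1] - y1) - (p[0] - x1) * (y2 - y1) >= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    ages, values, counts = zip(*hull, strict=True)
    return EnvelopeSeries(
        ages=np.array(ages),
        values=np.array(values),
        n_per_bin=np.array(counts),
        provenance={**env.provenance, "upper_concave_hull": True},
    )


class CSVFormatError(ValueError):
    """Malformed input CSV; message includes the offending line number."""


def read_series_csv(
    path: str | Path,
    age_unit: str = "years",
    value_unit: str = "",
    species: str = "",
    trait: str = "",
) -> PerformanceSeries:
    """Read raw records from CSV with columns ``age``, ``value`` and
    optional ``subject_id``, ``sex`` (header required, UTF-8, '.' decimal)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise CSVFormatError(f"{path}: file is empty") from None
    missing = {"age", "value"} - set(frame.columns)
    if missing:
        raise CSVFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if frame.empty:
        raise CSVFormatError(f"{path}: no data rows")
    for col in ("age", "value"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna()]
        if len(bad):
            # +2: 1-based lines plus the header row
            raise CSVFormatError(
                f"{path}: line {bad[0] + 2}: non-numeric {col!r} value {frame[col][bad[0]]!r}"
            )
        frame[col] = coerced
    records = [
        PerformanceRecord(
            age=float(row.age),
            value=float(row.value),
            subject_id=str(row.subject_id) if "subject_id" in frame.columns and pd.notna(row.subject_id) else None,
            sex=str(row.sex) if "sex" in frame.columns and pd.notna(row.sex) else None,
        )
        for row in frame.itertuples()
    ]
    return PerformanceSeries(records, age_unit=age_unit, value_unit=value_unit,
                             species=species, trait=trait)


def read_envelope_csv(path: str | Path) -> EnvelopeSeries:
    """Read an already-binned envelope (columns ``age``, ``value``,
    optional ``n_per_bin``; ages in years)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise CSVFormatError(f"{path}: file is empty") from None
    missing = {"age", "value"} - set(frame.columns)
    if missing:
        raise CSVFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    n = frame["n_per_bin"] if "n_per_bin" in frame.columns else np.ones(len(frame), dtype=int)
    return EnvelopeSeries(
        ages=frame["age"].to_numpy(dtype=float),
        values=frame["value"].to_numpy(dtype=float),
        n_per_bin=np.asarray(n, dtype=int),
        provenance={"source": str(path)},
    )
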