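"""Synthetic age-performance data and packaged reference parameter sets.

The original study fitted the top-performance envelope of 17 time series
(human track and field, weightlifting, chess, facial recognition,
greyhound and thoroughbred racing, mouse wheel running, mouse lemur grip
strength), none of which ship with deposited data.  This module packages
the published IMAP1 shape-parameter sets of those 17 series as fixtures
and generates synthetic datasets with the same structure, so every stage
of the pipeline is testable without downloads.

Two noise modes are provided:

* ``envelope_gaussian`` perturbs the model envelope directly with
  multiplicative Gaussian noise — quick, suited to parameter-recovery
  experiments;
* ``population_deficit`` generates ``n_per_age`` individual records per
  age bin, each at or below the model curve by a half-normal relative
  deficit — the extreme-value structure of ranking-style data, whose
  per-bin maximum converges to the model curve as the cohort grows.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .envelope import AGE_UNITS, EnvelopeSeries, PerformanceRecord, PerformanceSeries, _UNIT_TO_YEARS
from .models import DegeneratePeakError, IMAPShape, imap_reduced, peak_age

__all__ = [
    "SeriesFixture",
    "SimulationDesign",
    "fixture_names",
    "load_fixture",
    "load_all_fixtures",
    "simulate_envelope",
    "simulate_population",
]

#: Published IMAP1 peak ages are reproducible from the published shape
#: parameters only to within rounding of the 2-decimal printed values;
#: fixtures whose recomputed peak differs by more than this are flagged.
PEAK_CONSISTENCY_TOL = 0.15


@dataclass(frozen=True)
class SeriesFixture:
    """One of the 17 published series: shape parameters plus derived values.

    ``shape`` carries the published dimensionless parameters with
    ``scale_inf = 1`` (the published tables are scale-free);
    ``peak_consistent`` records whether the published IMAP1 peak age is
    reproduced from the published shape parameters to within
    ``PEAK_CONSISTENCY_TOL`` years — several printed rows are internally
    inconsistent (rounded parameters, ambiguous age units) and are flagged
    rather than asserted.
    """

    name: str
    species: str
    value_unit: str
    age_unit: str  # native discretization of the source data
    shape: IMAPShape
    tau_published: float
    peak_moore_published: float
    peak_imap1_published: float

    @property
    def peak_computed(self) -> float | None:
        """Peak age in years recomputed from the shape (None if degenerate)."""
        try:
            return peak_age(self.shape)
        except DegeneratePeakError:
            return None

    @property
    def peak_consistent(self) -> bool:
        peak = self.peak_computed
        if peak is None:
            return False
        return abs(peak - self.peak_imap1_published) <= PEAK_CONSISTENCY_TOL


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one synthetic dataset.

    ``age_grid`` is in ``age_unit`` (default years); ``n_per_age`` the
    cohort size per bin (population mode); ``noise_scale`` the relative
    standard deviation of the noise; ``seed`` makes the draw reproducible.
    """

    age_grid: np.ndarray
    n_per_age: int = 1
    noise_model: str = "envelope_gaussian"
    noise_scale: float = 0.01
    seed: int = 0
    age_unit: str = "years"

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_grid", np.asarray(self.age_grid, dtype=float))
        if self.age_grid.size == 0:
            raise ValueError("age_grid must be non-empty")
        if self.n_per_age < 1:
            raise ValueError("n_per_age must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_model not in ("envelope_gaussian", "population_deficit"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.age_unit not in AGE_UNITS:
            raise ValueError(f"unknown age unit {self.age_unit!r}")


@lru_cache(maxsize=1)
def _fixture_table() -> pd.DataFrame:
    with importlib.resources.files("ageperf").joinpath("data/fixtures.csv").open("r") as fh:
        return pd.read_csv(fh)


def fixture_names() -> list[str]:
    """Names of all packaged series, in published order."""
    return list(_fixture_table()["name"])


def load_fixture(name: str) -> SeriesFixture:
    """Load one packaged series by name (see :func:`fixture_names`)."""
    table = _fixture_table()
    match = table[table["name"] == name]
    if match.empty:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(fixture_names())}"
        )
    row = match.iloc[0]
    shape = IMAPShape(
        alpha0_star=float(row.alpha0_star),
        alphar_star=float(row.alphar_star),
        betar_star=float(row.betar_star),
        td=float(row.td_years),
        scale_inf=1.0,
    )
    return SeriesFixture(
        name=str(row["name"]),
        species=str(row.species),
        value_unit=str(row.value_unit),
        age_unit=str(row.age_unit),
        shape=shape,
        tau_published=float(row.tau_published),
        peak_moore_published=float(row.peak_moore_published),
        peak_imap1_published=float(row.peak_imap1_published),
    )


def load_all_fixtures() -> list[SeriesFixture]:
    return [load_fixture(name) for name in fixture_names()]


def _ages_in_years(design: SimulationDesign) -> np.ndarray:
    return design.age_grid * _UNIT_TO_YEARS[design.age_unit]


def simulate_envelope(shape: IMAPShape, design: SimulationDesign) -> EnvelopeSeries:
    """Synthetic envelope: the model curve with multiplicative Gaussian noise.

    ``value = scale_inf * x(t/td) * (1 + eps)`` with
    ``eps ~ Normal(0, noise_scale)`` redrawn where it would make the value
    non-positive.  Grid points at or beyond ``td`` are emitted as exact
    zeros and their indices flagged in the provenance.
    """
    rng = np.random.default_rng(design.seed)
    t_years = _ages_in_years(design)
    u = t_years / shape.td
    curve = shape.scale_inf * imap_reduced(u, shape)
    past_death = u >= 1.0
    eps = rng.normal(0.0, design.noise_scale, size=curve.size) if design.noise_scale > 0 else np.zeros(curve.size)
    # truncate the noise so live-age values stay positive
    for _ in range(100):
        bad = (~past_death) & (1.0 + eps <= 0.0)
        if not bad.any():
            break
        eps[bad] = rng.normal(0.0, design.noise_scale, size=int(bad.sum()))
    values = np.where(past_death, 0.0, curve * (1.0 + eps))
    return EnvelopeSeries(
        ages=t_years,
        values=values,
        n_per_bin=np.ones(curve.size, dtype=int),
        provenance={
            "synthetic": True,
            "noise_model": "envelope_gaussian",
            "noise_scale": design.noise_scale,
            "seed": design.seed,
            "shape": {n: float(v) for n, v in zip(IMAPShape.names, shape.as_array(), strict=True)},
            "flagged_past_death": np.flatnonzero(past_death).tolist(),
        },
    )


def simulate_population(shape: IMAPShape, design: SimulationDesign) -> PerformanceSeries:
    """Synthetic cohort: ``n_per_age`` individuals per bin, at or below the
    model curve.

    Each record's value is ``curve * (1 - |delta|)`` with
    ``delta ~ Normal(0, noise_scale)`` — a half-normal relative deficit, so
    the per-bin maximum (the envelope) is stochastically below the true
    curve and converges to it as ``n_per_age`` grows.  Record ages keep the
    design's native unit so the output feeds the envelope module
    unmodified.
    """
    if design.noise_model != "population_deficit":
        raise ValueError("simulate_population requires noise_model='population_deficit'")
    rng = np.random.default_rng(design.seed)
    t_years = _ages_in_years(design)
    u = t_years / shape.td
    curve = shape.scale_inf * imap_reduced(u, shape)
    records: list[PerformanceRecord] = []
    for age_native, c in zip(design.age_grid, curve, strict=True):
        deficits = np.abs(rng.normal(0.0, design.noise_scale, size=design.n_per_age))
        deficits = np.minimum(deficits, 1.0)  # performance cannot go below zero
        for value in c * (1.0 - deficits):
            records.append(PerformanceRecord(age=float(age_native), value=float(value)))
    return PerformanceSeries(
        records=records,
        age_unit=design.age_unit,
        value_unit="synthetic",
        species="synthetic",
        trait="synthetic",
    )
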