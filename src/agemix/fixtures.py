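"""Synthetic demography, life tables, contact matrices, and table I/O.

Real analyses draw age pyramids and life tables from published sources; the
generators here produce stylised stand-ins so the whole pipeline builds and
tests offline. Two demographic shapes are provided:

* ``rectangular`` — near-flat counts to retirement age with a logistic
  old-age taper, resembling many high-income-country (HIC) pyramids;
* ``young`` — counts decreasing with age (exponential decay), resembling
  many low- and middle-income-country (LMIC) pyramids.

Companion life tables give remaining life expectancy e(x) (higher at birth
for the rectangular/HIC shape) and a U-shaped all-cause mortality rate m(x)
(elevated infant and old-age mortality) that doubles as the flu-like IFR
shape. All generators are pure functions of their arguments and seed. Real
tables in the same CSV schemas can be loaded through ``load_table``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .partitions import FeatureFunction, Partition, interpolate_density
from .seir import ContactMatrix

__all__ = [
    "SyntheticDemography",
    "make_demography",
    "make_life_table",
    "make_contact_matrix",
    "load_table",
    "write_table",
    "DEMOGRAPHY_SHAPES",
]

DEMOGRAPHY_SHAPES = ("rectangular", "young")

#: Default total population for synthetic demographies.
DEFAULT_TOTAL_POPULATION = 1_000_000.0


@dataclass(frozen=True)
class SyntheticDemography:
    """Stylised age pyramid at 1-year resolution on [0, max_age]."""

    shape: str
    max_age: float
    table: pd.DataFrame  # columns: age, population (per year of age)

    @property
    def total(self) -> float:
        """Total population, the integral of the (linear) pyramid."""
        return float(
            np.trapezoid(self.table["population"], self.table["age"])
        )

    def density(self) -> FeatureFunction:
        """Normalised population density ρ(x) over age."""
        return interpolate_density(self.table)


def make_demography(
    shape: str,
    max_age: float = 101.0,
    total_population: float = DEFAULT_TOTAL_POPULATION,
    seed: int = 0,
) -> SyntheticDemography:
    """Generate a stylised age pyramid, deterministic given the seed."""
    if shape not in DEMOGRAPHY_SHAPES:
        raise ValueError(f"unknown demography shape {shape!r}; "
                         f"choose from {DEMOGRAPHY_SHAPES}")
    if max_age <= 1 or total_population <= 0:
        raise ValueError("max_age must exceed 1 and total_population be positive")
    rng = np.random.default_rng(seed)
    ages = np.arange(0.0, max_age + 0.5, 1.0)
    if ages[-1] != max_age:
        ages = np.append(ages, max_age)
    if shape == "rectangular":
        # flat cohorts with mild seeded ripple, logistic taper above ~70
        base = 1.0 + 0.02 * rng.standard_normal(ages.size)
        taper = 1.0 / (1.0 + np.exp((ages - 85.0) / 5.0))
        counts = np.clip(base, 0.5, None) * (0.02 + 0.98 * taper)
    else:
        # strictly decreasing exponential decay; the seed perturbs the rate
        rate = 30.0 + rng.uniform(-3.0, 3.0)
        counts = np.exp(-ages / rate)
    counts = counts * (total_population / np.trapezoid(counts, ages))
    table = pd.DataFrame({"age": ages, "population": counts})
    return SyntheticDemography(shape, float(max_age), table)


@dataclass(frozen=True)
class LifeTable:
    """Remaining life expectancy e(x) and all-cause mortality m(x) by age."""

    table: pd.DataFrame  # columns: age, ex, mx

    def __post_init__(self) -> None:
        for col in ("age", "ex"):
            if col not in self.table.columns:
                raise ValueError(f"life table missing column {col!r}")
        if (self.table["ex"] <= 0).any():
            raise ValueError("remaining life expectancy must be positive")

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    def expectancy(self, age: float | np.ndarray) -> np.ndarray | float:
        """e(x), linearly interpolated; ages outside the table are an error."""
        a = np.asarray(age, dtype=float)
        if np.any(a < self.ages[0]) or np.any(a > self.ages[-1]):
            raise ValueError("age outside the life table's range")
        out = np.interp(a, self.ages, self.table["ex"].to_numpy(dtype=float))
        return float(out) if np.ndim(age) == 0 else out

    def mortality(self) -> FeatureFunction:
        """All-cause mortality m(x) as an interpolated feature function."""
        if "mx" not in self.table.columns:
            raise ValueError("life table carries no mortality column")
        ages = self.ages
        mx = self.table["mx"].to_numpy(dtype=float)

        def evaluate(x: np.ndarray) -> np.ndarray:
            return np.interp(np.clip(x, ages[0], ages[-1]), ages, mx)

        return FeatureFunction(evaluate, (float(ages[0]), float(ages[-1])))


def make_life_table(demography_shape: str, max_age: float = 101.0) -> LifeTable:
    """Stylised life table matched to a demography shape.

    The rectangular (HIC-like) shape gets the higher life expectancy at
    birth. m(x) is U-shaped: elevated infant mortality, a mid-life minimum,
    and exponentially rising old-age mortality.
    """
    if demography_shape not in DEMOGRAPHY_SHAPES:
        raise ValueError(f"unknown demography shape {demography_shape!r}")
    hic = demography_shape == "rectangular"
    e0 = 81.0 if hic else 64.0
    ages = np.arange(0.0, max_age + 0.5, 1.0)
    if ages[-1] != max_age:
        ages = np.append(ages, max_age)
    # e(x): concave decline from e0 to a small positive tail value
    tail = 1.5
    ex = tail + (e0 - tail) * (1.0 - ages / (max_age + 2.0)) ** 1.15
    infant = (0.030 if hic else 0.060) * np.exp(-ages / 1.5)
    senescent = (0.45 if hic else 0.40) * np.exp((ages - max_age) / 9.0)
    baseline = 0.0006 if hic else 0.0020
    mx = infant + senescent + baseline
    return LifeTable(pd.DataFrame({"age": ages, "ex": ex, "mx": mx}))


def make_contact_matrix(
    model: Partition,
    assortativity: float = 0.3,
    seed: int = 0,
    *,
    population_shares: np.ndarray | None = None,
    total_contacts: float = 8.0,
) -> ContactMatrix:
    """Age-assortative contact matrix for the model partition.

    A convex blend of proportional mixing (contacts distributed by the
    partners' population shares — a rank-one matrix) and fully assortative
    within-group mixing (diagonal). Every individual makes
    ``total_contacts`` contacts per day. The construction is deterministic;
    ``seed`` is accepted for interface uniformity with the other generators.
    """
    del seed  # deterministic construction, no random draws
    if not 0.0 <= assortativity <= 1.0:
        raise ValueError("assortativity must lie in [0, 1]")
    n = model.n_intervals
    if population_shares is None:
        shares = model.widths / model.widths.sum()
    else:
        shares = np.asarray(population_shares, dtype=float)
        if shares.shape != (n,) or np.any(shares < 0) or shares.sum() <= 0:
            raise ValueError("population_shares must be n non-negative values")
        shares = shares / shares.sum()
    proportional = np.tile(shares, (n, 1))
    matrix = total_contacts * (
        (1.0 - assortativity) * proportional + assortativity * np.eye(n)
    )
    return ContactMatrix(model, matrix)


def load_table(path: str | Path, schema: tuple[str, ...]) -> pd.DataFrame:
    """Read a delimited text table, validating the required columns.

    Extra columns are preserved and ignored (tolerant-reader rule); the
    required columns are coerced to float.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and df.columns.size == 0:
        raise ValueError(f"{path} is empty")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {missing}")
    for col in schema:
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric values in column {col!r}") from exc
    return df


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV with full float precision (lossless round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False, float_format="%.17g")
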