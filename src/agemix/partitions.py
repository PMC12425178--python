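"""Partitions, interpolated feature functions, and the mixing table.

A *partition* divides a continuous stratification feature (age, in the
demonstration) into half-open intervals ``[b_i, b_{i+1})``; the terminal
interval is closed. Two partitions matter: the coarse *model* partition used
for compartments and the fine *output* partition wanted for outcomes. Their
union — the *mixing* partition — is where the weighted-parameter and
population integrals

    weight_k     = ∫_{c_k} parameter(x) ρ(x) dx
    population_k = ∫_{c_k} ρ(x) dx

are evaluated, one row per mixing interval. Downstream, aggregation sums
these rows by model group and disaggregation re-apportions by output group;
both are ratio forms, so the overall normalisation of ρ cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Partition",
    "FeatureFunction",
    "MixingTable",
    "make_partition",
    "union_partition",
    "interpolate_parameter",
    "interpolate_density",
    "build_mixing_table",
]

#: Default absolute quadrature tolerance for mixing-table integrals.
QUAD_ABS_TOL = 1e-9

#: Grid step (feature units) of the composite-Simpson fallback used when
#: adaptive quadrature does not converge (e.g. on kinked interpolants).
SIMPSON_STEP = 0.01


@dataclass(frozen=True)
class Partition:
    """Ordered interval boundaries over the stratification feature.

    Intervals are half-open ``[b_i, b_{i+1})`` except the last, which is
    closed so the overall support ``[lower, upper]`` is covered exactly.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("a partition needs at least 2 boundaries")
        if not np.all(np.isfinite(b)):
            raise ValueError("partition boundaries must be finite")
        if not np.all(np.diff(b) > 0):
            raise ValueError("partition boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size - 1

    @property
    def lower(self) -> float:
        return float(self.boundaries[0])

    @property
    def upper(self) -> float:
        return float(self.boundaries[-1])

    @property
    def lowers(self) -> np.ndarray:
        return self.boundaries[:-1]

    @property
    def uppers(self) -> np.ndarray:
        return self.boundaries[1:]

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.lowers + self.uppers)

    def locate(self, x: float | np.ndarray) -> np.ndarray:
        """Index of the interval containing ``x``.

        Half-open convention: a boundary value belongs to the interval it
        opens, except the overall upper bound which belongs to the terminal
        (closed) interval.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lower) or np.any(x > self.upper):
            raise ValueError(
                f"feature value outside partition support "
                f"[{self.lower}, {self.upper}]"
            )
        idx = np.searchsorted(self.boundaries, x, side="right") - 1
        return np.minimum(idx, self.n_intervals - 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return (
            self.boundaries.shape == other.boundaries.shape
            and bool(np.all(self.boundaries == other.boundaries))
        )

    def __repr__(self) -> str:
        return f"Partition({self.boundaries.tolist()})"


@dataclass(frozen=True)
class FeatureFunction:
    """A real-valued function of the stratification feature on ``[lo, hi]``.

    Evaluation outside the domain is constant (flat) extrapolation: the
    argument is clipped to the domain first. ``is_density`` marks functions
    that must be strictly positive (a population density).
    """

    fn: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    is_density: bool = False

    def __call__(self, x: float | np.ndarray) -> np.ndarray | float:
        lo, hi = self.domain
        x_arr = np.clip(np.asarray(x, dtype=float), lo, hi)
        out = np.asarray(self.fn(x_arr), dtype=float)
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out)
        return out


def as_feature_function(
    obj: FeatureFunction | Callable | pd.DataFrame | Iterable,
    *,
    density: bool = False,
    domain: tuple[float, float] | None = None,
) -> FeatureFunction:
    """Coerce a callable or two-column table into a :class:`FeatureFunction`."""
    if isinstance(obj, FeatureFunction):
        return obj
    if callable(obj):
        if domain is None:
            raise ValueError("a bare callable needs an explicit domain")
        return FeatureFunction(obj, domain, is_density=density)
    if density:
        return interpolate_density(obj)
    return interpolate_parameter(obj)


def make_partition(boundaries: Sequence[float]) -> Partition:
    """Build a partition from boundary values, sorting and deduplicating."""
    b = np.asarray(list(boundaries), dtype=float)
    if b.size and not np.all(np.isfinite(b)):
        raise ValueError("partition boundaries must be finite")
    b = np.unique(b)
    if b.size < 2:
        raise ValueError("a partition needs at least 2 distinct boundaries")
    return Partition(b)


def union_partition(model: Partition, output: Partition) -> Partition:
    """Union of two partitions' boundary sets — the mixing partition.

    Both partitions must share the same overall support; refusing mismatched
    supports avoids silently clipping population mass.
    """
    if model.lower != output.lower or model.upper != output.upper:
        raise ValueError(
            "model and output partitions must share the same overall support; "
            f"got [{model.lower}, {model.upper}] vs [{output.lower}, {output.upper}]"
        )
    return Partition(np.union1d(model.boundaries, output.boundaries))


def _table_to_xy(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise ValueError("table needs two columns (feature, value)")
        x = table.iloc[:, 0].to_numpy(dtype=float)
        y = table.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray([(float(a), float(b)) for a, b in table], dtype=float)
        if arr.size == 0:
            raise ValueError("empty table")
        x, y = arr[:, 0], arr[:, 1]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # collapse exact duplicates; conflicting duplicates are an input error
    keep = np.ones(x.size, dtype=bool)
    for i in range(1, x.size):
        if x[i] == x[i - 1]:
            if y[i] != y[i - 1]:
                raise ValueError(
                    f"duplicate feature value {x[i]} with conflicting values"
                )
            keep[i] = False
    return x[keep], y[keep]


def interpolate_parameter(table) -> FeatureFunction:
    """Monotonicity-preserving cubic interpolant through (feature, value) rows.

    PCHIP avoids the negative overshoot a raw cubic spline can produce on
    steep, positive data such as infection-fatality ratios. Beyond the
    tabulated range the function is held constant at the end values.
    """
    x, y = _table_to_xy(table)
    if x.size < 2:
        raise ValueError("parameter table needs at least 2 distinct features")
    interp = PchipInterpolator(x, y, extrapolate=False)
    lo, hi = float(x[0]), float(x[-1])

    def evaluate(q: np.ndarray) -> np.ndarray:
        return interp(np.clip(q, lo, hi))

    return FeatureFunction(evaluate, (lo, hi))


def interpolate_density(table) -> FeatureFunction:
    """Piecewise-linear population density, normalised to unit mass.

    The (feature, count) rows are linearly interpolated and rescaled so the
    integral over the tabulated range is 1. All downstream formulas are
    ratio forms and therefore invariant to this normalisation, which in turn
    makes population-conservation invariants directly testable.
    """
    x, y = _table_to_xy(table)
    if x.size < 2:
        raise ValueError("density table needs at least 2 distinct features")
    if np.any(y < 0):
        raise ValueError("density counts must be non-negative")
    mass = np.trapezoid(y, x)
    if mass <= 0:
        raise ValueError("density table has zero total mass")
    y = y / mass
    lo, hi = float(x[0]), float(x[-1])

    def evaluate(q: np.ndarray) -> np.ndarray:
        return np.interp(np.clip(q, lo, hi), x, y)

    return FeatureFunction(evaluate, (lo, hi), is_density=True)


def _integrate(
    f: Callable[[np.ndarray], np.ndarray],
    lo: float,
    hi: float,
    tol: float,
) -> float:
    """Adaptive quadrature with a deterministic composite-Simpson fallback."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, abserr, info, *rest = integrate.quad(
            f, lo, hi, epsabs=tol, epsrel=tol, limit=200, full_output=True
        )
    if not rest and abserr <= max(tol, 1e-8 * abs(val)):
        return float(val)
    # fall back to a fixed Simpson rule on a fine grid
    n = max(4, int(np.ceil((hi - lo) / SIMPSON_STEP)))
    n += n % 2  # Simpson needs an even interval count
    grid = np.linspace(lo, hi, n + 1)
    return float(integrate.simpson(np.asarray(f(grid), dtype=float), x=grid))


@dataclass(frozen=True)
class MixingTable:
    """Per-mixing-interval weights and populations linking two partitions.

    ``table`` has one row per mixing interval with columns ``lower``,
    ``upper``, ``weight``, ``population``, ``model_group``, ``output_group``.
    """

    table: pd.DataFrame
    model: Partition
    output: Partition
    mixing: Partition = field(repr=False)
    parameter: FeatureFunction = field(repr=False)
    density: FeatureFunction = field(repr=False)

    @property
    def n_model_groups(self) -> int:
        return self.model.n_intervals

    @property
    def n_output_groups(self) -> int:
        return self.output.n_intervals

    def group_populations(self, total: float = 1.0) -> np.ndarray:
        """Population mass per model group, scaled to ``total``."""
        pop = (
            self.table.groupby("model_group")["population"]
            .sum()
            .reindex(range(self.n_model_groups), fill_value=0.0)
            .to_numpy()
        )
        return pop / pop.sum() * total

    def output_populations(self, total: float = 1.0) -> np.ndarray:
        """Population mass per output group, scaled to ``total``."""
        pop = (
            self.table.groupby("output_group")["population"]
            .sum()
            .reindex(range(self.n_output_groups), fill_value=0.0)
            .to_numpy()
        )
        return pop / pop.sum() * total


def build_mixing_table(
    parameter: FeatureFunction,
    density: FeatureFunction,
    model: Partition,
    output: Partition,
    *,
    tol: float = QUAD_ABS_TOL,
) -> MixingTable:
    """Integrate parameter·density and density over every mixing interval.

    Each mixing interval lies inside exactly one model interval and one
    output interval; the row records both memberships so aggregation and
    disaggregation can share the same table.
    """
    mixing = union_partition(model, output)
    rows = []
    for k in range(mixing.n_intervals):
        lo = float(mixing.boundaries[k])
        hi = float(mixing.boundaries[k + 1])
        weight = _integrate(lambda x: parameter(x) * density(x), lo, hi, tol)
        population = _integrate(density, lo, hi, tol)
        if population <= 0:
            raise ValueError(
                f"non-positive population mass {population} on mixing "
                f"interval [{lo}, {hi})"
            )
        mid = 0.5 * (lo + hi)
        rows.append(
            {
                "lower": lo,
                "upper": hi,
                "weight": weight,
                "population": population,
                "model_group": int(model.locate(mid)),
                "output_group": int(output.locate(mid)),
            }
        )
    table = pd.DataFrame(rows)
    return MixingTable(table, model, output, mixing, parameter, density)
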