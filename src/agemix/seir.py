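"""Age-stratified SEIR demonstration model with vaccination scenarios.

The archetypal model stratifies S, E, I, R compartments by age group. The
force of infection on group i is

    λ_i = β · Σ_j c_ij · I_j / N_j

with β the per-contact transmissibility, c_ij the daily contacts a member of
group i has with group j, and N_j the (constant) size of group j. Exposed
individuals become infectious at rate τ and recover at rate γ; there is no
ageing, demography or waning. Fatalities stay in R — deaths are pure
post-processing: an infection-fatality ratio per group multiplies cumulative
infections, so trajectories are identical across IFR choices.

Vaccination is all-or-nought: before the simulation starts, the effectively
protected fraction (coverage × efficacy) of the target group moves from S to
R. The epidemic is seeded with 0.001% of every age group placed in E.

Two parameterisations are bundled: a flu-like pathogen (β=0.15, 1/τ=1 d,
1/γ=2 d, IFR proportional to all-cause mortality, hence U-shaped in age) and
a COVID-like pathogen (β=0.1, 1/τ=3 d, 1/γ=5 d, IFR = 10^(−3.27+0.0524·age)/100,
strictly increasing in age).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .blending import BlendedParameters, OutcomeVector
from .partitions import FeatureFunction, Partition

__all__ = [
    "PathogenParams",
    "ContactMatrix",
    "VaccinationScenario",
    "SEIRState",
    "EpidemicRun",
    "covid_ifr",
    "flu_ifr",
    "covid_like",
    "flu_like",
    "force_of_infection",
    "seed_epidemic",
    "apply_vaccination",
    "run_seir",
    "compute_deaths",
    "calibrate_flu_scale",
    "expand_contacts",
]

#: Fraction of each age group seeded into E at t=0 (0.001%).
SEED_FRACTION = 1e-5

#: Default simulation horizon in days.
DEFAULT_HORIZON = 365

#: ODE solver tolerances (relative, absolute).
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10


def covid_ifr(age: float | np.ndarray) -> float | np.ndarray:
    """COVID-like infection-fatality ratio, 10^(−3.27 + 0.0524·age) / 100."""
    return 10.0 ** (-3.27 + 0.0524 * np.asarray(age, dtype=float)) / 100.0


def flu_ifr(
    mortality: FeatureFunction, scale: float
) -> FeatureFunction:
    """Flu-like IFR: proportional to all-cause mortality m(x), clipped to [0, 1]."""
    if scale < 0:
        raise ValueError("scale must be non-negative")

    def evaluate(x: np.ndarray) -> np.ndarray:
        return np.clip(scale * np.asarray(mortality(x), dtype=float), 0.0, 1.0)

    return FeatureFunction(evaluate, mortality.domain)


@dataclass(frozen=True)
class PathogenParams:
    """Transmission parameters plus the age-varying IFR of a pathogen."""

    beta: float                  # per-contact transmissibility, /contact/day
    latent_period: float         # 1/τ, days
    infectious_period: float     # 1/γ, days
    ifr: FeatureFunction         # age → fraction in [0, 1]
    name: str = "pathogen"

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.latent_period <= 0 or self.infectious_period <= 0:
            raise ValueError("beta, latent and infectious periods must be positive")

    @property
    def tau(self) -> float:
        return 1.0 / self.latent_period

    @property
    def gamma(self) -> float:
        return 1.0 / self.infectious_period


def covid_like(domain: tuple[float, float] = (0.0, 101.0)) -> PathogenParams:
    """COVID-like parameterisation; the IFR is capped at 1 at extreme ages."""
    ifr = FeatureFunction(lambda x: np.minimum(covid_ifr(x), 1.0), domain)
    return PathogenParams(0.1, 3.0, 5.0, ifr, name="covid_like")


def flu_like(mortality: FeatureFunction, scale: float = 1.0) -> PathogenParams:
    """Flu-like parameterisation with IFR ∝ all-cause mortality."""
    return PathogenParams(0.15, 1.0, 2.0, flu_ifr(mortality, scale), name="flu_like")


@dataclass(frozen=True)
class ContactMatrix:
    """Daily contact rates between model age groups."""

    partition: Partition
    matrix: np.ndarray  # c[i, j] = daily contacts of an i-member with group j

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = self.partition.n_intervals
        if m.shape != (n, n):
            raise ValueError(f"contact matrix must be {n}×{n}, got {m.shape}")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("contact rates must be finite and non-negative")
        object.__setattr__(self, "matrix", m)


def expand_contacts(
    contacts: ContactMatrix, fine: Partition, fine_populations: np.ndarray
) -> ContactMatrix:
    """Expand a coarse contact matrix onto a refining partition.

    A person in fine group i keeps the coarse per-capita rate toward each
    coarse block, split across the block's fine groups proportionally to
    population: c_ij = C_IJ · N_j / N_J. Block-aggregated dynamics are then
    identical to the coarse model when prevalence is uniform within blocks.
    """
    fine_populations = np.asarray(fine_populations, dtype=float)
    if fine_populations.shape != (fine.n_intervals,):
        raise ValueError("one population per fine group required")
    mids = fine.midpoints
    block = contacts.partition.locate(mids)  # coarse block of each fine group
    block_pop = np.bincount(block, weights=fine_populations,
                            minlength=contacts.partition.n_intervals)
    share = fine_populations / block_pop[block]
    fine_matrix = contacts.matrix[np.ix_(block, block)] * share[np.newaxis, :]
    return ContactMatrix(fine, fine_matrix)


@dataclass(frozen=True)
class SEIRState:
    """Per-group compartment occupancies at a single time."""

    partition: Partition
    S: np.ndarray
    E: np.ndarray
    I: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        n = self.partition.n_intervals
        for name in ("S", "E", "I", "R"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have one entry per group")
            if np.any(v < -1e-9):
                raise ValueError(f"negative occupancy in {name}")
            object.__setattr__(self, name, v)

    @property
    def populations(self) -> np.ndarray:
        return self.S + self.E + self.I + self.R

    @property
    def total(self) -> float:
        return float(self.populations.sum())


@dataclass(frozen=True)
class VaccinationScenario:
    """Pre-simulation dose allocation to one age range, all-or-nought."""

    name: str
    target: tuple[float, float] | None  # (lo, hi) age range, or None for no programme
    doses: float = 0.0
    efficacy: float = 0.5

    def __post_init__(self) -> None:
        if self.doses < 0:
            raise ValueError("doses must be non-negative")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("efficacy must lie in [0, 1]")


def no_vaccination() -> VaccinationScenario:
    return VaccinationScenario("none", None, 0.0, 0.0)


def force_of_infection(
    state: SEIRState, params: PathogenParams, contacts: ContactMatrix
) -> np.ndarray:
    """λ_i = β Σ_j c_ij I_j / N_j for the current state."""
    n_tot = state.populations
    if np.any(n_tot <= 0):
        raise ValueError("every group must have positive total population")
    return params.beta * contacts.matrix @ (state.I / n_tot)


def seed_epidemic(
    partition: Partition, populations: Sequence[float],
    seed_fraction: float = SEED_FRACTION,
) -> SEIRState:
    """Seed 0.001% of every age group into the E compartment.

    Because the seeded fraction is uniform across groups, seeding a refined
    partition is automatically population-proportional within coarse bounds.
    """
    pop = np.asarray(populations, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("group populations must be positive")
    e0 = seed_fraction * pop
    return SEIRState(partition, pop - e0, e0, np.zeros_like(pop), np.zeros_like(pop))


def apply_vaccination(state: SEIRState, scenario: VaccinationScenario) -> SEIRState:
    """Move the effectively protected fraction of the target range from S to R.

    Coverage is doses / target population, capped at 1. On a refined
    partition the same coverage applies to every group inside the target
    range, which is exactly population-proportional dose allocation.
    """
    if scenario.target is None or scenario.doses == 0:
        return state
    lo, hi = scenario.target
    part = state.partition
    in_target = (part.lowers >= lo) & (part.uppers <= hi)
    if not np.any(in_target):
        raise ValueError(f"no model group lies inside target range [{lo}, {hi})")
    pop = state.populations
    target_pop = pop[in_target].sum()
    coverage = min(1.0, scenario.doses / target_pop)
    protected = np.where(in_target, coverage * scenario.efficacy * pop, 0.0)
    protected = np.minimum(protected, state.S)  # S cannot go negative
    return replace(state, S=state.S - protected, R=state.R + protected)


@dataclass(frozen=True)
class EpidemicRun:
    """Solved trajectories plus cumulative infections per group."""

    partition: Partition
    times: np.ndarray
    S: np.ndarray  # shape (n_times, n_groups)
    E: np.ndarray
    I: np.ndarray
    R: np.ndarray
    cumulative_infections_t: np.ndarray = field(repr=False)

    @property
    def cumulative_infections(self) -> np.ndarray:
        """Final cumulative infections (∫ λS dt) per group."""
        return self.cumulative_infections_t[-1]

    @property
    def final_state(self) -> SEIRState:
        return SEIRState(self.partition, self.S[-1], self.E[-1], self.I[-1], self.R[-1])

    def attack_rate(self) -> np.ndarray:
        """Cumulative infections as a fraction of each group's population."""
        pop = self.S[0] + self.E[0] + self.I[0] + self.R[0]
        return self.cumulative_infections / pop


def run_seir(
    initial: SEIRState,
    params: PathogenParams,
    contacts: ContactMatrix,
    horizon: float = DEFAULT_HORIZON,
) -> EpidemicRun:
    """Integrate the age-stratified SEIR system over ``horizon`` days.

    Cumulative infections are tracked as an auxiliary integrated state
    (d/dt = λS) rather than by differencing S, avoiding cancellation error.
    Output is recorded on a 1-day grid.
    """
    n = initial.partition.n_intervals
    n_tot = initial.populations  # constant: closed system per group
    beta_c = params.beta * contacts.matrix
    tau, gamma = params.tau, params.gamma

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        s, e, i = y[:n], y[n : 2 * n], y[2 * n : 3 * n]
        lam = beta_c @ (i / n_tot)
        new_inf = lam * s
        return np.concatenate(
            [-new_inf, new_inf - tau * e, tau * e - gamma * i, gamma * i, new_inf]
        )

    y0 = np.concatenate(
        [initial.S, initial.E, initial.I, initial.R, np.zeros(n)]
    )
    t_eval = np.arange(0.0, float(horizon) + 0.5, 1.0)
    sol = solve_ivp(
        rhs, (0.0, float(horizon)), y0, t_eval=t_eval,
        method="RK45", rtol=ODE_RTOL, atol=ODE_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    y = sol.y.T
    if y.min() < -1e-6:
        raise RuntimeError(f"negative compartment beyond tolerance: {y.min()}")
    return EpidemicRun(
        initial.partition,
        sol.t,
        y[:, :n],
        y[:, n : 2 * n],
        y[:, 2 * n : 3 * n],
        y[:, 3 * n : 4 * n],
        y[:, 4 * n : 5 * n],
    )


def compute_deaths(run: EpidemicRun, blended_ifr: BlendedParameters) -> OutcomeVector:
    """Deaths per group = IFR_j × cumulative infections_j (post-processing)."""
    if blended_ifr.partition != run.partition:
        raise ValueError("IFR values are not indexed by the run's partition")
    deaths = blended_ifr.values * run.cumulative_infections
    return OutcomeVector(run.partition, deaths)


def ifr_at_lower_bound(ifr: FeatureFunction, partition: Partition) -> BlendedParameters:
    """High-resolution IFR assignment: group [x, x+1) uses IFR(x)."""
    return BlendedParameters(partition, np.asarray(ifr(partition.lowers)))


def calibrate_flu_scale(
    mortality: FeatureFunction,
    reference_run: EpidemicRun,
    covid_deaths_total: float,
    *,
    ifr_assignment=ifr_at_lower_bound,
) -> float:
    """Scale m(x) so flu deaths match COVID deaths in the reference scenario.

    Deaths are post-processing and exactly linear in the scale (below the
    IFR clip at 1), so the calibrated scale is the ratio of the COVID death
    total to the unit-scale flu death total in the same reference setting.
    """
    unit = ifr_assignment(flu_ifr(mortality, 1.0), reference_run.partition)
    unit_total = float(
        (unit.values * reference_run.cumulative_infections).sum()
    )
    if unit_total <= 0 or covid_deaths_total <= 0:
        raise ValueError("calibration requires positive death totals on both sides")
    scale = covid_deaths_total / unit_total
    peak_ifr = scale * float(np.max(mortality(np.linspace(*mortality.domain, 512))))
    if peak_ifr > 1.0:
        raise ValueError(
            f"calibrated flu IFR exceeds 1 (peak {peak_ifr:.3f}); "
            "linearity of the calibration no longer holds"
        )
    return scale
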