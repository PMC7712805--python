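"""Age-structured multi-state population model for Alzheimer's disease (AD).

The regional population aged 65+ is split into a disease-free group and an
AD group staged Mild / Moderate / Severe, with Death as an absorbing fourth
state.  Counts are propagated deterministically as expected values: within
one simulated year every AD cohort ages by one year (the 95+ bin absorbing),
the 4x4 one-year stage transition matrix is applied, disease-free counts are
taken as the residual of the official population projection, and incident
cases enter the Mild stage.

Age-specific incidence is not an external input: it is back-calculated from
an age-specific prevalence target during a calibration run, one year at a
time.  Because a single simulated year is linear in the incidence rate, the
calibration is a closed-form ratio (required new cases / disease-free pool)
rather than a numerical root-find.

The initial split of prevalent cases into stages uses the limit distribution
of the survivor-restricted stage chain, obtained by re-running the stage
simulation with end-state feedback until the proportions converge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STAGES",
    "STATES",
    "AGE_MIN",
    "AGE_MAX",
    "N_AGES",
    "N_COHORTS",
    "PopulationProjection",
    "PrevalenceCurve",
    "IncidenceCurve",
    "TransitionMatrix",
    "StageDistribution",
    "ADState",
    "ClampEvent",
    "CalibrationError",
    "ConvergenceError",
    "InternalConsistencyError",
    "simulate_step",
    "derive_incidence",
    "init_stage_proportions",
    "converge_stage_composition",
    "simulate_trajectory",
    "run_projection",
]

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = ("mild", "moderate", "severe")
STATES: tuple[str, ...] = STAGES + ("death",)

AGE_MIN = 65          #: youngest age with non-zero AD prevalence
AGE_MAX = 95          #: top age bin, aggregating ages 95 and above
N_AGES = AGE_MAX - AGE_MIN + 1   # 31 bins: 65..94 single years, 95+
N_COHORTS = 96        #: projection bins 0..94 single years, 95+


class CalibrationError(RuntimeError):
    """Incidence is missing or cannot be derived for a simulated year."""


class ConvergenceError(RuntimeError):
    """Limit-distribution iteration failed to converge.

    Carries the last two iterates for diagnosis.
    """

    def __init__(self, message: str, last: np.ndarray, previous: np.ndarray):
        super().__init__(message)
        self.last = last
        self.previous = previous


class InternalConsistencyError(RuntimeError):
    """A simulated state violated a non-negativity / bookkeeping invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationProjection:
    """Official population projection for one region.

    Parameters
    ----------
    region
        Region identifier (e.g. ``"khk"``).
    years
        Contiguous calendar years covered, length ``n_years``.
    counts
        Array of shape ``(96, n_years)``: person counts per single-year age
        cohort 0..94 plus an aggregated 95+ bin, per calendar year.
    """

    region: str
    years: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != N_COHORTS:
            raise ValueError(
                f"projection counts must have shape (96, n_years), got {counts.shape}"
            )
        if counts.shape[1] != years.size:
            raise ValueError("projection counts/years length mismatch")
        if years.size >= 2 and not np.all(np.diff(years) == 1):
            raise ValueError("projection years must be contiguous")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("projection counts must be finite and non-negative")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= self.n_years:
            raise KeyError(f"year {year} outside projection range "
                           f"{self.years[0]}..{self.years[-1]}")
        return idx

    def senior_counts(self) -> np.ndarray:
        """Counts for ages 65..95+, shape ``(31, n_years)``."""
        return self.counts[AGE_MIN:, :]


@dataclass(frozen=True)
class PrevalenceCurve:
    """AD prevalence by age, 31 proportions for ages 65..95+."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (N_AGES,):
            raise ValueError(f"prevalence curve must have {N_AGES} values")
        if not np.all(np.isfinite(values)):
            raise ValueError("prevalence values must be finite")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("prevalence values must lie in [0, 1]")


@dataclass(frozen=True)
class IncidenceCurve:
    """Per-age annual incidence, one curve per simulated one-year step.

    ``values[k, a]`` is the probability that a disease-free person in age bin
    ``a`` (65..95+) develops AD during the step from ``start_years[k]`` to
    ``start_years[k] + 1``.
    """

    values: np.ndarray
    start_years: np.ndarray
    clamp_events: tuple["ClampEvent", ...] = ()

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        start_years = np.asarray(self.start_years, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "start_years", start_years)
        if values.shape != (start_years.size, N_AGES):
            raise ValueError("incidence values must have shape (n_steps, 31)")
        if np.any(values < 0) or np.any(values > 1) or not np.all(np.isfinite(values)):
            raise ValueError("incidence values must lie in [0, 1]")

    def for_year(self, year: int) -> np.ndarray:
        """Incidence curve governing the step ``year -> year + 1``."""
        matches = np.nonzero(self.start_years == int(year))[0]
        if matches.size == 0:
            raise CalibrationError(
                f"no incidence available for the step starting in {year}; "
                "run derive_incidence first"
            )
        return self.values[matches[0]]


@dataclass(frozen=True)
class ClampEvent:
    """Record of one incidence value forced back into [0, 1] at calibration."""

    year: int
    age: int
    raw_value: float
    clamped_to: float
    infeasible: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        kind = "infeasible" if self.infeasible else "clamped"
        return (f"{kind} incidence at age {self.age}, step {self.year}->"
                f"{self.year + 1}: {self.raw_value:.6g} -> {self.clamped_to}")


@dataclass(frozen=True)
class TransitionMatrix:
    """One-year stage transition probabilities over (Mild, Moderate, Severe, Death).

    Entry ``(i, j)`` is the probability of moving from state ``i`` to state
    ``j`` within one year.  Death is absorbing; rows are exact probability
    vectors (sum 1 within 1e-12).
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = p.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-12):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"transition row '{STATES[bad]}' sums to {row_sums[bad]:.15f}, not 1"
            )
        if not np.array_equal(p[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("death row must be (0, 0, 0, 1): death is absorbing")

    @property
    def survivor_matrix(self) -> np.ndarray:
        """3x3 sub-matrix of flows among living stages (death column dropped)."""
        return self.probabilities[:3, :3]

    @property
    def death_column(self) -> np.ndarray:
        return self.probabilities[:3, 3]


@dataclass(frozen=True)
class StageDistribution:
    """Proportions of prevalent AD cases in (mild, moderate, severe)."""

    proportions: np.ndarray
    iterations: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)
        if p.shape != (3,):
            raise ValueError("stage distribution must have 3 values")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("stage proportions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"stage proportions sum to {p.sum():.12f}, not 1")


@dataclass(frozen=True)
class ADState:
    """Simulated population state for one calendar year.

    ``ad_counts`` has shape ``(31, 3)``: AD person counts per age bin
    (65..95+) and stage; ``healthy_counts`` holds the disease-free counts for
    the same age bins.
    """

    year: int
    ad_counts: np.ndarray
    healthy_counts: np.ndarray

    def __post_init__(self) -> None:
        ad = np.asarray(self.ad_counts, dtype=float)
        healthy = np.asarray(self.healthy_counts, dtype=float)
        object.__setattr__(self, "ad_counts", ad)
        object.__setattr__(self, "healthy_counts", healthy)
        if ad.shape != (N_AGES, 3):
            raise ValueError("ad_counts must have shape (31, 3)")
        if healthy.shape != (N_AGES,):
            raise ValueError("healthy_counts must have shape (31,)")
        if np.any(ad < -1e-9) or np.any(healthy < -1e-9):
            raise InternalConsistencyError(
                f"negative counts in state for year {self.year}"
            )

    @property
    def ad_total(self) -> float:
        return float(self.ad_counts.sum())

    def stage_totals(self) -> np.ndarray:
        return self.ad_counts.sum(axis=0)

    def check_against(self, projection: PopulationProjection, tol: float = 1e-6) -> None:
        """Verify AD + disease-free counts never exceed the projection."""
        pop = projection.senior_counts()[:, projection.year_index(self.year)]
        total = self.ad_counts.sum(axis=1) + self.healthy_counts
        if np.any(total > pop + tol):
            age = AGE_MIN + int(np.argmax(total - pop))
            raise InternalConsistencyError(
                f"year {self.year}, age {age}: AD + disease-free exceeds projection"
            )


# ---------------------------------------------------------------------------
# core dynamics
# ---------------------------------------------------------------------------


def _age_forward(ad_counts: np.ndarray) -> np.ndarray:
    """Shift AD counts one age bin up; the 95+ bin absorbs its own survivors."""
    aged = np.zeros_like(ad_counts)
    aged[1:] = ad_counts[:-1]
    aged[-1] += ad_counts[-1]
    return aged


def _as_composition(distribution) -> np.ndarray:
    """Normalise a stage split to per-age proportions of shape (31, 3)."""
    if isinstance(distribution, StageDistribution):
        props = np.broadcast_to(distribution.proportions, (N_AGES, 3))
    else:
        props = np.asarray(distribution, dtype=float)
        if props.shape == (3,):
            props = np.broadcast_to(props, (N_AGES, 3))
        elif props.shape != (N_AGES, 3):
            raise ValueError("stage split must have shape (3,) or (31, 3)")
    sums = props.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6) or np.any(props < 0):
        raise ValueError("stage proportions must be non-negative and sum to 1")
    return props / sums[:, None]


def initial_state(
    projection: PopulationProjection,
    prevalence: PrevalenceCurve,
    distribution,
    year: int | None = None,
) -> ADState:
    """Build the start-of-simulation state.

    Prevalent cases at each age are ``prevalence(age) x projection(age, year)``,
    split into stages by ``distribution`` (a :class:`StageDistribution`
    applied uniformly, or an age-resolved ``(31, 3)`` array); the
    disease-free pool is the residual of the projection.
    """
    year = int(projection.years[0]) if year is None else int(year)
    pop = projection.senior_counts()[:, projection.year_index(year)]
    ad_by_age = prevalence.values * pop
    ad = ad_by_age[:, None] * _as_composition(distribution)
    healthy = pop - ad_by_age
    return ADState(year=year, ad_counts=ad, healthy_counts=healthy)


def simulate_step(
    state: ADState,
    projection: PopulationProjection,
    incidence: IncidenceCurve,
    transitions: TransitionMatrix,
) -> ADState:
    """Advance the AD population by one simulated year.

    The fixed update order within the year is:

    1. age every AD cohort by one year (the 95+ bin absorbing);
    2. apply the stage transition matrix as expected counts, removing deaths;
    3. set the disease-free pool to the projection residual, floored at 0;
    4. draw incident cases into Mild: ``new(age) = healthy(age) x incidence(age)``.

    Raises
    ------
    CalibrationError
        If no incidence curve is available for ``state.year``.
    InternalConsistencyError
        If the update produces negative counts beyond tolerance.
    """
    inc = incidence.for_year(state.year)
    next_year = state.year + 1
    pop_next = projection.senior_counts()[:, projection.year_index(next_year)]

    aged = _age_forward(state.ad_counts)
    survivors = aged @ transitions.survivor_matrix
    healthy = np.maximum(pop_next - survivors.sum(axis=1), 0.0)

    new_cases = healthy * inc
    ad_next = survivors.copy()
    ad_next[:, 0] += new_cases
    healthy = healthy - new_cases

    if np.any(ad_next < -1e-9) or np.any(healthy < -1e-9):
        raise InternalConsistencyError(
            f"negative counts produced advancing {state.year} -> {next_year}"
        )
    return ADState(year=next_year, ad_counts=ad_next, healthy_counts=healthy)


def derive_incidence(
    projection: PopulationProjection,
    prevalence: PrevalenceCurve,
    transitions: TransitionMatrix,
    distribution: "StageDistribution | np.ndarray | None" = None,
) -> IncidenceCurve:
    """Back-calculate age- and year-specific incidence from a prevalence target.

    A calibration run walks the simulation forward one year at a time.  After
    ageing and stage transitions, the AD count the target demands at age ``a``
    in year ``t+1`` is ``prevalence(a) x projection(a, t+1)``; since one
    simulated year is linear in incidence, the solve is the closed-form ratio

        incidence(a, t) = (target - survivors) / disease-free pool,

    clamped to [0, 1].  Clamping events (including the infeasible case of a
    positive requirement with an empty disease-free pool, where incidence is
    pinned at 1) are recorded on the returned curve and logged.

    The initial stage split matters because stage-specific death probabilities
    change the survivor counts; ``distribution`` (uniform 3-vector or
    age-resolved ``(31, 3)`` proportions) defaults to all-Mild.
    """
    if distribution is None:
        distribution = StageDistribution(np.array([1.0, 0.0, 0.0]))
    pops = projection.senior_counts()
    years = projection.years
    n_steps = projection.n_years - 1
    target0 = prevalence.values * pops[:, 0]
    ad = target0[:, None] * _as_composition(distribution)

    values = np.zeros((n_steps, N_AGES))
    events: list[ClampEvent] = []
    for k in range(n_steps):
        aged = _age_forward(ad)
        survivors = aged @ transitions.survivor_matrix
        surv_by_age = survivors.sum(axis=1)
        pop_next = pops[:, k + 1]
        healthy = np.maximum(pop_next - surv_by_age, 0.0)
        required = prevalence.values * pop_next - surv_by_age

        inc = np.zeros(N_AGES)
        for a in range(N_AGES):
            if healthy[a] > 0.0:
                raw = required[a] / healthy[a]
                inc[a] = min(max(raw, 0.0), 1.0)
                if raw < 0.0 or raw > 1.0:
                    events.append(ClampEvent(int(years[k]), AGE_MIN + a,
                                             float(raw), float(inc[a])))
            elif required[a] > 1e-9:
                inc[a] = 1.0
                events.append(ClampEvent(int(years[k]), AGE_MIN + a,
                                         float("inf"), 1.0, infeasible=True))
                logger.warning(
                    "infeasible calibration: age %d, step %d->%d needs %.3f "
                    "new cases from an empty disease-free pool",
                    AGE_MIN + a, years[k], years[k] + 1, required[a],
                )
            elif required[a] < -1e-9:
                # survivors already exceed the target and nobody is left to
                # not-convert: record the overshoot as a clamp at 0
                events.append(ClampEvent(int(years[k]), AGE_MIN + a,
                                         float("-inf"), 0.0))
        values[k] = inc
        new_cases = healthy * inc
        ad = survivors
        ad[:, 0] += new_cases

    for ev in events:
        if not ev.infeasible:
            logger.info("%s", ev)
    return IncidenceCurve(values=values, start_years=years[:-1],
                         clamp_events=tuple(events))


def init_stage_proportions(
    transitions: TransitionMatrix,
    projection: PopulationProjection,
    prevalence: PrevalenceCurve,
    tolerance: float = 1e-8,
    max_iter: int = 200,
    initial: np.ndarray | None = None,
) -> StageDistribution:
    """Determine the initial stage split as the limit distribution of the chain.

    One "run" propagates a stage-proportion vector through the
    survivor-restricted transition chain for the full projection horizon,
    renormalising over survivors each year.  The run's end-state proportions
    are fed back as the next run's initial split; iteration stops when
    successive runs agree within ``tolerance`` in sup-norm.  The converged
    vector is applied uniformly across age cohorts at initialisation.

    ``prevalence`` is accepted for interface symmetry with the other
    calibration entry points; the limit split is governed by the transition
    structure and the horizon length alone.  ``initial`` sets the first
    run's split (default all-Mild); the converged result does not depend
    on it.

    Raises
    ------
    ConvergenceError
        After ``max_iter`` runs without convergence (carries last iterates).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    del prevalence  # interface symmetry; see docstring
    n_steps = max(projection.n_years - 1, 1)
    m = transitions.survivor_matrix
    if initial is None:
        v = np.array([1.0, 0.0, 0.0])
    else:
        v = np.asarray(initial, dtype=float)
        if v.shape != (3,) or np.any(v < 0) or v.sum() <= 0:
            raise ValueError("initial split must be 3 non-negative values")
        v = v / v.sum()
    for iteration in range(1, max_iter + 1):
        w = v.copy()
        for _ in range(n_steps):
            w = w @ m
            total = w.sum()
            if total <= 0.0:
                raise ConvergenceError(
                    "stage chain has no survivors after one year; "
                    "limit distribution undefined", w, v,
                )
            w = w / total
        if np.max(np.abs(w - v)) < tolerance:
            return StageDistribution(proportions=w / w.sum(),
                                     iterations=iteration)
        v = w
    raise ConvergenceError(
        f"limit distribution did not converge in {max_iter} runs", w, v
    )


def converge_stage_composition(
    projection: PopulationProjection,
    prevalence: PrevalenceCurve,
    transitions: TransitionMatrix,
    seed_distribution: StageDistribution,
    tolerance: float = 1e-9,
    max_iter: int = 200,
) -> tuple[np.ndarray, int]:
    """Refine the uniform limit split into an age-resolved composition.

    Starting from the survivor-chain limit split applied at every age, each
    iteration calibrates incidence, simulates the horizon, and feeds the
    end-state per-age stage proportions back as the initial split.  The
    fixed point is the model's own steady-state composition by age: under a
    stationary scenario the resulting trajectory has a constant stage mix
    at every age (young bins mild-rich from incident inflow, the 95+ bin
    near the survivor-chain limit).

    Returns the converged ``(31, 3)`` proportions and the iteration count.

    Raises
    ------
    ConvergenceError
        After ``max_iter`` feedback runs without convergence.
    """
    pops = projection.senior_counts()
    composition = _as_composition(seed_distribution).copy()
    fallback = _as_composition(seed_distribution)
    previous = composition
    for iteration in range(1, max_iter + 1):
        incidence = derive_incidence(projection, prevalence, transitions,
                                     composition)
        trajectory = simulate_trajectory(projection, prevalence, transitions,
                                         incidence, composition)
        end = trajectory[-1].ad_counts
        totals = end.sum(axis=1)
        new = fallback.copy()
        occupied = totals > 0
        new[occupied] = end[occupied] / totals[occupied, None]
        if np.max(np.abs(new - composition)) < tolerance:
            return new, iteration
        previous, composition = composition, new
    raise ConvergenceError(
        f"stage composition did not converge in {max_iter} feedback runs",
        composition, previous,
    )


def simulate_trajectory(
    projection: PopulationProjection,
    prevalence: PrevalenceCurve,
    transitions: TransitionMatrix,
    incidence: IncidenceCurve,
    distribution,
) -> list[ADState]:
    """Run the year-by-year simulation over the full projection horizon."""
    state = initial_state(projection, prevalence, distribution)
    trajectory = [state]
    for _ in range(projection.n_years - 1):
        state = simulate_step(state, projection, incidence, transitions)
        trajectory.append(state)
    return trajectory


@dataclass(frozen=True)
class ProjectionResult:
    """Full output of a calibrated population run."""

    trajectory: list[ADState]
    incidence: IncidenceCurve
    stage_distribution: StageDistribution
    stage_composition: np.ndarray | None = None
    region: str = ""
    warnings: tuple[str, ...] = field(default=())

    @property
    def years(self) -> np.ndarray:
        return np.array([s.year for s in self.trajectory])


def run_projection(config) -> ProjectionResult:
    """Orchestrate a calibrated run from a scenario configuration.

    Loads the projection, prevalence curve and transition matrix named by
    ``config`` (an :class:`adburden.io.ScenarioConfig`), determines the limit
    stage distribution, back-calculates incidence, and simulates the full
    trajectory.  Deterministic given identical inputs.
    """
    from . import io as adio  # local import: io depends on these types

    projection, prevalence, transitions = adio.load_population_inputs(config)
    return run_projection_from_inputs(
        projection, prevalence, transitions,
        limit_tolerance=config.limit_tolerance,
        max_iterations=config.max_iterations,
    )


def run_projection_from_inputs(
    projection: PopulationProjection,
    prevalence: PrevalenceCurve,
    transitions: TransitionMatrix,
    limit_tolerance: float = 1e-8,
    max_iterations: int = 200,
) -> ProjectionResult:
    """Calibrate and simulate from already-loaded inputs.

    Pipeline order: survivor-chain limit split -> age-resolved composition
    refinement -> incidence back-calculation -> year-by-year simulation.
    """
    distribution = init_stage_proportions(
        transitions, projection, prevalence,
        tolerance=limit_tolerance, max_iter=max_iterations,
    )
    composition, feedback_runs = converge_stage_composition(
        projection, prevalence, transitions, distribution,
        max_iter=max_iterations,
    )
    incidence = derive_incidence(projection, prevalence, transitions, composition)
    trajectory = simulate_trajectory(
        projection, prevalence, transitions, incidence, composition
    )
    warnings = tuple(str(ev) for ev in incidence.clamp_events)
    warnings += (
        f"limit distribution converged in {distribution.iterations} runs",
        f"stage composition converged in {feedback_runs} feedback runs",
    )
    return ProjectionResult(
        trajectory=trajectory,
        incidence=incidence,
        stage_distribution=distribution,
        stage_composition=composition,
        region=projection.region,
        warnings=warnings,
    )
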