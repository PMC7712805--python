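"""Unit and property tests for the multi-state population simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from adburden import synthetic
from adburden.population import (
    AGE_MIN,
    N_AGES,
    ADState,
    CalibrationError,
    ConvergenceError,
    IncidenceCurve,
    PrevalenceCurve,
    StageDistribution,
    TransitionMatrix,
    derive_incidence,
    init_stage_proportions,
    initial_state,
    run_projection_from_inputs,
    simulate_step,
    simulate_trajectory,
)

from conftest import empty_state, flat_projection, zero_incidence


def max_roundtrip_error(spec: synthetic.SyntheticSpec) -> float:
    """Worst relative gap between simulated AD counts and the prevalence
    target over all (age, year) cells with a non-zero target."""
    projection = synthetic.generate_projection(spec)
    prevalence = synthetic.generate_prevalence(spec)
    transitions = synthetic.generate_transition_matrix(spec)
    result = run_projection_from_inputs(projection, prevalence, transitions)
    assert not result.incidence.clamp_events
    target = prevalence.values[:, None] * projection.senior_counts()
    simulated = np.array([s.ad_counts.sum(axis=1) for s in result.trajectory]).T
    mask = target > 0
    return float(np.max(np.abs(simulated[mask] - target[mask]) / target[mask]))


# ---------------------------------------------------------------------------
# type invariants
# ---------------------------------------------------------------------------


class TestTransitionMatrix:
    def test_rejects_row_not_summing_to_one(self):
        bad = np.eye(4)
        bad[0, 0] = 0.97
        with pytest.raises(ValueError, match="sums to"):
            TransitionMatrix(bad)

    def test_rejects_non_absorbing_death(self):
        bad = np.eye(4)
        bad[3] = [0.1, 0.0, 0.0, 0.9]
        with pytest.raises(ValueError, match="absorbing"):
            TransitionMatrix(bad)

    def test_survivor_matrix_drops_death(self, progressive_matrix):
        m = progressive_matrix.survivor_matrix
        assert m.shape == (3, 3)
        np.testing.assert_allclose(
            m.sum(axis=1) + progressive_matrix.death_column, 1.0, atol=1e-12
        )


def test_stage_distribution_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        StageDistribution(np.array([0.5, 0.3, 0.1]))


def test_negative_counts_rejected():
    with pytest.raises(Exception, match="negative"):
        ADState(year=2020, ad_counts=np.full((N_AGES, 3), -1.0),
                healthy_counts=np.zeros(N_AGES))


# ---------------------------------------------------------------------------
# simulate_step
# ---------------------------------------------------------------------------


class TestSimulateStep:
    def test_identity_matrix_shifts_counts_one_age_up(self, identity_matrix):
        projection = flat_projection(n_years=3, count=10_000.0)
        ad = np.zeros((N_AGES, 3))
        ad[5, 0] = 100.0   # mild, age 70
        ad[10, 1] = 50.0   # moderate, age 75
        ad[-1, 2] = 7.0    # severe, top bin
        ad[-2, 2] = 3.0    # severe, age 94
        state = ADState(2020, ad, np.zeros(N_AGES))
        nxt = simulate_step(state, projection, zero_incidence(projection),
                            identity_matrix)
        assert nxt.ad_counts[6, 0] == 100.0
        assert nxt.ad_counts[11, 1] == 50.0
        assert nxt.ad_counts[-1, 2] == 10.0  # 94 ages in, 95+ absorbs
        assert nxt.ad_total == state.ad_total

    def test_single_cohort_expected_count_update(self, progressive_matrix):
        """100 mild patients under mild -> (0.6, 0.3, 0, 0.1): 60 stay mild,
        30 progress to moderate, 10 die."""
        projection = flat_projection(n_years=2, count=10_000.0)
        ad = np.zeros((N_AGES, 3))
        ad[5, 0] = 100.0
        state = ADState(2020, ad, np.zeros(N_AGES))
        nxt = simulate_step(state, projection, zero_incidence(projection),
                            progressive_matrix)
        assert nxt.ad_counts[6, 0] == pytest.approx(60.0)
        assert nxt.ad_counts[6, 1] == pytest.approx(30.0)
        assert nxt.ad_counts[6, 2] == 0.0
        assert state.ad_total - nxt.ad_total == pytest.approx(10.0)  # deaths

    def test_incident_cases_enter_mild(self, identity_matrix):
        """A 1000-person disease-free cohort ageing 70 -> 71 under incidence
        0.02 yields 20 new mild cases at 71, no other stages."""
        projection = flat_projection(n_years=2, count=1000.0)
        values = np.zeros((1, N_AGES))
        values[0, 71 - AGE_MIN] = 0.02
        incidence = IncidenceCurve(values, np.array([2020]))
        state = empty_state(2020, healthy=1000.0)
        nxt = simulate_step(state, projection, incidence, identity_matrix)
        assert nxt.ad_counts[71 - AGE_MIN, 0] == pytest.approx(20.0)
        assert nxt.ad_counts[:, 1:].sum() == 0.0
        assert nxt.ad_total == pytest.approx(20.0)
        # the incident cases left the disease-free pool
        assert nxt.healthy_counts[71 - AGE_MIN] == pytest.approx(980.0)

    def test_missing_incidence_year_raises(self, identity_matrix):
        projection = flat_projection(n_years=3)
        incidence = IncidenceCurve(np.zeros((1, N_AGES)), np.array([2020]))
        state = empty_state(2021)
        with pytest.raises(CalibrationError, match="2021"):
            simulate_step(state, projection, incidence, identity_matrix)


# ---------------------------------------------------------------------------
# derive_incidence
# ---------------------------------------------------------------------------


class TestDeriveIncidence:
    def test_zero_prevalence_gives_zero_incidence(self, progressive_matrix):
        projection = flat_projection(n_years=6)
        prevalence = PrevalenceCurve(np.zeros(N_AGES))
        curve = derive_incidence(projection, prevalence, progressive_matrix)
        assert np.all(curve.values == 0.0)
        assert not curve.clamp_events

    @pytest.mark.parametrize("count_next", [1000.0, 900.0])
    def test_one_step_inversion_closed_cohort(self, count_next):
        """With no deaths and prevalence only at age a+1, the solved rate for
        the cohort ageing a -> a+1 is p * N' / N (= p for constant size)."""
        deathless = TransitionMatrix(np.array([
            [0.7, 0.3, 0.0, 0.0],
            [0.0, 0.7, 0.3, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]))
        n0 = 1000.0
        p = 0.04
        a = 70 - AGE_MIN
        counts = np.zeros((96, 2))
        counts[70, 0] = n0
        counts[71, 1] = count_next
        projection = flat_projection(n_years=2)
        projection = type(projection)(
            region="test", years=projection.years, counts=counts
        )
        prev_values = np.zeros(N_AGES)
        prev_values[a + 1] = p
        prevalence = PrevalenceCurve(prev_values)
        curve = derive_incidence(projection, prevalence, deathless)
        # destination-age labeling: the flow lands at age 71
        solved = curve.values[0, a + 1]
        assert solved == pytest.approx(p * count_next / count_next)
        # the implied new-case count matches p * N'
        assert solved * count_next == pytest.approx(p * count_next)

    def test_round_trip_reproduces_prevalence_target(self):
        assert max_roundtrip_error(synthetic.SyntheticSpec(seed=11)) < 1e-6

    def test_total_prevalence_converts_whole_pool(self, progressive_matrix):
        """Demanding prevalence 1.0 everywhere is the feasibility boundary:
        the entire disease-free pool must convert, so the solved incidence
        is exactly 1 with no clamping."""
        projection = flat_projection(n_years=3)
        prevalence = PrevalenceCurve(np.ones(N_AGES))
        curve = derive_incidence(projection, prevalence, progressive_matrix)
        np.testing.assert_allclose(curve.values[:, :-1], 1.0, atol=1e-12)
        # the aggregated 95+ bin is the known end-of-range exception: two
        # full cohorts age into one bin, so survivors overshoot the target
        assert np.all(curve.values[:, -1] == 0.0)
        assert all(ev.age == 95 for ev in curve.clamp_events)

    def test_shrinking_cohort_clamps_negative_requirement(self):
        """If the projection shrinks faster than AD patients die, survivors
        exceed the target and the solved rate is clamped at 0."""
        deathless = TransitionMatrix(np.array([
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]))
        counts = np.full((96, 2), 1000.0)
        counts[:, 1] = 500.0  # every cohort halves
        projection = flat_projection(n_years=2)
        projection = type(projection)(region="test",
                                      years=projection.years, counts=counts)
        prevalence = PrevalenceCurve(np.full(N_AGES, 0.5))
        curve = derive_incidence(projection, prevalence, deathless)
        assert curve.clamp_events
        assert all(ev.raw_value < 0 and ev.clamped_to == 0.0
                   for ev in curve.clamp_events)

    def test_monotone_in_prevalence_scale(self):
        """Scaling the whole prevalence curve up scales the solved incidence
        up, pointwise, on a clamp-free scenario."""
        spec = synthetic.SyntheticSpec(seed=3)
        projection = synthetic.generate_projection(spec)
        transitions = synthetic.generate_transition_matrix(spec)
        base = synthetic.generate_prevalence(spec)
        scaled = PrevalenceCurve(base.values * 1.5)
        dist = init_stage_proportions(transitions, projection, base)
        low = derive_incidence(projection, base, transitions, dist)
        high = derive_incidence(projection, scaled, transitions, dist)
        assert not low.clamp_events and not high.clamp_events
        assert np.all(high.values >= low.values - 1e-12)


# ---------------------------------------------------------------------------
# limit distribution
# ---------------------------------------------------------------------------


def power_iteration_oracle(transitions: TransitionMatrix,
                           tol: float = 1e-13) -> np.ndarray:
    """Brute-force power iteration on the survivor-restricted stage chain."""
    m = transitions.survivor_matrix
    v = np.array([1.0, 0.0, 0.0])
    for _ in range(200_000):
        w = v @ m
        w = w / w.sum()
        if np.max(np.abs(w - v)) < tol:
            return w
        v = w
    return v


class TestInitStageProportions:
    def test_unreachable_stages_get_zero_weight(self):
        matrix = TransitionMatrix(np.array([
            [0.9, 0.0, 0.0, 0.1],
            [0.0, 0.8, 0.0, 0.2],
            [0.0, 0.0, 0.7, 0.3],
            [0.0, 0.0, 0.0, 1.0],
        ]))
        projection = flat_projection(n_years=10)
        prevalence = PrevalenceCurve(np.full(N_AGES, 0.05))
        dist = init_stage_proportions(matrix, projection, prevalence)
        np.testing.assert_allclose(dist.proportions, [1.0, 0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_power_iteration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix = synthetic.random_progressive_matrix(rng)
        projection = flat_projection(n_years=20)
        prevalence = PrevalenceCurve(np.full(N_AGES, 0.05))
        dist = init_stage_proportions(matrix, projection, prevalence)
        oracle = power_iteration_oracle(matrix)
        np.testing.assert_allclose(dist.proportions, oracle, atol=1e-6)

    def test_independent_of_initial_split(self):
        rng = np.random.default_rng(42)
        matrix = synthetic.random_progressive_matrix(rng)
        projection = flat_projection(n_years=20)
        prevalence = PrevalenceCurve(np.full(N_AGES, 0.05))
        tol = 1e-8
        from_mild = init_stage_proportions(matrix, projection, prevalence,
                                           tolerance=tol,
                                           initial=np.array([1.0, 0.0, 0.0]))
        from_uniform = init_stage_proportions(matrix, projection, prevalence,
                                              tolerance=tol,
                                              initial=np.array([1.0, 1.0, 1.0]))
        assert np.max(np.abs(from_mild.proportions
                             - from_uniform.proportions)) < 2 * tol

    def test_no_survivors_raises(self):
        lethal = TransitionMatrix(np.array([
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 1.0],
        ]))
        projection = flat_projection(n_years=5)
        prevalence = PrevalenceCurve(np.zeros(N_AGES))
        with pytest.raises(ConvergenceError):
            init_stage_proportions(lethal, projection, prevalence)


# ---------------------------------------------------------------------------
# full projection properties
# ---------------------------------------------------------------------------


class TestRunProjection:
    def test_zero_prevalence_propagates_zero(self, progressive_matrix):
        projection = flat_projection(n_years=8)
        prevalence = PrevalenceCurve(np.zeros(N_AGES))
        result = run_projection_from_inputs(projection, prevalence,
                                            progressive_matrix)
        assert all(s.ad_total == 0.0 for s in result.trajectory)

    def test_stationary_projection_gives_constant_ad_totals(self):
        spec = synthetic.SyntheticSpec(seed=5, growth_65plus=0.0,
                                       growth_under65=0.0, decline_rate=0.0,
                                       n_years=20)
        projection = synthetic.generate_projection(spec)
        prevalence = synthetic.generate_prevalence(spec)
        transitions = synthetic.generate_transition_matrix(spec)
        result = run_projection_from_inputs(projection, prevalence, transitions)
        totals = np.array([s.ad_total for s in result.trajectory])
        assert np.max(np.abs(totals / totals[0] - 1.0)) < 1e-6

    def test_ad_population_scales_with_senior_growth(self):
        g = 0.02
        spec = synthetic.SyntheticSpec(seed=5, growth_65plus=g,
                                       growth_under65=0.0, decline_rate=0.0,
                                       decline_start=100, n_years=20)
        projection = synthetic.generate_projection(spec)
        prevalence = synthetic.generate_prevalence(spec)
        transitions = synthetic.generate_transition_matrix(spec)
        result = run_projection_from_inputs(projection, prevalence, transitions)
        totals = np.array([s.ad_total for s in result.trajectory])
        expected = totals[0] * (1.0 + g) ** np.arange(totals.size)
        np.testing.assert_allclose(totals, expected, rtol=1e-6)

    def test_deterministic_given_inputs(self):
        spec = synthetic.SyntheticSpec(seed=9, n_years=15)
        projection = synthetic.generate_projection(spec)
        prevalence = synthetic.generate_prevalence(spec)
        transitions = synthetic.generate_transition_matrix(spec)
        a = run_projection_from_inputs(projection, prevalence, transitions)
        b = run_projection_from_inputs(projection, prevalence, transitions)
        for sa, sb in zip(a.trajectory, b.trajectory):
            assert np.array_equal(sa.ad_counts, sb.ad_counts)
            assert np.array_equal(sa.healthy_counts, sb.healthy_counts)


# ---------------------------------------------------------------------------
# conservation property (randomised)
# ---------------------------------------------------------------------------


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    ad=hnp.arrays(np.float64, (N_AGES, 3), elements=st.floats(0, 500)),
    inc=hnp.arrays(np.float64, (N_AGES,), elements=st.floats(0, 0.2)),
    seed=st.integers(0, 10_000),
)
def test_one_step_conservation_and_nonnegativity(ad, inc, seed):
    """AD(t+1) = aged survivors of AD(t) + incident cases, exactly, and no
    negative counts, for arbitrary states, rates and progressive matrices."""
    rng = np.random.default_rng(seed)
    transitions = synthetic.random_progressive_matrix(rng)
    projection = flat_projection(n_years=2, count=100_000.0)
    state = ADState(2020, ad, np.zeros(N_AGES))
    incidence = IncidenceCurve(inc[None, :], np.array([2020]))
    nxt = simulate_step(state, projection, incidence, transitions)

    # independent recomputation of the step rule
    aged = np.zeros_like(ad)
    aged[1:] = ad[:-1]
    aged[-1] += ad[-1]
    survivors = aged @ transitions.survivor_matrix
    healthy = np.maximum(100_000.0 - survivors.sum(axis=1), 0.0)
    incident = healthy * inc
    # totals balance: survivors + incident cases, no other source or sink
    assert nxt.ad_total == pytest.approx(survivors.sum() + incident.sum(),
                                         rel=1e-12, abs=1e-9)
    assert np.all(nxt.ad_counts >= 0.0)
    assert np.all(nxt.healthy_counts >= 0.0)
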