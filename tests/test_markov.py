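"""Markov cohort engine tests: matrix composition, knockback,
untreated progression, mortality adjustment and trace invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hs

import drscreen as d
from drscreen import states as st
from drscreen.markov import ConstantOnset, build_transition_matrix


@pytest.fixture()
def zero_model(tables, life_table):
    """No onset hazard; useful for isolating mortality and schedules."""
    return d.TransitionModel(
        onset={"T1DM": ConstantOnset(0.0), "T2DM": ConstantOnset(0.0)},
        tables=tables,
        life_table=life_table,
    )


def _stratum(dtype="T1DM", age=40.0):
    return d.CohortStratum(dtype, age, {"hba1c": 8.7, "duration": 7.8})


class TestAdjustMortality:
    def test_closed_form_example(self):
        assert d.adjust_mortality(0.02, 1.0, 0.5) == pytest.approx(1 - 0.98**0.5, abs=1e-12)
        assert d.adjust_mortality(0.02, 1.0, 0.5) == pytest.approx(0.010050, abs=1e-6)

    def test_cap_at_certain_death(self):
        assert d.adjust_mortality(0.6, 2.0, 0.5) == 1.0

    def test_two_half_cycles_compound_to_annual(self):
        q = d.adjust_mortality(0.037, 1.5, 0.5)
        assert 1 - (1 - q) ** 2 == pytest.approx(min(0.037 * 1.5, 1.0), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="qx"):
            d.adjust_mortality(1.2, 1.0, 0.5)
        with pytest.raises(ValueError, match="multiplier"):
            d.adjust_mortality(0.1, 0.0, 0.5)


class TestKnockback:
    def test_minimal_state_mass_unchanged(self):
        dist = np.zeros(st.N_RDR)
        dist[0] = 0.7
        np.testing.assert_allclose(d.knockback_adjust(dist), dist)

    def test_definition_single_state(self):
        dist = np.zeros(st.N_RDR)
        dist[4] = 1.0
        out = d.knockback_adjust(dist)
        assert out[4] == 0.5 and out[3] == 0.5 and out.sum() == 1.0

    def test_mass_conserved_and_dominates_toward_lower_severity(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            dist = rng.dirichlet(np.ones(st.N_RDR)) * rng.uniform(0.1, 1.0)
            out = d.knockback_adjust(dist)
            assert out.sum() == pytest.approx(dist.sum(), abs=1e-12)
            assert np.all(out >= 0)
            # stochastic dominance: cumulative mass at low severities grows
            assert np.all(np.cumsum(out) >= np.cumsum(dist) - 1e-12)

    def test_negative_mass_rejected(self):
        dist = np.zeros(st.N_RDR)
        dist[1] = -0.1
        with pytest.raises(ValueError, match="negative"):
            d.knockback_adjust(dist)


class TestUntreatedProgression:
    def test_identity_transitions_leave_distribution_unchanged(self):
        dist = np.full(st.N_RDR, 0.1)
        np.testing.assert_allclose(d.untreated_progression(dist, np.eye(st.N_RDR)), dist)

    def test_shift_matrix_moves_two_steps(self):
        shift = np.zeros((st.N_RDR, st.N_RDR))
        for i in range(st.N_RDR - 1):
            shift[i, i + 1] = 1.0
        shift[-1, -1] = 1.0
        dist = np.zeros(st.N_RDR)
        dist[0] = 1.0
        out = d.untreated_progression(dist, shift)
        assert out[2] == 1.0

    def test_equals_matrix_square(self, tables):
        rng = np.random.default_rng(1)
        dist = rng.dirichlet(np.ones(st.N_RDR))
        np.testing.assert_allclose(
            d.untreated_progression(dist, tables.hes), dist @ np.linalg.matrix_power(tables.hes, 2)
        )

    def test_mass_conserved(self, tables):
        dist = np.full(st.N_RDR, 1.0 / st.N_RDR)
        assert d.untreated_progression(dist, tables.hes).sum() == pytest.approx(1.0, abs=1e-12)


class TestHesEntryDistribution:
    def test_degenerate_mix_identity_transitions(self):
        mix = np.zeros(st.N_RDR)
        mix[0] = 1.0
        out = d.build_hes_entry_distribution(mix, np.eye(st.N_RDR))
        np.testing.assert_allclose(out, mix)

    def test_uniform_mix_identity_transitions(self):
        mix = np.full(st.N_RDR, 0.1)
        np.testing.assert_allclose(d.build_hes_entry_distribution(mix, np.eye(st.N_RDR)), mix)

    def test_matches_hand_matrix_vector_product(self, tables):
        rng = np.random.default_rng(2)
        mix = rng.dirichlet(np.ones(st.N_RDR))
        out = d.build_hes_entry_distribution(mix, tables.hes)
        hand = mix.copy()
        for _ in range(2):
            hand = np.array([sum(hand[i] * tables.hes[i, j] for i in range(st.N_RDR)) for j in range(st.N_RDR)])
        hand /= hand.sum()
        np.testing.assert_allclose(out, hand, atol=1e-12)

    def test_zero_mass_rejected(self, tables):
        with pytest.raises(ValueError, match="zero mass"):
            d.build_hes_entry_distribution(np.zeros(st.N_RDR), tables.hes)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self, model, strata):
        for k in (0, 1, 3, 40):
            P = build_transition_matrix(model, d.ANNUAL, strata["T1DM"], k)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= 0.0

    def test_no_hazard_no_mortality_is_identity(self, tables):
        life = d.LifeTable(np.arange(12, 101), np.zeros(89))
        model = d.TransitionModel(
            onset={"T1DM": ConstantOnset(0.0)}, tables=tables, life_table=life
        )
        # also neutralise pre-RDR grade drift
        model.tables = d.TransitionTables(
            hes=tables.hes, rdr_entry=tables.rdr_entry, pre_rdr_minbdr=0.0,
            pre_rdr_modbdr=0.0, p_treat=tables.p_treat,
            treat_resources=tables.treat_resources,
        )
        P = build_transition_matrix(model, d.ANNUAL, _stratum(), 0)
        occ = np.zeros(st.N_STATES)
        occ[:3] = [0.5, 0.3, 0.2]
        np.testing.assert_allclose(occ @ P, occ, atol=1e-12)

    def test_detection_schedule_arithmetic(self):
        annual, biennial = d.ANNUAL, d.BIENNIAL
        assert [annual.is_screen_boundary(k) for k in range(1, 9)] == [
            False, True, False, True, False, True, False, True,
        ]
        assert [biennial.is_screen_boundary(k) for k in range(1, 9)] == [
            False, False, False, True, False, False, False, True,
        ]
        # annual screens are a superset: detection never happens later
        assert all(
            annual.is_screen_boundary(k) or not biennial.is_screen_boundary(k)
            for k in range(1, 200)
        )

    def test_eligibility_rule_adds_year_one_screen(self):
        s = d.StrategySpec("biennial", 2.0, eligibility_rule=True)
        assert s.is_screen_boundary(2) and s.is_screen_boundary(4)
        assert not s.is_screen_boundary(3)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            d.StrategySpec("bad", 0.75)

    def test_detection_routes_to_hes_only_at_screen_boundaries(self, model, strata):
        P_off = build_transition_matrix(model, d.BIENNIAL, strata["T1DM"], 0)
        P_on = build_transition_matrix(model, d.BIENNIAL, strata["T1DM"], 3)
        und, hes = st.I_UND, st.I_HES
        assert P_off[und, hes].sum() == 0.0
        assert P_on[und, und].sum() == 0.0 and P_on[und, hes].sum() > 0

    def test_competing_risks_composition_matches_brute_force(self, tables, life_table):
        """Two cycles of (event vs death) on the pre-RDR block equal the
        brute-force enumeration of all paths on a 3-state toy."""
        h, q = 0.12, 0.03
        life = d.LifeTable(np.arange(12, 101), np.full(89, 1 - (1 - q) ** 2))
        model = d.TransitionModel(
            onset={"T1DM": ConstantOnset(h)},
            tables=d.TransitionTables(
                hes=np.eye(st.N_RDR), rdr_entry=tables.rdr_entry,
                pre_rdr_minbdr=0.0, pre_rdr_modbdr=0.0,
            ),
            life_table=life,
            mortality_multipliers={"T1DM": 1.0},
        )
        occ = np.zeros(st.N_STATES)
        occ[0] = 1.0
        for k in range(2):  # cycles 0,1 (no screening boundary at k=1 for biennial)
            occ = occ @ build_transition_matrix(model, d.BIENNIAL, _stratum(), k)
        # brute force over 2 cycles: alive-no-event, alive-event, dead.
        # event paths: (event in cycle 1, survive both) or (no event then event)
        p_nothing = ((1 - q) * (1 - h)) ** 2
        p_event = (1 - q) * h * (1 - q) + (1 - q) * (1 - h) * (1 - q) * h
        p_dead = 1 - p_nothing - p_event
        assert occ[0] == pytest.approx(p_nothing, abs=1e-12)
        assert occ[st.I_UND].sum() == pytest.approx(p_event, abs=1e-12)
        assert occ[st.I_DEAD] == pytest.approx(p_dead, abs=1e-12)


class TestRunCohort:
    def test_zero_hazard_zero_mortality_constant_occupancy(self, tables):
        life = d.LifeTable(np.arange(12, 101), np.zeros(89))
        model = d.TransitionModel(
            onset={"T1DM": ConstantOnset(0.0)},
            tables=d.TransitionTables(
                hes=tables.hes, rdr_entry=tables.rdr_entry,
                pre_rdr_minbdr=0.0, pre_rdr_modbdr=0.0,
            ),
            life_table=life,
        )
        trace = d.run_cohort(model, d.ANNUAL, _stratum(age=80.0))
        np.testing.assert_allclose(
            trace.occupancy, np.broadcast_to(trace.occupancy[0], trace.occupancy.shape), atol=1e-12
        )

    def test_two_state_geometric_survival(self, tables):
        q_annual = 1 - (1 - 0.05) ** 2  # gives per-cycle q = 0.05 exactly
        life = d.LifeTable(np.arange(12, 101), np.full(89, q_annual))
        model = d.TransitionModel(
            onset={"T1DM": ConstantOnset(0.0)},
            tables=tables,
            life_table=life,
            mortality_multipliers={"T1DM": 1.0},
        )
        trace = d.run_cohort(model, d.ANNUAL, _stratum(age=20.0), max_cycles=30)
        alive = trace.alive_mass()
        np.testing.assert_allclose(alive, 0.95 ** np.arange(len(alive)), atol=1e-12)

    def test_occupancy_conserved_and_dead_monotone(self, model, strata):
        trace = d.run_cohort(model, d.BIENNIAL, strata["T1DM"])
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        dead = trace.state_series("Dead")
        assert np.all(np.diff(dead) >= -1e-12)

    def test_mortality_only_life_expectancy_matches_life_table(self, tables, life_table):
        """With all DR transitions zeroed the trace reproduces the
        life-table closed-form expectation."""
        model = d.TransitionModel(
            onset={"T2DM": ConstantOnset(0.0)},
            tables=d.TransitionTables(
                hes=tables.hes, rdr_entry=tables.rdr_entry,
                pre_rdr_minbdr=0.0, pre_rdr_modbdr=0.0,
            ),
            life_table=life_table,
            mortality_multipliers={"T2DM": 1.5},
        )
        stratum = d.CohortStratum("T2DM", 62.3, {})
        trace = d.run_cohort(model, d.ANNUAL, stratum, horizon_age=100.0)
        # closed form from the same q sequence
        age, le, surv = 62.3, 0.0, 1.0
        for k in range(trace.n_cycles):
            le += surv * st.CYCLE_YEARS
            q = d.adjust_mortality(life_table.annual_qx(age), 1.5, st.CYCLE_YEARS)
            surv *= 1 - q
            age += st.CYCLE_YEARS
        assert trace.life_expectancy() == pytest.approx(le, abs=1e-6)

    def test_annual_dominates_biennial_in_qalys_and_screen_costs(self, model, strata):
        for dtype in strata:
            ta = d.run_cohort(model, d.ANNUAL, strata[dtype])
            tb = d.run_cohort(model, d.BIENNIAL, strata[dtype])
            ca, ea = d.accumulate(ta, d.CostTable(), d.UtilityTable(), d.DiscountSpec(0.0))
            cb, eb = d.accumulate(tb, d.CostTable(), d.UtilityTable(), d.DiscountSpec(0.0))
            assert ea >= eb
            assert (
                ta.resources["screening_visits"].sum() >= tb.resources["screening_visits"].sum()
            )

    def test_non_stochastic_matrix_reports_cycle(self, tables, life_table):
        class BadOnset:
            def prob(self, stratum, t, dt):
                return 1.5 if t >= 2.0 else 0.01

        model = d.TransitionModel(
            onset={"T1DM": BadOnset()}, tables=tables, life_table=life_table
        )
        with pytest.raises(ValueError, match="onset probability"):
            d.run_cohort(model, d.ANNUAL, _stratum())

    def test_horizon_must_cover_a_cycle(self, model, strata):
        with pytest.raises(ValueError, match="horizon"):
            d.run_cohort(model, d.ANNUAL, strata["T2DM"], horizon_age=60.0)


@given(hs.floats(0.0, 1.0), hs.floats(0.5, 5.0))
def test_adjust_mortality_always_a_probability(qx, mult):
    q = d.adjust_mortality(qx, mult, st.CYCLE_YEARS)
    assert 0.0 <= q <= 1.0
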