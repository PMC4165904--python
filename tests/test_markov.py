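"""Cohort engine: hazard bridge, competing risks, trace invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from ceassay import (
    LifeTable,
    annual_prob_from_cumulative,
    chemo_adjusted_risk,
    run_subgroup_cohort,
    subgroup_spec,
)
from ceassay.markov import (
    DEAD_BREAST_CANCER,
    DEAD_OTHER,
    DISTANT_RECURRENCE,
    RECURRENCE_FREE,
    SubgroupSpec,
    apply_time_zero_events,
    transition_row_recurrence,
    transition_row_recurrence_free,
)


def flat_life_table(q, max_age=120):
    ages = np.arange(0, max_age + 1)
    return LifeTable(ages, np.full(ages.shape, q, dtype=float))


class TestHazardBridge:
    @pytest.mark.parametrize(
        "cum, horizon, expected",
        [
            (0.0, 10, 0.0),
            (0.248, 10, 0.0280995),  # 1 - 0.752**0.1
            (0.033, 10, 0.0033500),  # 1 - 0.967**0.1
        ],
    )
    def test_known_values(self, cum, horizon, expected):
        assert annual_prob_from_cumulative(cum, horizon) == pytest.approx(
            expected, abs=5e-7
        )

    @given(cum=st.floats(0.0, 0.95), horizon=st.floats(1.0, 50.0))
    @hsettings(max_examples=200, derandomize=True)
    def test_inverse_property(self, cum, horizon):
        """Compounding the annual probability over the horizon recovers the
        cumulative risk."""
        p = annual_prob_from_cumulative(cum, horizon)
        assert 1.0 - (1.0 - p) ** horizon == pytest.approx(cum, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            annual_prob_from_cumulative(1.0, 10)
        with pytest.raises(ValueError):
            annual_prob_from_cumulative(0.2, 0)
        with pytest.raises(ValueError):
            annual_prob_from_cumulative(-0.1, 10)


class TestChemoAdjustedRisk:
    @pytest.mark.parametrize(
        "risk, rrr, treated, expected",
        [
            (0.248, 0.74, True, 0.06448),
            (0.033, 0.0, True, 0.033),  # no chemo benefit in the low-risk group
            (0.137, 0.39, False, 0.137),  # untreated identity
        ],
    )
    def test_examples(self, risk, rrr, treated, expected):
        assert chemo_adjusted_risk(risk, rrr, treated) == pytest.approx(
            expected, abs=1e-12
        )


def make_spec(p_rec, start_age=50.0, horizon=None):
    return SubgroupSpec(
        label="high",
        chemo_treated=False,
        annual_recurrence_prob=p_rec,
        recurrence_active_horizon=horizon,
        start_age=start_age,
    )


class TestTransitionRows:
    def test_recurrence_free_absorbing_free(self, base):
        row = transition_row_recurrence_free(
            50.0, make_spec(0.0), flat_life_table(0.0), base.settings
        )
        assert row[RECURRENCE_FREE] == pytest.approx(1.0)

    def test_recurrence_free_single_risk_passthrough(self, base):
        row = transition_row_recurrence_free(
            50.0, make_spec(0.0), flat_life_table(0.01), base.settings
        )
        assert row[DEAD_OTHER] == pytest.approx(0.01, abs=1e-12)

    def test_recurrence_free_two_risk_decomposition(self, base):
        """Rate-scale competing risks: joint survival multiplies, causes are
        apportioned by cause-specific hazard."""
        p1, q = 0.0281, 0.002
        row = transition_row_recurrence_free(
            50.0, make_spec(p1), flat_life_table(q), base.settings
        )
        r1, r2 = -np.log(1 - p1), -np.log(1 - q)
        total = 1 - (1 - p1) * (1 - q)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)
        assert row[DISTANT_RECURRENCE] == pytest.approx(total * r1 / (r1 + r2), rel=1e-12)
        assert row[DEAD_OTHER] == pytest.approx(total * r2 / (r1 + r2), rel=1e-12)

    def test_horizon_truncates_recurrence_hazard(self, base):
        spec = make_spec(0.05, start_age=50.0, horizon=10)
        row = transition_row_recurrence_free(
            61.0, spec, flat_life_table(0.0), base.settings
        )
        assert row[DISTANT_RECURRENCE] == 0.0

    def test_recurrence_row_base_mortality(self, base):
        row = transition_row_recurrence(50.0, base.settings, flat_life_table(0.0))
        assert row[DEAD_BREAST_CANCER] == pytest.approx(0.40, abs=1e-12)

    def test_recurrence_row_competing_product(self, base):
        row = transition_row_recurrence(50.0, base.settings, flat_life_table(0.01))
        total_death = row[DEAD_BREAST_CANCER] + row[DEAD_OTHER]
        assert total_death == pytest.approx(1 - 0.6 * 0.99, abs=1e-12)

    def test_recurrence_row_no_mortality(self, base):
        s = dataclasses.replace(
            base.settings,
            post_recurrence_mortality_annual=base.settings.post_recurrence_mortality_annual.with_base(
                0.0
            ),
        )
        row = transition_row_recurrence(50.0, s, flat_life_table(0.0))
        assert row[DISTANT_RECURRENCE] == pytest.approx(1.0)


class TestTimeZero:
    def test_fatal_toxicity_product(self, base):
        row = apply_time_zero_events(48 / 104, base.settings)
        assert row[DEAD_BREAST_CANCER] == pytest.approx(48 / 104 * 0.002, abs=1e-12)
        assert row.sum() == pytest.approx(1.0)

    def test_no_chemo_or_no_toxicity(self, base):
        assert apply_time_zero_events(0.0, base.settings)[RECURRENCE_FREE] == 1.0
        s = dataclasses.replace(
            base.settings,
            fatal_toxicity_risk=base.settings.fatal_toxicity_risk.with_base(0.0),
        )
        assert apply_time_zero_events(1.0, s)[RECURRENCE_FREE] == 1.0


class TestRunSubgroup:
    def test_no_risk_no_mortality_stays_recurrence_free(self, base):
        s = dataclasses.replace(
            base.settings,
            fatal_toxicity_risk=base.settings.fatal_toxicity_risk.with_base(0.0),
        )
        trace = run_subgroup_cohort(make_spec(0.0), 0.0, flat_life_table(0.0), s)
        assert np.allclose(trace.occupancy[:, RECURRENCE_FREE], 1.0)

    def test_certain_death_absorbs_in_one_cycle(self, base):
        trace = run_subgroup_cohort(
            make_spec(1e-9), 0.0, flat_life_table(1.0), base.settings
        )
        assert trace.occupancy[1, DEAD_OTHER] == pytest.approx(1.0, abs=1e-8)
        assert trace.n_cycles == 1  # extinction stops the run

    def test_against_hand_rolled_matrix_product(self, base):
        """10 steps of an explicit 4x4 transition-matrix chain reproduce the
        engine trace for the high-risk untreated subgroup."""
        settings = base.settings
        lt = base.life_table
        spec = subgroup_spec(base.group("high"), False, settings)
        trace = run_subgroup_cohort(spec, 0.0, lt, settings)

        state = np.array([1.0, 0.0, 0.0, 0.0])
        p_rec = 1 - (1 - 0.248) ** 0.1
        p_bc = settings.post_recurrence_mortality_annual.base
        for k in range(10):
            age = settings.start_age.base + k
            q = lt.q(age)
            r1, r2 = -np.log(1 - p_rec), -np.log(1 - q)
            tot = 1 - (1 - p_rec) * (1 - q)
            a_rec, a_oth = tot * r1 / (r1 + r2), tot * r2 / (r1 + r2)
            rb = -np.log(1 - p_bc)
            totr = 1 - (1 - p_bc) * (1 - q)
            b_bc, b_oth = totr * rb / (rb + r2), totr * r2 / (rb + r2)
            M = np.array(
                [
                    [1 - a_rec - a_oth, a_rec, 0.0, a_oth],
                    [0.0, 1 - b_bc - b_oth, b_bc, b_oth],
                    [0.0, 0.0, 1.0, 0.0],
                    [0.0, 0.0, 0.0, 1.0],
                ]
            )
            state = state @ M
        assert np.allclose(state, trace.occupancy[10], atol=1e-12)

    def test_intermediate_zero_risk_degenerate(self, base):
        """The Japan intermediate group has 0% baseline risk; recurrence
        occupancy must stay identically zero for any RRR."""
        for treated in (False, True):
            spec = subgroup_spec(base.group("intermediate"), treated, base.settings)
            trace = run_subgroup_cohort(
                spec, 1.0 if treated else 0.0, base.life_table, base.settings
            )
            assert np.all(trace.occupancy[:, DISTANT_RECURRENCE] == 0.0)

    def test_trace_export_columns(self, base, tmp_path):
        spec = subgroup_spec(base.group("low"), False, base.settings)
        trace = run_subgroup_cohort(spec, 0.0, base.life_table, base.settings)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "cycle,age,recurrence_free,distant_recurrence,dead_bc,dead_other"


class TestConservation:
    @given(
        risk=st.floats(0.0, 0.378),
        rrr=st.floats(0.0, 0.87),
        q=st.floats(0.0, 0.2),
        mort=st.floats(0.20, 0.60),
        tox=st.floats(0.0, 0.004),
        treated=st.booleans(),
    )
    @hsettings(max_examples=60, derandomize=True, deadline=None)
    def test_rows_sum_to_one_across_sensitivity_ranges(
        self, base, risk, rrr, q, mort, tox, treated
    ):
        s = dataclasses.replace(
            base.settings,
            post_recurrence_mortality_annual=base.settings.post_recurrence_mortality_annual.with_base(
                mort
            ),
            fatal_toxicity_risk=base.settings.fatal_toxicity_risk.with_base(tox),
        )
        p = annual_prob_from_cumulative(chemo_adjusted_risk(risk, rrr, treated), 10)
        spec = SubgroupSpec("high", treated, p, None, s.start_age.base)
        trace = run_subgroup_cohort(spec, 1.0 if treated else 0.0, flat_life_table(q), s)
        sums = trace.occupancy.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-9)
        dead = trace.occupancy[:, [DEAD_BREAST_CANCER, DEAD_OTHER]]
        assert np.all(np.diff(dead, axis=0) >= -1e-12)

    def test_ten_year_cumulative_recurrence_inverts_bridge(self, base):
        """With a 10-year-limited hazard and no competing mortality, the
        cumulative recurrence at cycle 10 equals the 10-year risk."""
        for risk in (0.033, 0.248, 0.378):
            p = annual_prob_from_cumulative(risk, 10)
            spec = make_spec(p, horizon=10)
            s = dataclasses.replace(
                base.settings,
                post_recurrence_mortality_annual=base.settings.post_recurrence_mortality_annual.with_base(
                    0.0
                ),
            )
            trace = run_subgroup_cohort(spec, 0.0, flat_life_table(0.0), s)
            cum_rec = trace.occupancy[10, DISTANT_RECURRENCE]
            assert cum_rec == pytest.approx(risk, abs=1e-9)
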