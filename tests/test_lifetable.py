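"""Life-table construction: interval assignment, final-interval choice,
the Table-1-style equations, and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dogyears as dy
from dogyears.errors import DataError

RELAXED = dy.EligibilityRule(min_per_interval=1, min_last_interval=1)


class TestAssignIntervals:
    def test_fractions_kept(self):
        assert dy.assign_intervals([0.5, 0.5, 1.2]) == {
            0: [0.5, 0.5],
            1: [pytest.approx(0.2)],
        }

    def test_integer_lifespan_on_boundary(self):
        assert dy.assign_intervals([3.0]) == {3: [0.0]}

    def test_counts_conserved_on_random_input(self, rng):
        t = rng.gamma(3.0, 3.0, size=500)
        binned = dy.assign_intervals(t)
        assert sum(len(v) for v in binned.values()) == 500

    def test_negative_lifespan_rejected(self):
        with pytest.raises(DataError):
            dy.assign_intervals([1.0, -0.1])


class TestChooseFinalInterval:
    def brute_force(self, counts, rule):
        """Oracle: try every candidate n explicitly."""
        xs = range(max(counts) + 1)
        candidates = [
            n for n in xs
            if sum(c for x, c in counts.items() if x >= n) >= rule.min_last_interval
        ]
        if not candidates:
            return None, False
        n = max(candidates)
        ok = all(counts.get(x, 0) >= rule.min_per_interval for x in range(n))
        return n, ok

    def test_tail_sum_rule(self):
        n, eligible = dy.choose_final_interval({0: 5, 1: 4, 2: 12})
        assert (n, eligible) == (2, True)

    def test_sparse_early_interval_ineligible(self):
        n, eligible = dy.choose_final_interval({0: 2, 1: 20})
        assert (n, eligible) == (1, False)

    def test_total_below_last_floor_ineligible(self):
        n, eligible = dy.choose_final_interval({0: 4, 1: 4})
        assert not eligible

    def test_reference_counts_eligible_at_twenty(self, reference_table):
        counts = {r.x: r.d for r in reference_table.rows}
        n, eligible = dy.choose_final_interval(counts)
        assert (n, eligible) == (20, True)
        assert reference_table.rows[20].d == 23

    @given(
        st.dictionaries(st.integers(0, 12), st.integers(0, 30), min_size=1, max_size=10),
        st.integers(1, 4),
        st.integers(1, 15),
    )
    @settings(derandomize=True, max_examples=200)
    def test_agrees_with_brute_force(self, counts, min_per, min_last):
        counts = {x: c for x, c in counts.items() if c > 0} or {0: 1}
        rule = dy.EligibilityRule(min_per, min_last)
        want_n, want_ok = self.brute_force(counts, rule)
        got_n, got_ok = dy.choose_final_interval(counts, rule)
        if want_n is None:
            assert not got_ok
        else:
            assert (got_n, got_ok) == (want_n, want_ok)


class TestBuildLifeTable:
    def test_single_interval_cohort(self):
        t = dy.build_life_table([0.5] * 4, rule=RELAXED)
        row = t.rows[0]
        assert (row.d, row.l, row.q_hat, row.a_hat, t.e(0)) == (4, 4, 1.0, 0.5, 0.5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(DataError):
            dy.build_life_table([])

    def test_e0_is_cohort_mean_lifespan(self, rng):
        t = rng.gamma(4.0, 2.8, size=1000)
        table = dy.build_life_table(t, rule=RELAXED)
        assert table.e(0) == pytest.approx(t.mean(), abs=1e-12)
        assert table.rows[0].T == pytest.approx(t.sum(), rel=1e-12)
        assert sum(r.d for r in table.rows) == 1000

    def test_e_x_is_mean_residual_lifespan(self, rng):
        """Brute-force oracle: e_x == mean(t - x | t >= x) at every age."""
        for n in (20, 200, 500):
            t = rng.gamma(3.0, 3.0, size=n)
            table = dy.build_life_table(t, rule=RELAXED)
            for row in table.rows:
                survivors = t[t >= row.x]
                assert row.l == survivors.size
                assert row.e_hat == pytest.approx(
                    (survivors - row.x).mean(), abs=1e-10
                )

    def test_final_row_identities(self, rng):
        t = rng.gamma(4.0, 2.5, size=400)
        table = dy.build_life_table(t, rule=RELAXED)
        final = table.rows[-1]
        assert final.x == table.final_open_start
        assert final.l == final.d
        assert final.q_hat == 1.0
        assert final.e_hat == pytest.approx(final.a_hat)

    def test_open_row_a_may_exceed_one(self):
        t = dy.build_life_table([0.1, 0.2, 0.3, 5.0, 6.0, 7.0], rule=dy.EligibilityRule(1, 4))
        final = t.rows[-1]
        assert final.x == 0  # tail-sum rule pools everything
        assert final.a_hat > 1

    def test_gap_interval_with_no_deaths(self):
        # deaths at 0.x and 2.x only: interval 1 has d = 0, a undefined
        t = dy.build_life_table([0.5, 0.5, 2.5, 2.5, 2.5], rule=RELAXED)
        row1 = t.rows[1]
        assert (row1.d, row1.a_hat) == (0, None)
        assert row1.L == row1.l  # everyone lives the whole year
        assert t.eligible is False  # a 0-death closed row is below any floor

    def test_ineligible_cohort_flagged_not_raised(self):
        table = dy.build_life_table([0.5, 1.5, 1.6], rule=dy.EligibilityRule(3, 11))
        assert table.eligible is False
        assert table.n_animals == 3

    def test_mean_residual_decreases_under_increasing_hazard(self):
        sched = dy.HazardSchedule(form="gompertz_makeham", lam=0.0, a=0.02, b=0.35)
        t = dy.sample_lifespans(sched, 30_000, seed=7)
        table = dy.build_life_table(t)
        es = [r.e_hat for r in table.rows if r.x <= table.final_open_start]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_agrees_with_kaplan_meier_restricted_mean(self, rng):
        """Independent oracle: with every death observed, the area under the
        Kaplan-Meier curve equals the cohort mean lifespan, i.e. e_0."""
        lifelines = pytest.importorskip("lifelines")
        from lifelines.utils import restricted_mean_survival_time

        t = rng.gamma(4.0, 2.5, size=300)
        km = lifelines.KaplanMeierFitter().fit(t, event_observed=np.ones_like(t))
        rmst = restricted_mean_survival_time(km, t=float(t.max()))
        table = dy.build_life_table(t, rule=RELAXED)
        assert table.e(0) == pytest.approx(rmst, rel=1e-9)


class TestBuildFromAggregates:
    def test_reference_expectancies_at_printed_precision(self, reference_table):
        assert round(reference_table.e(1), 2) == 10.41
        assert round(reference_table.e(10), 2) == 3.28

    def test_single_open_row_identity(self):
        t = dy.build_from_aggregates([10], [0.46])
        assert t.e(0) == pytest.approx(0.46)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError, match="mismatch"):
            dy.build_from_aggregates([5, 11], [0.5])

    def test_matches_individual_route_on_degenerate_lifespans(self, rng):
        """Aggregates (d, a) expanded to one lifespan per dog rebuild the
        identical table through the individual-lifespan route."""
        d = [5, 7, 9, 15]
        a = [0.3, 0.5, 0.25, 0.8]
        from_agg = dy.build_from_aggregates(d, a, rule=RELAXED)
        lifespans = np.concatenate(
            [np.full(di, x + ai) for x, (di, ai) in enumerate(zip(d, a))]
        )
        from_ind = dy.build_life_table(lifespans, rule=dy.EligibilityRule(1, 15))
        for ra, ri in zip(from_agg.rows, from_ind.rows):
            assert (ra.d, ra.l) == (ri.d, ri.l)
            assert ra.e_hat == pytest.approx(ri.e_hat, abs=1e-12)
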