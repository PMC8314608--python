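"""KM / log-rank machinery: hand and brute-force oracles, an independent
lifelines cross-check, stratification conventions, and the screen contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import targetfunnel as tf
from targetfunnel.survival import run_survival_screen

from conftest import brute_force_logrank


class TestKM:
    def test_no_censoring_equals_empirical_survival(self):
        km = tf.km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(km.event_times, [1, 2, 3])
        assert np.allclose(km.survival_prob, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_at_one(self):
        km = tf.km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert km.event_times.size == 0  # S(t) = 1 everywhere

    def test_hand_computed_product(self):
        # 8 subjects, interleaved censoring; hand product-limit:
        # t=1: d=1 n=8 -> 7/8 ; t=3: d=2 n=6 -> 7/8*4/6 ; t=5: d=1 n=3 -> *2/3
        times = [1, 2, 3, 3, 4, 5, 6, 7]
        events = [1, 0, 1, 1, 0, 1, 0, 0]
        km = tf.km_estimate(times, events)
        assert np.allclose(km.event_times, [1, 3, 5])
        assert np.allclose(km.survival_prob,
                           [7 / 8, 7 / 8 * 4 / 6, 7 / 8 * 4 / 6 * 2 / 3])

    def test_events_processed_before_censorings_at_ties(self):
        # censored subject at t=2 is still at risk for the t=2 event
        km = tf.km_estimate([1, 2, 2, 3], [1, 1, 0, 1])
        assert np.allclose(km.survival_prob, [3 / 4, 3 / 4 * 2 / 3, 0.0])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 40).round(1) + 0.1
        e = rng.random(40) < 0.6
        km = tf.km_estimate(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(km.event_times, km.survival_prob):
            assert ref.predict(ti) == pytest.approx(si, abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            tf.km_estimate([0.0, 1.0], [True, True])


class TestLogRank:
    def _random_cohort(self, rng, n):
        t = rng.exponential(5, n).round(1) + 0.1   # force ties
        e = rng.random(n) < 0.7
        g = rng.random(n) < 0.5
        if g.all() or not g.any():
            g[0] = ~g[0]
        return t, e, g

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        t, e, g = self._random_cohort(rng, 25)
        a = tf.logrank_test(np.where(g, "x", "y"), t, e)
        b = tf.logrank_test(np.where(g, "y", "x"), t, e)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_identical_groups_statistic_zero(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        e = np.array([1, 1, 0, 1] * 2, bool)
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = tf.logrank_test(g, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_events_gives_p_one(self):
        res = tf.logrank_test(["a", "a", "b", "b"], [1, 2, 3, 4], [0, 0, 0, 0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            tf.logrank_test(["a"] * 4, [1, 2, 3, 4], [1, 1, 1, 1])

    def test_twelve_subject_fixture_matches_brute_force(self):
        t = np.array([1, 1, 2, 3, 3, 4, 5, 5, 6, 7, 8, 9], float)
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1, 0, 1, 1, 0], bool)
        g = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0], bool)
        O1, E1, V, stat = brute_force_logrank(t, e, g)
        res = tf.logrank_test(np.where(g, "high", "low"), t, e)
        assert res.statistic == pytest.approx(stat, abs=1e-12)
        assert res.observed["high"] == pytest.approx(O1)
        assert res.expected["high"] == pytest.approx(E1)

    def test_expected_events_sum_to_observed(self):
        rng = np.random.default_rng(5)
        t, e, g = self._random_cohort(rng, 30)
        res = tf.logrank_test(np.where(g, "a", "b"), t, e)
        assert sum(res.expected.values()) == pytest.approx(sum(res.observed.values()))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_property_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        t, e, g = self._random_cohort(rng, n)
        _, _, _, stat = brute_force_logrank(t, e, g)
        res = tf.logrank_test(np.where(g, "a", "b"), t, e)
        assert res.statistic == pytest.approx(stat, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll
        rng = np.random.default_rng(8)
        for _ in range(20):
            t, e, g = self._random_cohort(rng, 40)
            res = tf.logrank_test(np.where(g, "a", "b"), t, e)
            ref = ll(t[g], t[~g], e[g], e[~g])
            assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_direction_names_worse_group(self):
        # group "high" dies fast -> more observed than expected events
        t = np.r_[np.full(20, 1.0), np.full(20, 10.0)]
        e = np.ones(40, bool)
        labels = np.r_[["high"] * 20, ["low"] * 20]
        assert tf.logrank_test(labels, t, e).direction == "high"


class TestStratification:
    def test_78th_percentile_of_1_to_100(self):
        labels = tf.stratify_by_quantile(np.arange(1.0, 101.0), 0.78)
        assert (labels == "high").sum() == 22

    def test_median_of_four_strictly_greater(self):
        labels = tf.stratify_by_quantile(np.array([1.0, 2, 3, 4]), 0.5)
        assert list(labels) == ["low", "low", "high", "high"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        perm = rng.permutation(30)
        a = tf.stratify_by_quantile(v, 0.4)
        b = tf.stratify_by_quantile(v[perm], 0.4)
        assert (a[perm] == b).all()

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            tf.stratify_by_quantile(np.ones(10), 0.5)

    @pytest.mark.parametrize("q", [-0.1, 0.0, 1.0, 1.5])
    def test_percentile_range(self, q):
        with pytest.raises(ValueError):
            tf.stratify_by_quantile(np.arange(10.0), q)

    @pytest.mark.parametrize("irs,label", [(2, "low"), (3, "high"), (0, "low"), (12, "high")])
    def test_irs_boundaries(self, irs, label):
        assert tf.stratify_by_irs([irs])[0] == label

    def test_irs_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tf.stratify_by_irs([13])


class TestBonferroni:
    def test_definition(self):
        assert np.allclose(tf.bonferroni_adjust([0.01, 0.2]), [0.02, 0.4])

    def test_cap_at_one(self):
        assert tf.bonferroni_adjust([0.9], m=5)[0] == 1.0

    def test_single_test_identity(self):
        assert tf.bonferroni_adjust([0.37])[0] == pytest.approx(0.37)

    def test_never_decreases(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 50)
        assert (tf.bonferroni_adjust(p) >= p).all()


class TestScreen:
    def _planted_cohort(self, seed, n=300, n_cand=20, n_planted=3):
        genes = [f"P{i}" for i in range(n_planted)] + \
                [f"N{i}" for i in range(n_cand - n_planted)]
        spec = tf.CompendiumSpec(
            n_genes=n_cand, n_tumor=n, tissues=(("x", 5),),
            planted_overexpressed=tuple((g, 0.0) for g in genes), seed=seed)
        expr = tf.generate_expression_compendium(spec)
        cohort = tf.generate_survival_cohort(expr, tf.CohortSpec(
            n_patients=n, baseline_hazard=0.1,
            planted_prognostic=tuple((f"P{i}", np.log(3.0), 0.78)
                                     for i in range(n_planted)),
            censoring_rate=0.02, max_followup=120.0, seed=seed + 1))
        return genes, cohort

    def test_planted_sensitivity(self):
        # planted-truth recovery over replicates; HR=3 at q=0.78, n=300
        hits, truths, reps_with_fp = 0, 0, 0
        for seed in range(25):
            genes, cohort = self._planted_cohort(seed)
            res = run_survival_screen(genes, cohort, percentile=0.78)
            passed = set(res.loc[res["passes"], "gene_id"])
            truths += 3
            hits += len(passed & {"P0", "P1", "P2"})
            reps_with_fp += bool(passed - {"P0", "P1", "P2"})
        assert hits / truths >= 0.9
        assert reps_with_fp <= 4  # FWER <= 0.05 plus binomial slack at 25 reps

    def test_untested_genes_reported_not_failed(self):
        genes, cohort = self._planted_cohort(0)
        res = run_survival_screen(genes + ["ABSENT"], cohort)
        row = res[res["gene_id"] == "ABSENT"].iloc[0]
        assert not row["tested"] and not row["passes"]
        assert res.attrs["m_tested"] == len(genes)

    def test_alpha_threshold_log10_equivalence(self):
        # adjusted p < 0.05 iff -log10(adjusted p) > 1.3 (to printed precision)
        genes, cohort = self._planted_cohort(3)
        res = run_survival_screen(genes, cohort)
        tested = res[res["tested"]]
        for _, row in tested.iterrows():
            if row["direction"] == "high":
                assert row["passes"] == (-np.log10(row["adjusted_p"]) > -np.log10(0.05))
        assert -np.log10(0.05) == pytest.approx(1.3, abs=0.002)

    def test_scan_policy_reports_minimum_p(self):
        genes, cohort = self._planted_cohort(1, n=120, n_cand=5, n_planted=1)
        grid = [0.3, 0.5, 0.7]
        scan = run_survival_screen(genes, cohort, percentile=grid)
        for q in grid:
            fixed = run_survival_screen(genes, cohort, percentile=q)
            merged = scan.set_index("gene_id")["raw_p"]
            for g in genes:
                assert merged[g] <= fixed.set_index("gene_id")["raw_p"][g] + 1e-12
        assert "optimistic" in scan.attrs["note"]

    def test_empty_candidates(self):
        _, cohort = self._planted_cohort(0, n=50, n_cand=3, n_planted=1)
        res = run_survival_screen([], cohort)
        assert len(res) == 0

    def test_deterministic(self):
        genes, cohort = self._planted_cohort(7)
        a = run_survival_screen(genes, cohort)
        b = run_survival_screen(genes, cohort)
        pd.testing.assert_frame_equal(a, b)
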