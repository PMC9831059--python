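import numpy as np
import pytest
from scipy import stats

import oracle
from conftest import make_matrix
from isoswitch.core_data import relative_abundance
from isoswitch.switch_detection import (
    DetectionConfig,
    adjust_pvalues,
    detect_isoform_switches,
    diff_abundance,
    dissimilarity,
    domain_gain_loss,
    event_importance,
    events_to_frame,
    find_switch_points,
    switch_probability,
)
from isoswitch.switch_detection import _interval_bounds
from isoswitch.switch_detection import test_switch_replicated as mwu_switch_test
from isoswitch.switch_detection import test_switch_single_replicate as perm_switch_test


def courses_to_matrix(Ia, Ib):
    """Build a 2-isoform TimeCourseMatrix whose fractions equal Ia, Ib."""
    Ia, Ib = np.asarray(Ia, dtype=float), np.asarray(Ib, dtype=float)
    T, R = Ia.shape
    scale = 100.0
    values = np.vstack([Ia.reshape(-1) * scale, Ib.reshape(-1) * scale])
    return make_matrix(values, {"g.a": "g", "g.b": "g"}, n_replicates=R)


class TestFindSwitchPoints:
    def test_clean_flip(self):
        Ia = [[0.7], [0.3]]
        Ib = [[0.3], [0.7]]
        I = relative_abundance(courses_to_matrix(Ia, Ib))
        pts = find_switch_points(I, "g", "g.a", "g.b", 0.6)
        assert len(pts) == 1
        assert pts[0].time_index == 0
        assert pts[0].replicate_support == 1.0

    def test_parallel_courses_no_points(self):
        Ia = [[0.7], [0.6], [0.7]]
        Ib = [[0.3], [0.4], [0.3]]
        I = relative_abundance(courses_to_matrix(Ia, Ib))
        assert find_switch_points(I, "g", "g.a", "g.b", 0.6) == []

    def test_support_below_threshold_not_reported(self):
        # crossing in 2 of 4 replicates -> support 0.5 < 0.6
        Ia = np.array([[0.7, 0.7, 0.7, 0.7], [0.3, 0.3, 0.7, 0.7]])
        Ib = 1.0 - Ia
        I = relative_abundance(courses_to_matrix(Ia, Ib))
        assert find_switch_points(I, "g", "g.a", "g.b", 0.6) == []
        pts = find_switch_points(I, "g", "g.a", "g.b", 0.5)
        assert len(pts) == 1 and pts[0].replicate_support == 0.5

    def test_wrong_gene_raises(self, two_isoform_switch):
        I = relative_abundance(two_isoform_switch)
        with pytest.raises(ValueError):
            find_switch_points(I, "other", "g1.t1", "g1.t2", 0.6)

    def test_matches_oracle_random(self, rng):
        for _ in range(50):
            T, R = rng.integers(2, 6), rng.integers(1, 4)
            Ia = rng.random((T, R))
            Ib = 1.0 - Ia
            I = relative_abundance(courses_to_matrix(Ia, Ib))
            got = {(p.time_index, p.replicate_support)
                   for p in find_switch_points(I, "g", "g.a", "g.b", 0.0)}
            want = {(s, sup) for s, sup in oracle.crossings(Ia.tolist(), Ib.tolist()) if sup > 0}
            got_nonzero = {(s, sup) for s, sup in got if sup > 0}
            assert got_nonzero == want


class TestSwitchProbability:
    def test_clean_switch_is_one(self):
        Ia = np.array([[0.7], [0.8], [0.2]])
        Ib = 1.0 - Ia
        assert switch_probability(Ia, Ib, range(0, 2), range(2, 3)) == 1.0

    def test_hand_enumeration(self):
        # 1 time point each side, 3 reps: higher in 2/3 before, lower 3/3 after
        Ia = np.array([[0.6, 0.6, 0.4], [0.3, 0.2, 0.1]])
        Ib = 1.0 - Ia
        p = switch_probability(Ia, Ib, range(0, 1), range(1, 2))
        assert p == pytest.approx((2 / 3 + 1.0) / 2)

    def test_random_orderings_near_half(self, rng):
        Ia = rng.random((400, 1))
        Ib = rng.random((400, 1))
        p = switch_probability(Ia, Ib, range(0, 200), range(200, 400))
        assert abs(p - 0.5) < 0.1

    def test_empty_interval_raises(self):
        Ia = np.array([[0.7], [0.3]])
        with pytest.raises(ValueError):
            switch_probability(Ia, 1 - Ia, range(0, 0), range(1, 2))


class TestDiffAbundance:
    def test_arithmetic(self):
        Ia = np.array([[0.3, 0.3], [0.5, 0.5]])
        Ib = np.array([[0.5, 0.5], [0.3, 0.3]])
        assert diff_abundance(Ia, Ib, 0) == pytest.approx(0.2)

    def test_no_change_is_zero(self):
        Ia = np.array([[0.4], [0.4]])
        assert diff_abundance(Ia, 1 - Ia, 0) == 0.0

    def test_matches_oracle(self, rng):
        for _ in range(30):
            Ia, Ib = rng.random((4, 3)), rng.random((4, 3))
            s = int(rng.integers(0, 3))
            assert diff_abundance(Ia, Ib, s) == pytest.approx(
                oracle.diff_abundance(Ia.tolist(), Ib.tolist(), s)
            )


class TestEventImportance:
    def test_top_two_even_split_is_one(self):
        Ia = np.array([[0.5], [0.5]])
        Ib = np.array([[0.5], [0.5]])
        gene_max = np.array([[0.5], [0.5]])
        assert event_importance(Ia, Ib, gene_max, 0) == pytest.approx(1.0)

    def test_low_pair_bounded(self):
        # both switching isoforms at <= 10% of the dominant isoform
        Ia = np.array([[0.05], [0.04]])
        Ib = np.array([[0.04], [0.05]])
        gene_max = np.array([[0.9], [0.9]])
        assert event_importance(Ia, Ib, gene_max, 0) <= 0.1

    def test_two_isoform_gene_at_least_half(self, rng):
        # with 2 isoforms one of the pair IS the max at each time point
        for _ in range(50):
            Ia = rng.random((2, 2))
            Ib = 1.0 - Ia
            gene_max = np.maximum(Ia, Ib)
            assert event_importance(Ia, Ib, gene_max, 0) >= 0.5

    def test_zero_gene_abundance_gives_nan(self):
        Ia = np.array([[0.0], [0.5]])
        Ib = np.array([[0.0], [0.5]])
        gene_max = np.array([[0.0], [0.5]])
        assert np.isnan(event_importance(Ia, Ib, gene_max, 0))


class TestDissimilarity:
    def test_identical_courses_zero(self):
        Ia = np.array([[0.1], [0.5], [0.9]])
        assert dissimilarity(Ia, Ia.copy()) == pytest.approx(0.0)

    def test_anticorrelated_zero_under_r2(self):
        Ia = np.array([[0.1], [0.5], [0.9]])
        Ib = 1.0 - Ia
        assert dissimilarity(Ia, Ib, "r2") == pytest.approx(0.0, abs=1e-12)
        assert dissimilarity(Ia, Ib, "anticorr") == pytest.approx(1.0)

    def test_uncorrelated_near_one(self, rng):
        Ia, Ib = rng.random((2000, 1)), rng.random((2000, 1))
        assert dissimilarity(Ia, Ib) > 0.9

    def test_zero_variance_nan(self):
        Ia = np.array([[0.5], [0.5]])
        Ib = np.array([[0.2], [0.4]])
        assert np.isnan(dissimilarity(Ia, Ib))


class TestReplicatedTest:
    def test_identical_distributions_p_near_one(self):
        course = np.tile([0.4, 0.5, 0.6], (6, 1))
        p = mwu_switch_test(course, 1 - course, range(0, 3), range(3, 6))
        assert p > 0.9

    def test_complete_separation_small_p(self):
        Ia = np.vstack([np.full((4, 3), 0.8) + np.arange(12).reshape(4, 3) * 1e-3,
                        np.full((4, 3), 0.2) + np.arange(12).reshape(4, 3) * 1e-3])
        Ib = 1.0 - Ia
        p = mwu_switch_test(Ia, Ib, range(0, 4), range(4, 8))
        # exact two-sided MWU with n=m=12, complete separation
        expected = stats.mannwhitneyu(
            Ia[:4].ravel(), Ia[4:].ravel(), alternative="two-sided"
        ).pvalue
        assert p < 0.001
        assert p == pytest.approx(expected)

    def test_matches_scipy_oracle(self, rng):
        Ia, Ib = rng.random((6, 3)), rng.random((6, 3))
        p = mwu_switch_test(Ia, Ib, range(0, 3), range(3, 6))
        expected = max(
            stats.mannwhitneyu(c[:3].ravel(), c[3:].ravel(), alternative="two-sided").pvalue
            for c in (Ia, Ib)
        )
        assert p == pytest.approx(expected)

    def test_too_few_samples_warns_p_one(self):
        Ia = np.array([[0.7], [0.3]])
        with pytest.warns(UserWarning):
            assert mwu_switch_test(Ia, 1 - Ia, range(0, 1), range(1, 2)) == 1.0


class TestPermutationTest:
    def test_strong_switch_significant(self, rng):
        # non-complementary pair (3-isoform gene); anticorr mode has power
        base = np.where(np.arange(10) < 5, 0.6, 0.2).astype(float)
        Ia = base.reshape(-1, 1) + rng.normal(0, 0.02, (10, 1))
        Ib = (0.8 - base).reshape(-1, 1) + rng.normal(0, 0.02, (10, 1))
        p = perm_switch_test(Ia, Ib, 4, 999, rng, dissimilarity_mode="anticorr")
        assert p < 0.05

    def test_constant_courses_p_one(self, rng):
        Ia = np.full((8, 1), 0.5)
        p = perm_switch_test(Ia, Ia.copy(), 3, 99, rng)
        assert p == 1.0

    def test_lower_bound(self, rng):
        t = np.linspace(0, 1, 12)
        Ia = (0.9 - 0.8 * t).reshape(-1, 1)
        Ib = 1.0 - Ia
        p = perm_switch_test(Ia, Ib, 5, 199, rng)
        assert p >= 1 / 200


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("BH", "holm", "bonferroni"):
            np.testing.assert_allclose(adjust_pvalues([0.04], method), [0.04])

    def test_bh_hand_computation(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03]
        )

    def test_bonferroni_arithmetic(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.04, 0.5, 0.9], "bonferroni"), [0.12, 1.0, 1.0]
        )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40)
        for ours, theirs in (("BH", "fdr_bh"), ("holm", "holm"), ("bonferroni", "bonferroni")):
            np.testing.assert_allclose(
                adjust_pvalues(p, ours), multipletests(p, method=theirs)[1]
            )

    def test_matches_brute_force_bh(self, rng):
        p = rng.random(15)
        np.testing.assert_allclose(adjust_pvalues(p, "BH"), oracle.bh(p.tolist()))

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(25)
        for method in ("BH", "holm", "bonferroni"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2])


class TestDomainGainLoss:
    DM = {"a": frozenset({"A", "B"}), "b": frozenset({"A", "C"}), "c": frozenset()}

    def test_identical_sets(self):
        gained, lost, unknown = domain_gain_loss("a", "a", self.DM)
        assert gained == lost == frozenset() and not unknown

    def test_set_difference(self):
        gained, lost, unknown = domain_gain_loss("a", "b", self.DM)
        assert gained == {"C"} and lost == {"B"} and not unknown

    def test_missing_isoform_unknown(self):
        gained, lost, unknown = domain_gain_loss("a", "zzz", self.DM)
        assert unknown and gained == lost == frozenset()


class TestDetect:
    def test_no_crossings_empty(self):
        Ia = np.tile([0.7, 0.7, 0.7], (2, 1)).T
        m = courses_to_matrix(Ia, 1 - Ia)
        assert detect_isoform_switches(m) == []

    def test_events_respect_thresholds(self):
        from isoswitch.simulator import SimulationConfig, simulate
        from isoswitch.core_data import filter_low_expression

        sim = simulate(SimulationConfig(n_genes=150, noise=5.0, seed=8))
        cfg = DetectionConfig(seed=8)
        events = detect_isoform_switches(filter_low_expression(sim.matrix), cfg)
        assert events
        for ev in events:
            assert ev.adj_p_value < cfg.alpha
            assert ev.adj_p_value >= ev.p_value - 1e-12
            assert ev.switch_probability >= cfg.min_switch_prob
            assert ev.diff_abundance >= cfg.min_diff
            assert ev.event_importance >= cfg.min_event_importance
            assert ev.best.replicate_support >= cfg.min_support
            assert 0 <= ev.best.time_index <= sim.matrix.n_timepoints - 2

    def test_threshold_monotonicity(self):
        from isoswitch.simulator import SimulationConfig, simulate
        from isoswitch.core_data import filter_low_expression

        sim = simulate(SimulationConfig(n_genes=100, noise=5.0, seed=4))
        m = filter_low_expression(sim.matrix)
        base = detect_isoform_switches(m, DetectionConfig(seed=4))
        for field, value in (
            ("min_diff", 0.4),
            ("min_switch_prob", 0.9),
            ("min_event_importance", 0.6),
            ("min_support", 1.0),
            ("alpha", 0.001),
        ):
            cfg = DetectionConfig(seed=4, **{field: value})
            stricter = detect_isoform_switches(m, cfg)
            assert len(stricter) <= len(base)

    def test_pair_symmetry_canonical_orientation(self, two_isoform_switch):
        events = detect_isoform_switches(two_isoform_switch, DetectionConfig())
        assert len(events) == 1
        ev = events[0]
        # pre-switch dominant isoform is listed first
        assert ev.isoform_a == "g1.t1" and ev.isoform_b == "g1.t2"

    def test_events_frame_columns(self, two_isoform_switch):
        events = detect_isoform_switches(two_isoform_switch, DetectionConfig())
        df = events_to_frame(events, two_isoform_switch.time_points)
        assert df.loc[0, "switch_point"] == "t1"
        assert {"p_value", "adj_p_value", "event_importance"} <= set(df.columns)


class TestOracleEquivalence:
    """Brute-force equivalence on exhaustively enumerated 2-isoform inputs."""

    @staticmethod
    def enumerate_cases():
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        cases = []
        rng = np.random.default_rng(0)
        for T, R in ((2, 1), (3, 2), (4, 3)):
            for _ in range(60):
                Ia = rng.choice(grid, size=(T, R))
                cases.append(Ia)
        return cases

    def test_metrics_match_bruteforce(self):
        cfg_support = 0.6
        for Ia in self.enumerate_cases():
            Ib = 1.0 - Ia
            T = Ia.shape[0]
            I = relative_abundance(courses_to_matrix(Ia, Ib))
            pts = find_switch_points(I, "g", "g.a", "g.b", cfg_support)
            la, lb = Ia.tolist(), Ib.tolist()
            want = oracle.switch_points(la, lb, cfg_support)
            assert [(p.time_index, p.replicate_support) for p in pts] == want
            qualifying = [s for s, _ in want]
            for s, _ in want:
                T1, T2 = oracle.interval_bounds(s, qualifying, T)
                got_T1, got_T2 = _interval_bounds(s, qualifying, T)
                assert list(got_T1) == T1 and list(got_T2) == T2
                # orientation: dominant-first
                mean_a = np.mean([la[t][r] for t in T1 for r in range(Ia.shape[1])])
                mean_b = np.mean([lb[t][r] for t in T1 for r in range(Ia.shape[1])])
                A, B = (la, lb) if mean_a >= mean_b else (lb, la)
                Anp, Bnp = (Ia, Ib) if mean_a >= mean_b else (Ib, Ia)
                assert switch_probability(Anp, Bnp, got_T1, got_T2) == pytest.approx(
                    oracle.switch_probability(A, B, T1, T2)
                )
                assert diff_abundance(Ia, Ib, s) == pytest.approx(
                    oracle.diff_abundance(la, lb, s)
                )
                gene_max = np.maximum(Ia, Ib)
                assert event_importance(Ia, Ib, gene_max, s) == pytest.approx(
                    oracle.event_importance(la, lb, [la, lb], s)
                )
            x, y = Ia.mean(axis=1), Ib.mean(axis=1)
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                assert dissimilarity(Ia, Ib) == pytest.approx(
                    oracle.dissimilarity(la, lb)
                )
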