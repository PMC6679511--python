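"""Sensor profiles: estimation, comparison, clustering, novelty scoring."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import homesense as hs
from homesense import simulate as sim
from homesense.events import DayTrace


def make_traces(rows, bin_width=30):
    return [DayTrace(date(2024, 1, 1) + timedelta(days=i),
                     np.asarray(r, dtype=np.uint8), bin_width)
            for i, r in enumerate(rows)]


def wilson_interval(n_pos, n, z=1.959963984540054):
    """Closed-form Wilson score interval, the independent oracle."""
    p = n_pos / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


class TestEstimateProfile:
    def test_mle_is_count_ratio(self):
        rows = [[1] + [0] * 47] * 3 + [[0] * 48] * 7
        prof = hs.estimate_profile(make_traces(rows))
        assert prof.p_hat[0] == pytest.approx(0.3)
        assert prof.n_pos[0] == 3 and prof.n_total[0] == 10

    def test_all_active_bin_has_ci_high_one(self):
        rows = [[1] * 48] * 5
        prof = hs.estimate_profile(make_traces(rows))
        assert prof.p_hat[0] == 1.0 and prof.ci_high[0] == 1.0
        assert prof.ci_low[0] < 1.0

    def test_wilson_interval_matches_closed_form(self):
        rows = [[1] + [0] * 47] * 3 + [[0] * 48] * 7
        prof = hs.estimate_profile(make_traces(rows))
        lo, hi = wilson_interval(3, 10)
        assert prof.ci_low[0] == pytest.approx(lo, abs=1e-9)
        assert prof.ci_high[0] == pytest.approx(hi, abs=1e-9)
        assert (lo, hi) == (pytest.approx(0.108, abs=1e-3),
                            pytest.approx(0.603, abs=1e-3))

    def test_p_hat_inside_interval_everywhere(self, night, night_nap):
        traces, _ = sim.sample_day_traces([night, night_nap], 60, seed=4)
        prof = hs.estimate_profile(traces)
        assert np.all(prof.ci_low <= prof.p_hat)
        assert np.all(prof.p_hat <= prof.ci_high)

    def test_ci_width_shrinks_like_inverse_sqrt_n(self, night):
        solo = sim.ModeSpec(night.name, night.bin_probabilities, 1.0)
        widths = []
        for n in (25, 100):
            traces, _ = sim.sample_day_traces([solo], n, seed=5)
            prof = hs.estimate_profile(traces)
            j = 5  # a night bin with p ~ 0.97
            widths.append(prof.ci_high[j] - prof.ci_low[j])
        assert widths[1] < widths[0]
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hs.estimate_profile([])

    def test_clopper_pearson_variant(self):
        rows = [[1] + [0] * 47] * 3 + [[0] * 48] * 7
        wilson = hs.estimate_profile(make_traces(rows), ci="wilson")
        exact = hs.estimate_profile(make_traces(rows), ci="beta")
        assert exact.ci_low[0] < wilson.ci_low[0]  # Clopper-Pearson is wider
        assert exact.ci_high[0] > wilson.ci_high[0]


def manual_holm(p):
    """Stepwise textbook Holm adjustment, the independent oracle."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestHolmBonferroni:
    def test_worked_example(self):
        got = hs.holm_bonferroni([0.04, 0.01, 0.02])
        assert np.allclose(got, [0.04, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert hs.holm_bonferroni([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(hs.holm_bonferroni([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hs.holm_bonferroni([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_manual_oracle_and_dominates_raw(self, p):
        got = hs.holm_bonferroni(p)
        assert np.allclose(got, manual_holm(np.asarray(p)))
        assert np.all(got >= np.asarray(p) - 1e-12)
        assert np.all(got <= 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        base = hs.holm_bonferroni(p)
        shuffled = hs.holm_bonferroni([p[i] for i in perm])
        assert np.allclose(shuffled, [base[i] for i in perm])


class TestCompareProfiles:
    def test_identical_groups_nothing_significant(self):
        rows = [[1] * 10 + [0] * 38] * 20
        res = hs.compare_profiles(make_traces(rows), make_traces(rows))
        assert not res.significant.any()

    def test_single_differing_bin_detected(self):
        # bin 0: 15/20 vs 3/20 active; all other bins identical
        a = [[1] + [1] * 5 + [0] * 42] * 15 + [[0] + [1] * 5 + [0] * 42] * 5
        b = [[1] + [1] * 5 + [0] * 42] * 3 + [[0] + [1] * 5 + [0] * 42] * 17
        res = hs.compare_profiles(make_traces(a), make_traces(b), alpha=0.05)
        assert res.significant[0]
        assert res.significant.sum() == 1
        # oracle: chi-square on the 2x2 table, Holm with one real test
        chi_p = stats.chi2_contingency(
            [[15, 5], [3, 17]], correction=False)[1]
        assert res.raw_p[0] == pytest.approx(chi_p)

    def test_sparse_tables_use_exact_test(self):
        a = [[1] + [0] * 47] * 2 + [[0] * 48] * 8
        b = [[0] * 48] * 10
        res = hs.compare_profiles(make_traces(a), make_traces(b))
        fisher_p = stats.fisher_exact([[2, 8], [0, 10]])[1]
        assert res.raw_p[0] == pytest.approx(fisher_p)

    def test_simulated_nap_difference_localized(self, night, night_nap):
        m1 = sim.ModeSpec(night.name, night.bin_probabilities, 1.0)
        m2 = sim.ModeSpec(night_nap.name, night_nap.bin_probabilities, 1.0)
        nap_bins = {j for j in range(48)
                    if night.bin_probabilities[j] != night_nap.bin_probabilities[j]}
        false_hits = 0
        for s in range(60):
            ta, _ = sim.sample_day_traces([m1], 25, seed=s)
            tb, _ = sim.sample_day_traces([m2], 25, seed=s + 10_000)
            res = hs.compare_profiles(ta, tb, alpha=0.05)
            sig = {j for j in range(48) if res.significant[j]}
            false_hits += bool(sig - nap_bins)
        # significant bins stay inside the truly differing span at ~FWER
        assert false_hits <= 0.05 * 60 + 3 * np.sqrt(0.05 * 0.95 * 60)

    def test_fwer_under_null(self, night):
        solo = sim.ModeSpec(night.name, night.bin_probabilities, 1.0)
        any_sig = 0
        n_rep = 100
        for s in range(n_rep):
            ta, _ = sim.sample_day_traces([solo], 20, seed=s)
            tb, _ = sim.sample_day_traces([solo], 20, seed=s + 20_000)
            res = hs.compare_profiles(ta, tb, alpha=0.05)
            any_sig += res.significant.any()
        assert any_sig / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            hs.compare_profiles([], make_traces([[0] * 48]))


class TestClusterDayTraces:
    def test_two_separated_modes_recovered_exactly(self, separated_groups):
        t1, t2 = separated_groups
        res = hs.cluster_day_traces(t1 + t2, n_sam=5, k_max=8)
        truth = np.array([0] * 20 + [1] * 20)
        assert res.n_clus == 2
        assert (res.labels >= 0).all()
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.silhouette is not None and res.silhouette > 0

    def test_prototypes_built_from_members_only(self, separated_groups):
        t1, t2 = separated_groups
        res = hs.cluster_day_traces(t1 + t2, n_sam=5, k_max=8)
        for i, proto in enumerate(res.prototypes):
            members = [tr for tr, l in zip(t1 + t2, res.labels) if l == i]
            manual = hs.estimate_profile(members)
            assert np.allclose(proto.p_hat, manual.p_hat)

    def test_identical_traces_degenerate(self):
        rows = [[1] * 10 + [0] * 38] * 40
        res = hs.cluster_day_traces(make_traces(rows), n_sam=5)
        assert res.n_clus == 1 and res.silhouette is None
        assert (res.labels == 0).all()

    def test_valid_cluster_sizes_at_least_nsam(self, night, night_nap, daytime_mode):
        traces, _ = sim.sample_day_traces(
            [night, night_nap], 50, seed=17,
            deviant_mode=daytime_mode, n_deviant=2)
        res = hs.cluster_day_traces(traces, n_sam=5, k_max=8)
        for c in range(res.n_clus):
            assert (res.labels == c).sum() >= 5

    def test_too_few_traces_rejected(self):
        rows = [[1] * 48] * 9
        with pytest.raises(ValueError, match="2\\*n_sam"):
            hs.cluster_day_traces(make_traces(rows), n_sam=5)

    def test_zero_vector_convention_in_distances(self):
        X = np.array([[0, 0], [0, 0], [1, 0]], dtype=float)
        D = hs.profiles.cosine_distance_matrix(X)
        assert D[0, 1] == 0.0  # identical emptiness
        assert D[0, 2] == 1.0  # empty vs non-empty maximally distant


class TestNoveltyScore:
    def test_uniform_prototype_forces_constant_score(self):
        rows = [[0, 1] * 24]
        proto = hs.estimate_profile(make_traces([[1] * 48, [0] * 48]))  # p=0.5
        ns = hs.novelty_score(make_traces(rows)[0], proto, epsilon=0.01)
        assert ns == pytest.approx(48 * np.log(2), abs=1e-9)

    def test_perfect_match_after_clipping(self):
        proto = hs.estimate_profile(make_traces([[1] * 48]))  # p_hat = 1
        ns = hs.novelty_score(make_traces([[1] * 48])[0], proto, epsilon=0.01)
        assert ns == pytest.approx(-48 * np.log(0.99), abs=1e-9)

    def test_minimized_by_thresholded_prototype(self, night):
        solo = sim.ModeSpec(night.name, night.bin_probabilities, 1.0)
        traces, _ = sim.sample_day_traces([solo], 30, seed=8)
        proto = hs.estimate_profile(traces)
        eps = hs.profiles.default_epsilon(proto)
        theta = np.clip(proto.p_hat, eps, 1 - eps)
        best = DayTrace(date(2024, 6, 1), (theta > 0.5).astype(np.uint8), 30)
        best_ns = hs.novelty_score(best, proto)
        rng = np.random.default_rng(0)
        for _ in range(50):
            other = DayTrace(date(2024, 6, 2),
                             rng.integers(0, 2, 48).astype(np.uint8), 30)
            assert hs.novelty_score(other, proto) >= best_ns - 1e-12

    def test_additive_and_non_negative(self, night):
        solo = sim.ModeSpec(night.name, night.bin_probabilities, 1.0)
        traces, _ = sim.sample_day_traces([solo], 20, seed=9)
        proto = hs.estimate_profile(traces)
        for tr in traces[:5]:
            assert hs.novelty_score(tr, proto) >= 0.0

    def test_bin_structure_mismatch_rejected(self):
        proto = hs.estimate_profile(make_traces([[1] * 48]))
        bad = DayTrace(date(2024, 1, 1), np.zeros(24, dtype=np.uint8), 60)
        with pytest.raises(ValueError):
            hs.novelty_score(bad, proto)


class TestIqrOutlierThreshold:
    def test_hand_worked_example(self):
        res = hs.iqr_outlier_threshold([1, 2, 3, 4, 5, 6, 7, 8, 100])
        assert res.threshold == pytest.approx(13.0)
        assert list(res.scores[res.outlier]) == [100]

    def test_all_equal_scores_edge(self):
        res = hs.iqr_outlier_threshold([2.0] * 6)
        assert res.threshold == 2.0
        assert res.outlier.all()  # strict inlier rule: nothing is below
        guarded = hs.iqr_outlier_threshold([2.0] * 6, require_positive_iqr=True)
        assert not guarded.outlier.any()

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            hs.iqr_outlier_threshold([1.0, 2.0, 3.0])

    def test_deviant_days_separate_from_dominant_mode(self, night, daytime_mode):
        solo = sim.ModeSpec(night.name, night.bin_probabilities, 1.0)
        traces, truth = sim.sample_day_traces(
            [solo], 45, seed=13, deviant_mode=daytime_mode, n_deviant=5)
        clustering = hs.cluster_day_traces(traces, n_sam=5, k_max=8)
        proto = clustering.prototypes[0]
        scores = hs.novelty_scores(traces, proto)
        res = hs.iqr_outlier_threshold(scores)
        flagged = {i for i, o in enumerate(res.outlier) if o}
        assert truth.deviant_days <= flagged
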