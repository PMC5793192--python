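"""Trajectory filtering, standardisation, fuzzy c-means and active-set calls."""

import numpy as np
import pandas as pd
import pytest

from conftest import best_label_agreement
from eetnet import clustering as cl
from eetnet import synthetic as syn


def frame(rows, ids=None):
    ids = ids or [f"p{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids, columns=cl.SAMPLES)


class TestFilterUnexpressed:
    def test_all_zero_row_removed_others_kept_in_order(self):
        m = frame([[0, 0, 0, 0, 0, 0],
                   [0, 0, 0, 0, 0, 1],
                   [2, 0, 1, 0, 0, 0]])
        out = cl.filter_unexpressed(m)
        assert list(out.index) == ["p1", "p2"]

    def test_planted_all_zero_rows_counted(self):
        matrix, truth = syn.generate_proteomics(
            {"sharp_decrease": 30, "all_zero": 5}, noise_sd=0.1, seed=2)
        out = cl.filter_unexpressed(matrix)
        assert len(matrix) - len(out) == 5
        removed = set(matrix.index) - set(out.index)
        assert all(truth.pattern_labels[p] == "all_zero" for p in removed)

    def test_duplicate_protein_ids_rejected(self):
        m = frame([[1] * 6, [2] * 6], ids=["p0", "p0"])
        with pytest.raises(ValueError, match="duplicate"):
            cl.filter_unexpressed(m)


class TestStandardize:
    def test_rows_have_mean_zero_sd_one(self):
        m = frame([[1, 2, 3, 4, 5, 6], [10, 0, 5, 5, 5, 5]])
        out = cl.standardize(m)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(out.std(axis=1, ddof=0), 1.0)

    def test_idempotent(self):
        m = frame([[1, 2, 3, 4, 5, 6]])
        once = cl.standardize(m)
        twice = cl.standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_rows_dropped_with_warning(self):
        m = frame([[3, 3, 3, 3, 3, 3], [1, 2, 3, 4, 5, 6]])
        with pytest.warns(UserWarning, match="constant"):
            out = cl.standardize(m)
        assert list(out.index) == ["p1"]


class TestFuzzyCMeans:
    def test_memberships_sum_to_one_and_objective_non_increasing(self):
        matrix, _ = syn.generate_proteomics(
            {"sharp_decrease": 40, "sharp_increase": 40}, noise_sd=0.3,
            seed=0)
        fit = cl.fuzzy_cmeans(cl.standardize(matrix),
                              cl.ClusteringConfig(c=2, seed=0))
        assert np.allclose(fit.memberships.sum(axis=1), 1.0, atol=1e-9)
        trace = fit.objective_trace
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_two_separated_clouds_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.05, size=(30, 6)) + np.array([5.0] * 6)
        b = rng.normal(0.0, 0.05, size=(30, 6)) - np.array([5.0] * 6)
        m = frame(np.vstack([a, b]))
        fit = cl.fuzzy_cmeans(m, cl.ClusteringConfig(c=2, m=1.5, seed=0))
        labels = fit.hard_labels
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_c_larger_than_rows_rejected(self):
        m = frame([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]])
        with pytest.raises(ValueError, match="exceeds"):
            cl.fuzzy_cmeans(cl.standardize(m), cl.ClusteringConfig(c=4))

    def test_deterministic_given_seed(self):
        matrix, _ = syn.generate_proteomics(
            {"sharp_decrease": 25, "late_increase": 25}, noise_sd=0.2,
            seed=3)
        std = cl.standardize(matrix)
        f1 = cl.fuzzy_cmeans(std, cl.ClusteringConfig(c=2, seed=7))
        f2 = cl.fuzzy_cmeans(std, cl.ClusteringConfig(c=2, seed=7))
        assert np.array_equal(f1.memberships, f2.memberships)

    @pytest.mark.parametrize("seed", range(5))
    def test_four_archetypes_recovered_at_noise(self, seed):
        """>= 90% agreement with planted labels at noise_sd 0.2, c=4, m=1.5."""
        counts = {"sharp_decrease": 50, "sharp_increase": 50,
                  "fast_then_slow_decrease": 50, "late_increase": 50}
        matrix, truth = syn.generate_proteomics(counts, noise_sd=0.2,
                                                seed=seed)
        std = cl.standardize(cl.filter_unexpressed(matrix))
        fit = cl.fuzzy_cmeans(std, cl.ClusteringConfig(c=4, m=1.5, seed=seed))
        truth_labels = [truth.pattern_labels[p] for p in fit.protein_ids]
        assert best_label_agreement(fit.hard_labels, truth_labels) >= 0.90

    def test_noiseless_recovery_is_exact(self):
        counts = {"sharp_decrease": 20, "sharp_increase": 20,
                  "fast_then_slow_decrease": 20, "late_increase": 20}
        matrix, truth = syn.generate_proteomics(counts, noise_sd=0.0, seed=0)
        std = cl.standardize(matrix)
        fit = cl.fuzzy_cmeans(std, cl.ClusteringConfig(c=4, seed=0))
        truth_labels = [truth.pattern_labels[p] for p in fit.protein_ids]
        assert best_label_agreement(fit.hard_labels, truth_labels) == 1.0


class TestIdentifyActiveClusters:
    def fit_with_centroids(self, centroids, labels=None, n=0):
        centroids = np.asarray(centroids, dtype=float)
        if labels is None:
            labels = []
        memberships = np.zeros((len(labels), len(centroids)))
        for i, lab in enumerate(labels):
            memberships[i, lab] = 1.0
        return cl.MembershipMatrix(
            protein_ids=[f"p{i}" for i in range(len(labels))],
            memberships=memberships, centroids=centroids, objective=0.0)

    def test_step_templates_resolve_to_down_and_up(self):
        fit = self.fit_with_centroids(
            [[1, 1, 1, -1, -1, -1], [-1, -1, -1, 1, 1, 1]],
            labels=[0, 0, 1])
        active = cl.identify_active_clusters(fit)
        assert active.down_set == {"p0", "p1"}
        assert active.up_set == {"p2"}

    def test_uniform_slope_is_not_sharp(self):
        # every consecutive step equals the S3->S4 step: not sharp at ratio 2
        ramp = [0.5, 0.3, 0.1, -0.1, -0.3, -0.5]
        fit = self.fit_with_centroids(
            [ramp, [1, 1, 1, -1, -1, -1], [-1, -1, -1, 1, 1, 1]],
            labels=[0, 1, 2])
        active = cl.identify_active_clusters(fit, sharp_ratio=2.0)
        assert active.down_set == {"p1"}

    def test_error_lists_centroid_steps_when_no_sharp_cluster(self):
        fit = self.fit_with_centroids(
            [[0.5, 0.3, 0.1, -0.1, -0.3, -0.5]] * 2, labels=[0, 1])
        with pytest.raises(ValueError, match="S3->S4 step"):
            cl.identify_active_clusters(fit)

    def test_active_sets_recover_planted_sharp_patterns(self):
        counts = {"sharp_decrease": 60, "sharp_increase": 60,
                  "fast_then_slow_decrease": 60, "late_increase": 60}
        matrix, truth = syn.generate_proteomics(counts, noise_sd=0.2, seed=4)
        std = cl.standardize(matrix)
        fit = cl.fuzzy_cmeans(std, cl.ClusteringConfig(c=4, seed=4))
        active = cl.identify_active_clusters(fit)
        true_down = {p for p, l in truth.pattern_labels.items()
                     if l == "sharp_decrease"}
        true_up = {p for p, l in truth.pattern_labels.items()
                   if l == "sharp_increase"}
        down_hit = len(active.down_set & true_down) / len(true_down)
        up_hit = len(active.up_set & true_up) / len(true_up)
        assert down_hit >= 0.9 and up_hit >= 0.9

    def test_down_and_up_sets_disjoint_union_consistent(self):
        with pytest.raises(ValueError, match="overlap"):
            cl.ActiveProteinSet(down_set={"x"}, up_set={"x"})
        aps = cl.ActiveProteinSet(down_set={"a"}, up_set={"b"})
        assert aps.union == {"a", "b"}
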