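"""Normalisation chain and fuzzy c-means correctness."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from epiferro.chipcluster import (
    cpm_normalize,
    cv_filter,
    dmin_curve,
    fuzzy_cmeans,
    group_replicates,
    hard_assign,
    length_normalize,
    log2_zscore,
    mean_over_replicates,
)
from epiferro.genomio import SignalMatrix
from helpers import brute_dmin, naive_fcm


def _mat(values, stage="raw"):
    values = np.asarray(values, dtype=float)
    return SignalMatrix(values,
                        [f"r{i}" for i in range(values.shape[0])],
                        [f"s{j}" for j in range(values.shape[1])], stage)


class TestNormalisation:
    def test_cpm_definition_and_column_sums(self):
        m = cpm_normalize(_mat([[100, 5], [999_900, 5]]))
        assert m.values[0, 0] == pytest.approx(100.0)
        assert m.values.sum(axis=0) == pytest.approx([1e6, 1e6])

    def test_cpm_zero_column_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            cpm_normalize(_mat([[1, 0], [2, 0]]))

    def test_length_per_kilobase(self):
        m = length_normalize(_mat([[100.0]], stage="cpm"), {"r0": 2000})
        assert m.values[0, 0] == pytest.approx(50.0)

    def test_doubling_lengths_halves_values(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, (10, 3))
        lens = rng.integers(500, 5000, 10).astype(float)
        a = length_normalize(_mat(vals, "cpm"), lens)
        b = length_normalize(_mat(vals, "cpm"), lens * 2)
        np.testing.assert_allclose(a.values, b.values * 2)

    def test_missing_length_is_error(self):
        with pytest.raises(ValueError, match="r0"):
            length_normalize(_mat([[1.0]], "cpm"), {"other": 100})

    def test_replicate_grouping_and_mean(self):
        m = SignalMatrix(np.array([[1.0, 3.0, 10.0, 20.0]]), ["r0"],
                         ["Day0_rep1", "Day0_rep2", "Day2_rep1", "Day2_rep2"],
                         "cpm")
        assert group_replicates(m.col_ids) == {
            "Day0": ["Day0_rep1", "Day0_rep2"], "Day2": ["Day2_rep1", "Day2_rep2"]}
        avg = mean_over_replicates(m)
        assert avg.col_ids == ["Day0", "Day2"]
        assert avg.values.tolist() == [[2.0, 15.0]]


class TestCvFilter:
    @pytest.mark.parametrize("row,kept", [
        ([9, 10, 11], False),      # CV ~ 0.082
        ([7, 10, 13], True),       # CV ~ 0.245
        ([10, 10, 10], False),     # constant, CV 0
        ([0, 0, 0], False),        # zero mean
    ])
    def test_cv_threshold(self, row, kept):
        out = cv_filter(_mat([row], stage="cpm"), 0.2)
        assert (len(out.row_ids) == 1) == kept

    def test_rejects_log_scale_input(self):
        with pytest.raises(ValueError, match="linear"):
            cv_filter(_mat([[1, 2]], stage="zscore"))


class TestLog2Zscore:
    def test_closed_form_two_columns(self):
        out = log2_zscore(_mat([[1.0, 3.0]], "cpm"))
        np.testing.assert_allclose(out.values, [[-1.0, 1.0]])

    def test_rows_standardised(self):
        rng = np.random.default_rng(1)
        out = log2_zscore(_mat(rng.uniform(0, 50, (20, 5)), "cpm"))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1), 1, atol=1e-12)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 50, (10, 4))
        perm = [2, 0, 3, 1]
        a = log2_zscore(_mat(vals, "cpm")).values[:, perm]
        b = log2_zscore(_mat(vals[:, perm], "cpm")).values
        np.testing.assert_allclose(a, b)

    def test_constant_rows_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = log2_zscore(_mat([[5.0, 5.0], [1.0, 2.0]], "cpm"))
        assert out.row_ids == ["r1"] and "zero-variance" in caplog.text


class TestFuzzyCMeans:
    def test_single_cluster_is_column_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 4))
        model = fuzzy_cmeans(x, 1, seed=0)
        np.testing.assert_allclose(model.membership, 1.0)
        np.testing.assert_allclose(model.centroids[0], x.mean(axis=0), atol=1e-9)

    def test_two_separated_pairs_closed_form(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 100.0], [100.0, 100.0]])
        model = fuzzy_cmeans(x, 2, seed=1, tol=1e-12, max_iter=2000)
        hard = hard_assign(model)
        assert hard[0] == hard[1] and hard[2] == hard[3] and hard[0] != hard[2]
        assert model.membership.max(axis=1).min() >= 0.99
        got = sorted(model.centroids.tolist())
        np.testing.assert_allclose(got, [[0, 0], [100, 100]], atol=1e-6)

    def test_matches_naive_loop_reference(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(50, 4))
        model = fuzzy_cmeans(x, 3, m=2.0, seed=123, tol=1e-9, max_iter=1000)
        _, u_ref = naive_fcm(x, 3, 2.0, seed=123, tol=1e-9, max_iter=1000)
        np.testing.assert_allclose(model.membership, u_ref, atol=1e-6)

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        for seed in range(10):
            x = rng.normal(size=(30, 3))
            model = fuzzy_cmeans(x, 4, seed=seed)
            np.testing.assert_allclose(model.membership.sum(axis=1), 1.0,
                                       atol=1e-9)
            assert ((model.membership >= 0) & (model.membership <= 1)).all()

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(5)
        for seed in range(100):
            x = rng.normal(size=(30, 3))
            model = fuzzy_cmeans(x, 3, seed=seed)
            trace = np.array(model.objective_trace)
            assert (np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1)).all()

    def test_point_on_centroid_gets_full_membership(self):
        # duplicate far-apart points force centroids onto the data
        x = np.array([[0.0], [0.0], [0.0], [50.0], [50.0], [50.0]])
        model = fuzzy_cmeans(x, 2, seed=2, tol=1e-13, max_iter=5000)
        assert np.isfinite(model.membership).all()
        np.testing.assert_allclose(model.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_input_validation(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError, match="exceeds"):
            fuzzy_cmeans(x, 4, seed=0)
        with pytest.raises(ValueError, match="m must be"):
            fuzzy_cmeans(x, 2, m=1.0, seed=0)
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fuzzy_cmeans(x, 2, seed=0)

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0]], dtype=float)
        x = np.vstack([c + rng.normal(0, 0.3, (15, 3)) for c in centers])
        perm = rng.permutation(len(x))
        a = fuzzy_cmeans(x, 3, seed=9, tol=1e-10, max_iter=2000)
        b = fuzzy_cmeans(x[perm], 3, seed=9, tol=1e-10, max_iter=2000)
        # match clusters via centroid distances, then compare memberships
        from scipy.spatial.distance import cdist
        ri, ci = linear_sum_assignment(cdist(a.centroids, b.centroids))
        np.testing.assert_allclose(a.centroids[ri], b.centroids[ci], atol=1e-4)
        np.testing.assert_allclose(a.membership[perm][:, ri], b.membership[:, ci],
                                   atol=1e-4)


class TestDminAndAssignment:
    def test_dmin_two_clusters_equals_center_distance(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(0, 0.05, (20, 2)),
                       rng.normal(10, 0.05, (20, 2))])
        model = fuzzy_cmeans(x, 2, seed=0, tol=1e-10, max_iter=1000)
        assert model.dmin == pytest.approx(np.sqrt(2) * 10, rel=0.02)

    def test_dmin_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(40, 3))
        for c in (2, 3, 5, 7):
            model = fuzzy_cmeans(x, c, seed=c)
            assert abs(model.dmin - brute_dmin(model.centroids)) <= 1e-12

    def test_dmin_curve_is_deterministic_and_nonnegative(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(30, 3))
        a = dmin_curve(x, range(2, 6), seed=5, repeats=2)
        b = dmin_curve(x, range(2, 6), seed=5, repeats=2)
        assert a == b
        assert all(d >= 0 for _, d in a)

    def test_hard_assignment_ties_to_lowest_index(self):
        model = fuzzy_cmeans(np.zeros((4, 2)) + np.arange(4)[:, None], 1, seed=0)
        model.membership = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0]])
        labels = hard_assign(model)
        assert labels.tolist() == [2, 1]


class TestPlantedPrototypeRecovery:
    def test_full_chain_recovers_prototypes(self, dataset, sim_config):
        """Count table -> CPM -> length -> replicate mean -> CV filter ->
        log2 z-score -> FCM at c=7 recovers planted temporal patterns."""
        from epiferro.genomio import read_chrom_sizes, read_count_table, read_genes
        from epiferro.regions import tss5kb_windowsets
        d, truth = dataset
        counts = read_count_table(d / "chip" / "counts_tss5kb.tsv")
        genes = read_genes(d / "genes.tsv")
        sizes = read_chrom_sizes(d / "chrom_sizes.tsv")
        lengths = tss5kb_windowsets(genes, 5000, True, sizes).lengths_by_source()
        m = cv_filter(mean_over_replicates(
            length_normalize(cpm_normalize(counts), lengths)), 0.2)
        z = log2_zscore(m)
        # the CV filter removes exactly the flat (label 0) genes
        assert {r for r in z.row_ids} == \
            {g for g, k in truth.cluster_labels.items() if k > 0}
        model = fuzzy_cmeans(z, 7, seed=11, n_init=10)
        hard = hard_assign(model)
        t = np.array([truth.cluster_labels[g] for g in z.row_ids])
        cont = np.zeros((7, 7))
        for ti, pi in zip(t, hard):
            cont[ti - 1, pi - 1] += 1
        ri, ci = linear_sum_assignment(-cont)
        purity = cont[ri, ci].sum() / len(t)
        assert purity >= 0.95
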