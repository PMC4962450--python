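"""Spectral histopathology: annotation transfer, KKNN, IO-CV, statistics."""

import numpy as np
import pytest

from optiscreen.raman_preprocess import fit_pca, preprocess_map, project_pca
from optiscreen.shp import (
    EXAMPLE_CONFUSION,
    KknnModel,
    ShpDataset,
    assemble_dataset,
    cluster_scan,
    confusion_stats,
    individual_out_cv,
    kknn_predict,
    majority_truth_mapping,
    merge_confusion,
    transfer_annotation,
    wilcoxon_screen,
)


def brute_force_nn(X, y, Q, p=2.0):
    """Exhaustive nearest-neighbour oracle (first index wins on ties)."""
    out = []
    for q in Q:
        d = np.sum(np.abs(X - q) ** p, axis=1) ** (1 / p)
        out.append(y[np.argmin(d)])
    return np.array(out, dtype=object)


class TestClusterScan:
    def test_single_cluster(self):
        labels = cluster_scan(np.random.default_rng(0).random((30, 4)), k=1)
        assert set(labels) == {0}

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, (40, 3))
        b = rng.normal(5, 0.1, (40, 3))
        labels = cluster_scan(np.vstack([a, b]), k=2, seed=0)
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_default_k_accepted_for_full_scan(self):
        rng = np.random.default_rng(2)
        labels = cluster_scan(rng.random((1360, 5)), k=9, seed=0)
        assert labels.shape == (1360,) and set(labels) == set(range(9))

    def test_k_exceeding_spectra_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_scan(np.zeros((5, 2)), k=9)


class TestAnnotationTransfer:
    def test_uniform_mapping(self):
        labels = transfer_annotation(np.array([0, 1, 1, 2]), {0: "normal", 1: "normal", 2: "normal"})
        assert list(labels) == ["normal"] * 4

    def test_background_cluster_flagged(self):
        labels = transfer_annotation(
            np.array([0, 1, 0, 1]), {0: "carcinoma", 1: "background"}
        )
        assert list(labels) == ["carcinoma", "background", "carcinoma", "background"]

    def test_unmapped_cluster_rejected(self):
        with pytest.raises(KeyError, match="\\[2\\]"):
            transfer_annotation(np.array([0, 2]), {0: "normal"})

    def test_simulated_pathologist_recovers_truth_regions(self, tiny_cohort):
        params, cohort = tiny_cohort
        m, truth = cohort.maps[0], cohort.truth_labels[0]
        out = preprocess_map(m)
        pca = fit_pca(out.spectra[out.valid], 5)
        scores = project_pca(pca, out.spectra[out.valid])
        truth_v = truth[out.valid]
        clusters = cluster_scan(scores, k=min(9, scores.shape[0]), seed=0)
        mapping = majority_truth_mapping(clusters, truth_v)
        transferred = transfer_annotation(clusters, mapping)
        assert (transferred == truth_v).mean() >= 0.9


class TestAssembleDataset:
    def blocks(self):
        rng = np.random.default_rng(3)
        blocks, labels, inds, scans = [], [], [], []
        for ind in ("a", "b", "c"):
            for scan in ("s0", "s1"):
                blocks.append(rng.random((10, 4)))
                labels.append(
                    np.array(["normal"] * 4 + ["carcinoma"] * 3 + ["adenoma"] * 2 + ["background"], dtype=object)
                )
                inds.append(ind)
                scans.append(scan)
        return blocks, labels, inds, scans

    def test_excluded_classes_dropped_counts_conserved(self):
        blocks, labels, inds, scans = self.blocks()
        ds = assemble_dataset(blocks, labels, inds, scans)
        total = sum(len(l) for l in labels)
        excluded = sum((l == "background").sum() for l in labels)
        assert ds.labels.shape[0] + excluded == total
        assert ds.n_individuals == 3

    def test_individual_ids_preserved(self):
        blocks, labels, inds, scans = self.blocks()
        ds = assemble_dataset(blocks, labels, inds, scans)
        assert set(ds.individuals) == {"a", "b", "c"}

    def test_only_excluded_classes_rejected(self):
        labels = [np.array(["background", "muscle"], dtype=object)]
        with pytest.raises(ValueError, match="empty dataset"):
            assemble_dataset([np.zeros((2, 3))], labels, ["a"], ["s0"])

    def test_single_individual_rejected(self):
        labels = [np.array(["normal", "adenoma"], dtype=object)]
        with pytest.raises(ValueError, match="2 individuals"):
            assemble_dataset([np.zeros((2, 3))], labels, ["a"], ["s0"])

    def test_class_in_single_individual_warns(self):
        labels = [
            np.array(["normal", "adenoma"], dtype=object),
            np.array(["normal", "normal"], dtype=object),
        ]
        with pytest.warns(UserWarning, match="adenoma"):
            assemble_dataset(
                [np.zeros((2, 3)), np.ones((2, 3))], labels, ["a", "b"], ["s0", "s0"]
            )


class TestKknn:
    def test_single_training_point_dominates(self):
        model = KknnModel(np.zeros((1, 2)), np.array(["normal"], dtype=object))
        preds = kknn_predict(model, np.random.default_rng(4).random((5, 2)))
        assert list(preds) == ["normal"] * 5

    @pytest.mark.parametrize("seed", range(5))
    def test_one_neighbor_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((20, 2))
        y = np.array(rng.choice(["adenoma", "carcinoma", "normal"], 20), dtype=object)
        Q = rng.random((5, 2))
        model = KknnModel(X, y, k=1)
        np.testing.assert_array_equal(kknn_predict(model, Q), brute_force_nn(X, y, Q))

    def test_exact_tie_goes_to_earlier_training_row(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array(["carcinoma", "adenoma"], dtype=object)
        model = KknnModel(X, y, k=1)
        assert kknn_predict(model, np.array([[0.0, 0.0]]))[0] == "carcinoma"

    def test_kernels_coincide_at_one_neighbor(self):
        rng = np.random.default_rng(6)
        X = rng.random((30, 3))
        y = np.array(rng.choice(["normal", "adenoma"], 30), dtype=object)
        Q = rng.random((10, 3))
        preds = {
            kern: list(kknn_predict(KknnModel(X, y, k=1, kernel=kern), Q))
            for kern in ("optimal", "rectangular", "triangular", "inv")
        }
        assert all(v == preds["optimal"] for v in preds.values())

    def test_weighted_vote_with_larger_k(self):
        # two near neighbours of one class outvote one very close other
        X = np.array([[0.05, 0.0], [0.3, 0.0], [0.32, 0.0], [5.0, 5.0]])
        y = np.array(["adenoma", "normal", "normal", "normal"], dtype=object)
        model = KknnModel(X, y, k=3, kernel="rectangular")
        assert kknn_predict(model, np.array([[0.0, 0.0]]))[0] == "normal"

    def test_dimension_mismatch_rejected(self):
        model = KknnModel(np.zeros((3, 2)), np.array(["a", "b", "c"], dtype=object))
        with pytest.raises(ValueError, match="dimension"):
            kknn_predict(model, np.zeros((2, 5)))

    def test_minkowski_order_changes_neighbors(self):
        X = np.array([[0.7, 0.0], [0.55, 0.55]])
        y = np.array(["adenoma", "carcinoma"], dtype=object)
        q = np.array([[0.0, 0.0]])
        # Minkowski norms of the two rows: p=1 -> (0.7, 1.1); p=2 ->
        # (0.7, 0.778); p=6 -> (0.7, 0.617): the order flips at high p
        assert kknn_predict(KknnModel(X, y, k=1, p=1.0), q)[0] == "adenoma"
        assert kknn_predict(KknnModel(X, y, k=1, p=2.0), q)[0] == "adenoma"
        assert kknn_predict(KknnModel(X, y, k=1, p=6.0), q)[0] == "carcinoma"


class TestConfusionStats:
    def test_reference_matrix_rates(self):
        stats = confusion_stats(EXAMPLE_CONFUSION)
        assert stats["sensitivity"]["adenoma"] == pytest.approx(80.0)
        assert stats["sensitivity"]["carcinoma"] == pytest.approx(62.5)
        assert stats["sensitivity"]["normal"] == pytest.approx(100.0)
        assert stats["specificity"]["adenoma"] == pytest.approx(87.5)
        assert stats["specificity"]["carcinoma"] == pytest.approx(95.2, abs=0.05)
        assert stats["specificity"]["normal"] == pytest.approx(100.0)

    def test_reference_matrix_tumor_merge(self):
        merged = merge_confusion(EXAMPLE_CONFUSION, {"adenoma": "tumor", "carcinoma": "tumor"})
        np.testing.assert_array_equal(merged.to_numpy(), [[13, 0], [0, 16]])
        assert confusion_stats(merged)["mean_sensitivity"] == pytest.approx(100.0)

    def test_merge_preserves_total(self):
        merged = merge_confusion(EXAMPLE_CONFUSION, {"adenoma": "tumor", "carcinoma": "tumor"})
        assert merged.to_numpy().sum() == EXAMPLE_CONFUSION.to_numpy().sum()

    def test_identity_matrix_perfect_rates(self):
        stats = confusion_stats(np.diag([5, 7]), labels=["a", "b"])
        assert stats["mean_sensitivity"] == 100.0
        assert all(v == 100.0 for v in stats["specificity"].values())

    def test_zero_row_reported_missing(self):
        stats = confusion_stats(np.array([[0, 0], [1, 3]]), labels=["a", "b"])
        assert np.isnan(stats["sensitivity"]["a"])
        assert stats["mean_sensitivity"] == pytest.approx(75.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_stats(np.array([[1, -1], [0, 2]]), labels=["a", "b"])


def make_dataset(rng, n_ind=4, n_per=30, separation=6.0, ind_sd=0.0):
    centers = {"adenoma": [0, 0], "carcinoma": [separation, 0], "normal": [0, separation]}
    feats, labs, inds, regs = [], [], [], []
    for i in range(n_ind):
        shift = rng.normal(0, ind_sd, 2)
        for cls, c in centers.items():
            feats.append(rng.normal(c + shift, 1.0, (n_per, 2)))
            labs += [cls] * n_per
            inds += [f"ind{i}"] * n_per
            regs += [f"ind{i}|s0|{cls}"] * n_per
    return ShpDataset(
        np.vstack(feats), np.array(labs, dtype=object),
        np.array(inds, dtype=object), np.array(regs, dtype=object),
    )


class TestIndividualOutCV:
    def test_separated_classes_fully_recovered(self):
        ds = make_dataset(np.random.default_rng(7), separation=12.0)
        report = individual_out_cv(ds)
        assert report.mean_sensitivity == 100.0
        assert report.merged_mean_sensitivity == 100.0

    def test_folds_partition_individuals(self):
        ds = make_dataset(np.random.default_rng(8))
        report = individual_out_cv(ds)
        assert sum(f["n_test"] for f in report.folds) == ds.labels.shape[0]
        assert len(report.folds) == ds.n_individuals
        assert {f["individual"] for f in report.folds} == set(ds.individuals)

    def test_confusion_rows_sum_to_annotated_regions(self):
        ds = make_dataset(np.random.default_rng(9), separation=3.0)
        report = individual_out_cv(ds)
        rows = report.confusion.sum(axis=1)
        for cls in report.confusion.index:
            n_regions = len({r for r, l in zip(ds.regions, ds.labels) if l == cls})
            assert rows[cls] == n_regions

    def test_spectrum_level_reporting(self):
        ds = make_dataset(np.random.default_rng(10), separation=12.0)
        report = individual_out_cv(ds, level="spectrum")
        assert report.confusion.to_numpy().sum() == ds.labels.shape[0]

    def test_cv_no_easier_than_resubstitution(self):
        """Individual effects make held-out individuals harder than
        leave-one-spectrum-out on the training set."""
        rng = np.random.default_rng(11)
        ds = make_dataset(rng, separation=2.5, ind_sd=2.0)
        cv = individual_out_cv(ds, level="spectrum")
        # resubstitution: nearest other spectrum, any individual
        correct = 0
        X, y = ds.features, ds.labels
        for i in range(len(y)):
            d = np.linalg.norm(X - X[i], axis=1)
            d[i] = np.inf
            correct += y[np.argmin(d)] == y[i]
        resub = 100.0 * correct / len(y)
        assert cv.mean_sensitivity <= resub + 1e-9

    def test_sensitivity_monotone_in_separation(self):
        sens = []
        for sep in (0.5, 2.0, 8.0):
            ds = make_dataset(np.random.default_rng(12), separation=sep, ind_sd=0.3)
            sens.append(individual_out_cv(ds).mean_sensitivity)
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] == 100.0

    def test_single_individual_rejected(self):
        ds = make_dataset(np.random.default_rng(13), n_ind=1)
        with pytest.raises(ValueError, match="2 individuals"):
            individual_out_cv(ds)


class TestWilcoxonScreen:
    def test_identical_groups_not_significant(self):
        scores = np.tile(np.arange(8, dtype=float)[:, None], (1, 3))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        scores[4:, :] = scores[:4, :]
        p = wilcoxon_screen(scores, labels, [1, 2, 3])
        assert all(v > 0.9 for v in p.values())

    def test_extreme_ranking_matches_enumeration(self):
        """Exact two-sided p for {1,2,3} vs {10,11,12} equals the
        enumeration over all 20 rank assignments."""
        from itertools import combinations

        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        pooled = sorted(x + y)
        u_obs = sum(xi < yi for xi in x for yi in y)  # U statistic of group 1
        us = []
        for comb in combinations(range(6), 3):
            g1 = [pooled[i] for i in comb]
            g2 = [pooled[i] for i in range(6) if i not in comb]
            us.append(sum(a < b for a in g1 for b in g2))
        us = np.array(us)
        # two-sided: as or more extreme in either direction
        lo, hi = min(u_obs, 9 - u_obs), max(u_obs, 9 - u_obs)
        p_enum = ((us <= lo) | (us >= hi)).mean()
        assert p_enum == pytest.approx(0.1)
        scores = np.array(x + y)[:, None]
        labels = np.array(["a"] * 3 + ["b"] * 3)
        p = wilcoxon_screen(scores, labels, [1])
        assert p[1] == pytest.approx(p_enum, abs=1e-12)

    def test_shift_alternative_detected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            scores = np.r_[a, b][:, None]
            labels = np.array(["a"] * 50 + ["b"] * 50)
            if wilcoxon_screen(scores, labels, [1])[1] < 0.001:
                hits += 1
        assert hits >= 95

    def test_component_numbering_is_one_based(self):
        rng = np.random.default_rng(14)
        scores = np.c_[rng.normal(0, 1, 40), np.r_[rng.normal(0, 1, 20), rng.normal(5, 1, 20)]]
        labels = np.array(["a"] * 20 + ["b"] * 20)
        p = wilcoxon_screen(scores, labels, [1, 2])
        assert p[2] < 1e-4 < p[1]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            wilcoxon_screen(np.zeros((4, 2)), np.array(["a"] * 4), [1])
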