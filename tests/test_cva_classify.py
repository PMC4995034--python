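"""Canonical variate analysis, Mahalanobis distances, and LOO reclassification."""

import numpy as np
import pytest
import scipy.linalg

import wingmorph as wm
from conftest import similarity_transform


def _labelled_proc(x, labels):
    """Wrap a plain feature matrix as a ProcrustesResult-like object for the
    group statistics; x plays the role of tangent coordinates."""
    import pandas as pd

    from wingmorph.gpa import ProcrustesResult

    n, p = x.shape
    k = p // 2
    return ProcrustesResult(
        consensus=np.zeros((k, 2)), aligned=x.reshape(n, k, 2),
        tangent_coords=x, centroid_sizes=np.ones(n),
        specimen_ids=[f"s{i}" for i in range(n)],
        labels=pd.DataFrame({"genus": labels, "subgenus": labels,
                             "species": labels, "site": [""] * n}),
        iterations=1, converged=True,
    )


class TestMahalanobisDistance:
    def test_equal_means_zero(self):
        cov = np.eye(3)
        assert wm.mahalanobis_distance(np.ones(3), np.ones(3), cov) == 0.0

    def test_identity_covariance_is_euclidean(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert wm.mahalanobis_distance(a, b, np.eye(3)) == pytest.approx(
            np.linalg.norm(a - b))

    def test_matches_solver_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, b = rng.normal(size=5), rng.normal(size=5)
            m = rng.normal(size=(5, 5))
            cov = m @ m.T + 0.5 * np.eye(5)
            expected = np.sqrt((a - b) @ np.linalg.solve(cov, a - b))
            assert wm.mahalanobis_distance(a, b, cov) == pytest.approx(
                expected, abs=1e-10)

    def test_singular_covariance_raises_with_guidance(self):
        with pytest.raises(np.linalg.LinAlgError, match="reduce"):
            wm.mahalanobis_distance(np.zeros(2), np.ones(2),
                                    np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestCVA:
    def test_embedded_univariate_closed_form(self):
        # all variation along one coordinate: Mahalanobis = |m1-m2| / pooled sd
        rng = np.random.default_rng(2)
        n = 30
        vals = np.concatenate([rng.normal(0.0, 1.0, n), rng.normal(2.5, 1.0, n)])
        x = np.zeros((2 * n, 4))
        x[:, 1] = vals
        labels = np.array(["a"] * n + ["b"] * n)
        proc = _labelled_proc(x, labels)
        res = wm.cva(proc, "species", variance_retained=1.0)
        m1, m2 = vals[:n].mean(), vals[n:].mean()
        pooled = np.sqrt((np.var(vals[:n], ddof=1) * (n - 1)
                          + np.var(vals[n:], ddof=1) * (n - 1)) / (2 * n - 2))
        assert res.mahalanobis.loc["a", "b"] == pytest.approx(
            abs(m1 - m2) / pooled, abs=1e-8)
        assert res.pc_dims_used == 1

    def test_axis_matches_lda_oracle(self):
        # an established discriminant implementation as a cross-check
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 60
            x = rng.normal(size=(n, 5))
            x[n // 2:] += rng.normal(0.5, 0.3, size=5)
            labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
            proc = _labelled_proc(np.hstack([x, np.zeros((n, 1))]), labels)
            res = wm.cva(proc, "species", variance_retained=1.0)
            lda = LinearDiscriminantAnalysis().fit(x, labels)
            axis = res.axes[:5, 0] if res.axes.shape[0] >= 5 else res.axes[:, 0]
            # compare directions in the original 5-dim space
            v = res.axes[:, 0]
            # CVA worked in a PCA rotation; map back via axes_tangent
            v_full = res.axes_tangent[:5, 0]
            cos = abs(v_full @ lda.coef_[0]) / (
                np.linalg.norm(v_full) * np.linalg.norm(lda.coef_[0]))
            assert cos > 0.999

    def test_scores_invariant_to_input_similarity_transform(self, two_group_dataset):
        proc = wm.generalized_procrustes(two_group_dataset)
        res = wm.cva(proc, "species")
        rng = np.random.default_rng(4)
        moved = np.array([similarity_transform(rng, c, scale_range=(1.0, 1.0))
                          for c in two_group_dataset.coords_array()])
        proc2 = wm.generalized_procrustes_array(
            moved, labels=proc.labels)
        res2 = wm.cva(proc2, "species")
        np.testing.assert_allclose(np.abs(res2.scores[:, 0]),
                                   np.abs(res.scores[:, 0]), atol=1e-6)

    def test_within_group_variance_is_unity_along_axes(self, study_proc):
        res = wm.cva(study_proc, "genus")
        pooled = np.zeros(res.scores.shape[1])
        n_tot = 0
        for g in res.groups:
            s = res.scores[res.labels == g]
            pooled += ((s - s.mean(axis=0)) ** 2).sum(axis=0)
            n_tot += len(s)
        np.testing.assert_allclose(pooled / (n_tot - len(res.groups)), 1.0,
                                   atol=1e-8)

    def test_eigenvalues_sorted_axes_bounded(self, study_proc):
        res = wm.cva(study_proc, "species")
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert np.all(res.eigenvalues >= 0)
        assert res.scores.shape[1] <= len(res.groups) - 1
        m = res.mahalanobis.to_numpy()
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_mahalanobis_triangle_inequality(self, study_proc):
        res = wm.cva(study_proc, "species")
        m = res.mahalanobis.to_numpy()
        rng = np.random.default_rng(5)
        g = m.shape[0]
        for _ in range(50):
            i, j, k = rng.choice(g, 3, replace=False)
            assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_three_genus_clusters_distinct(self, study_proc):
        res = wm.cva(study_proc, "genus")
        assert res.scores.shape[1] == 2
        assert wm.mean_silhouette(res.scores, res.labels) > 0.5

    def test_too_small_groups_rejected(self):
        x = np.random.default_rng(6).normal(size=(4, 6))
        proc = _labelled_proc(x, np.array(["a", "a", "a", "b"]))
        with pytest.raises(ValueError):
            wm.cva(proc, "species")


class TestLooReclassify:
    def test_forced_separation_is_perfect(self):
        spec = wm.GeneratorSpec(
            taxa=[wm.TaxonSpec("G", "S", "sp1", 15), wm.TaxonSpec("G", "S", "sp2", 15)],
            genus_offset_sd=0.0, subgenus_offset_sd=0.0,
            species_offset_sd=0.1, within_species_sd=0.01,
            allometry_fraction=0.0, seed=7,
        )
        proc = wm.generalized_procrustes(wm.generate(spec))
        p1, p2, table = wm.loo_reclassify(proc, ("sp1", "sp2"))
        assert p1 == 100.0 and p2 == 100.0
        assert table["correct"].all()

    def test_identical_distributions_at_chance(self):
        rates = []
        for seed in range(4):
            spec = wm.GeneratorSpec(
                taxa=[wm.TaxonSpec("G", "S", "sp1", 30),
                      wm.TaxonSpec("G", "S", "sp2", 30)],
                genus_offset_sd=0.0, subgenus_offset_sd=0.0,
                species_offset_sd=0.0, within_species_sd=0.01,
                allometry_fraction=0.0, seed=seed,
            )
            proc = wm.generalized_procrustes(wm.generate(spec))
            p1, p2, _ = wm.loo_reclassify(proc, ("sp1", "sp2"))
            rates += [p1, p2]
        # each per-group accuracy within 3 binomial SDs of 50% (n=30); note
        # LOO is pessimistically biased at chance (held-out removal shifts the
        # own-group mean away), so rates sit at or slightly below 50%
        band = 300 * np.sqrt(0.25 / 30)
        assert all(abs(r - 50.0) < band for r in rates)

    def test_requires_three_specimens_per_group(self, two_group_dataset):
        proc = wm.generalized_procrustes(two_group_dataset)
        with pytest.raises(ValueError, match="two distinct"):
            wm.loo_reclassify(proc, ("sp1", "sp1"))


class TestPairwiseTable:
    def test_structure_and_mean(self, study_proc):
        table = wm.pairwise_table(study_proc, "genus")
        assert table.taxa == ["Aedes", "Anopheles", "Culex"]
        vals = table.percent_correct.to_numpy()
        assert np.all(np.isnan(np.diag(vals)))
        off = table.offdiag
        assert off.size == 6
        assert np.all((off >= 0) & (off <= 100))
        assert table.mean_rate == pytest.approx(off.mean())

    def test_separated_groups_all_100(self):
        spec = wm.GeneratorSpec(
            taxa=[wm.TaxonSpec(g, g, f"sp{i}", 12) for i, g in
                  enumerate(["A", "B", "C"])],
            genus_offset_sd=0.15, subgenus_offset_sd=0.0, species_offset_sd=0.0,
            within_species_sd=0.005, allometry_fraction=0.0, seed=8,
        )
        proc = wm.generalized_procrustes(wm.generate(spec))
        table = wm.pairwise_table(proc, "genus")
        assert np.all(table.offdiag == 100.0)


class TestLandmarkSubsets:
    def test_full_subset_matches_unrestricted(self, two_group_dataset):
        proc = wm.generalized_procrustes(two_group_dataset)
        full = wm.pairwise_table(proc, "species")
        table = wm.evaluate_landmark_subsets(
            two_group_dataset, [tuple(range(1, 19))], grouping="species")
        assert table.loc[0, "mean_accuracy"] == pytest.approx(full.mean_rate)
        assert table.loc[0, "n_landmarks"] == 18

    def test_default_subsets_are_five_seven_nine(self):
        from wingmorph.cva_classify import DEFAULT_SUBSETS
        assert [len(s) for s in DEFAULT_SUBSETS] == [5, 7, 9]
        assert DEFAULT_SUBSETS[0] == (1, 2, 14, 15, 16)
        assert DEFAULT_SUBSETS[2] == (1, 2, 12, 13, 14, 15, 16, 17, 18)

    def test_tiny_subset_rejected(self, two_group_dataset):
        with pytest.raises(ValueError, match="fewer than 3"):
            wm.evaluate_landmark_subsets(two_group_dataset, [(1, 2)],
                                         grouping="species")


class TestSilhouette:
    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(4, 1, (25, 2)),
                       rng.normal([0, 6], 1, (15, 2))])
        labels = np.array(["a"] * 20 + ["b"] * 25 + ["c"] * 15)
        assert wm.mean_silhouette(x, labels) == pytest.approx(
            silhouette_score(x, labels), abs=1e-10)


class TestSeparationPermutation:
    def test_separated_groups_give_floor_p(self, two_group_dataset):
        proc = wm.generalized_procrustes(two_group_dataset)
        p = wm.separation_permutation_p(proc, "species", n_permutations=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_null_p_not_small(self):
        spec = wm.GeneratorSpec(
            taxa=[wm.TaxonSpec("G", "S", "sp1", 20), wm.TaxonSpec("G", "S", "sp2", 20)],
            genus_offset_sd=0.0, subgenus_offset_sd=0.0, species_offset_sd=0.0,
            within_species_sd=0.01, allometry_fraction=0.0, seed=10,
        )
        proc = wm.generalized_procrustes(wm.generate(spec))
        p = wm.separation_permutation_p(proc, "species", n_permutations=99, seed=1)
        assert p > 0.05
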