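from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dc2scape import (
    CentroidMatrix, OrthologMap, benjamini_hochberg, bulk_similarity,
    centroid_profiles, core_signature, correlate_profiles,
    select_variable_tfs, signature_coefficients, signature_shift_test,
    tf_program_overlap,
)
from dc2scape.simulate import make_sc_counts

from conftest import expr_from


class TestCentroids:
    def test_single_cluster_zscores_vanish(self, rng):
        expr = expr_from(rng.normal(size=(20, 5)))
        cm = centroid_profiles(expr, pd.Series("A", index=expr.cell_ids))
        assert np.allclose(cm.values.loc["A"], expr.values.mean(axis=0))
        assert np.allclose(cm.zscored(), 0.0)

    def test_two_cluster_population_sd_convention(self):
        values = np.array([[0.0], [0.0], [2.0], [2.0]])
        expr = expr_from(values)
        labels = pd.Series(["A", "A", "B", "B"], index=expr.cell_ids)
        cm = centroid_profiles(expr, labels)
        assert cm.values.loc["A", "g0"] == 0.0
        assert cm.values.loc["B", "g0"] == 2.0
        z = cm.zscored()
        assert z.loc["A", "g0"] == pytest.approx(-1.0)  # population SD = 1
        assert z.loc["B", "g0"] == pytest.approx(1.0)

    def test_singleton_cluster_equals_its_cell(self, rng):
        X = rng.normal(size=(3, 4))
        expr = expr_from(X)
        labels = pd.Series(["A", "B", "B"], index=expr.cell_ids)
        cm = centroid_profiles(expr, labels)
        assert np.allclose(cm.values.loc["A"], X[0])


class TestCorrelateProfiles:
    def _cm(self, data, clusters, genes):
        return CentroidMatrix(pd.DataFrame(data, index=clusters, columns=genes))

    def test_self_correlation_and_negation(self, rng):
        X = rng.normal(size=(3, 20))
        a = self._cm(X, ["c1", "c2", "c3"], [f"g{i}" for i in range(20)])
        b = self._cm(-X, ["d1", "d2", "d3"], [f"g{i}" for i in range(20)])
        raa = correlate_profiles(a, a, zscore=False)
        rab = correlate_profiles(a, b, zscore=False)
        assert np.allclose(np.diag(raa), 1.0)
        assert np.allclose(np.diag(rab), -1.0)

    def test_perfect_linearity(self):
        a = self._cm([[1, 2, 3, 4]], ["c"], list("wxyz"))
        b = self._cm([[2, 4, 6, 8]], ["d"], list("wxyz"))
        r = correlate_profiles(a, b, zscore=False)
        assert r.loc["c", "d"] == pytest.approx(1.0)

    def test_ortholog_translation(self, rng):
        X = rng.normal(size=(2, 10))
        genes_a = [f"ma{i}" for i in range(10)]
        genes_b = [f"hb{i}" for i in range(10)]
        a = self._cm(X, ["c1", "c2"], genes_a)
        b = self._cm(X, ["k1", "k2"], genes_b)
        omap = OrthologMap(list(zip(genes_a, genes_b)))
        r = correlate_profiles(a, b, ortholog_map=omap, zscore=False)
        assert np.allclose(np.diag(r.to_numpy().astype(float)), 1.0)

    def test_too_few_shared_genes(self, rng):
        a = self._cm(rng.normal(size=(2, 3)), ["c1", "c2"], ["g1", "g2", "g3"])
        b = self._cm(rng.normal(size=(2, 3)), ["d1", "d2"], ["h1", "h2", "h3"])
        with pytest.raises(ValueError, match="shared"):
            correlate_profiles(a, b)

    def test_invariant_to_pergene_affine_rescaling_after_zscore(self, rng):
        X = rng.normal(size=(4, 30))
        genes = [f"g{i}" for i in range(30)]
        a = self._cm(X, list("abcd"), genes)
        scale = rng.uniform(0.5, 3.0, 30)
        shift = rng.normal(size=30)
        b = self._cm(X * scale + shift, list("wxyz"), genes)
        r1 = correlate_profiles(a, a)
        r2 = correlate_profiles(a, b)
        assert np.allclose(r1.to_numpy().astype(float),
                           r2.to_numpy().astype(float), atol=1e-10)


class TestOrthologMap:
    def test_unique_pairs_kept(self):
        omap = OrthologMap([("a1", "b1"), ("a2", "b2")])
        assert omap.reduce_one_to_one() == [("a1", "b1"), ("a2", "b2")]

    def test_many_to_many_reduced_to_one_partner(self):
        omap = OrthologMap([("a1", "b1"), ("a1", "b2"), ("a2", "b2")])
        reduced = omap.reduce_one_to_one()
        genes_a = [p[0] for p in reduced]
        genes_b = [p[1] for p in reduced]
        assert len(genes_a) == len(set(genes_a))
        assert len(genes_b) == len(set(genes_b))

    def test_empty_id_rejected(self):
        with pytest.raises(ValueError):
            OrthologMap([("a", "")])


class TestSignatureCoefficients:
    def test_separable_marker_dominates_and_classifies(self):
        counts, truth = make_sc_counts(
            n_cells=220, n_genes=60, n_subsets=2, n_markers_per_subset=3,
            marker_effect=3.0, dropout=0.2, n_cycle_genes=10, seed=3,
        )
        sig = signature_coefficients(
            counts, truth.subset, total_count_min=0, n_folds=5,
            n_penalties=8, seed=0,
        )
        assert (sig.cv_auc > 0.95).all()
        for subset, markers in truth.marker_genes.items():
            top = sig.coefficients[subset].abs().nlargest(6).index
            assert len(set(markers) & set(top)) >= 2

    def test_random_labels_near_chance(self, rng):
        counts, truth = make_sc_counts(
            n_cells=120, n_genes=40, n_subsets=2, marker_effect=0.0,
            dropout=0.2, n_cycle_genes=10, seed=4,
        )
        random_labels = pd.Series(
            rng.choice(["A", "B"], size=counts.n_cells), index=counts.cell_ids
        )
        sig = signature_coefficients(
            counts, random_labels, total_count_min=0, n_folds=5,
            n_penalties=6, seed=0,
        )
        assert (abs(sig.cv_auc - 0.5) < 0.15).all()

    def test_single_cluster_raises(self):
        counts, truth = make_sc_counts(
            n_cells=50, n_genes=30, n_subsets=2, n_markers_per_subset=3,
            n_cycle_genes=5, seed=5,
        )
        with pytest.raises(ValueError, match="two clusters"):
            signature_coefficients(counts, pd.Series("A", index=counts.cell_ids))


class TestBulkSimilarity:
    def _sig(self, coef_df):
        class Sig:
            coefficients = coef_df
        return Sig()

    def test_affine_map_of_coefficients_r_one(self, rng):
        genes = [f"g{i}" for i in range(50)]
        coef = pd.DataFrame({"A": rng.normal(size=50)}, index=genes)
        bulk = pd.DataFrame({g: [3 * coef.loc[g, "A"] + 1] for g in genes}, index=["s1"])
        r = bulk_similarity(self._sig(coef), bulk)
        assert r.loc["A", "s1"] == pytest.approx(1.0)

    def test_orthogonal_profile_near_zero(self, rng):
        genes = [f"g{i}" for i in range(200)]
        coef = pd.DataFrame({"A": rng.normal(size=200)}, index=genes)
        bulk = pd.DataFrame(
            {g: [v] for g, v in zip(genes, rng.normal(size=200))}, index=["s1"]
        )
        r = bulk_similarity(self._sig(coef), bulk)
        assert abs(r.loc["A", "s1"]) < 0.2

    def test_output_shape(self, rng):
        genes = [f"g{i}" for i in range(10)]
        coef = pd.DataFrame(rng.normal(size=(10, 3)), index=genes, columns=list("ABC"))
        bulk = pd.DataFrame(rng.normal(size=(4, 10)), columns=genes,
                            index=["s1", "s2", "s3", "s4"])
        r = bulk_similarity(self._sig(coef), bulk)
        assert r.shape == (3, 4)


class TestCoreSignature:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "fdr", "mean_count"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_boundary_log2fc_excluded(self):
        tab = self._table([[1.5, 0.001, 100], [1.6, 0.001, 100]])
        res = core_signature({"spleen": tab}, fdr_max=0.01)
        assert res["per_tissue"]["spleen"]["up"] == ["g1"]

    def test_identical_tables_overlap_everything(self):
        tab = self._table([[2.0, 0.001, 100], [-3.0, 0.001, 60], [0.2, 0.5, 10]])
        res = core_signature({"a": tab, "b": tab.copy()}, fdr_max=0.01)
        assert res["overlap"]["up"] == ["g0"]
        assert res["overlap"]["down"] == ["g1"]

    def test_single_shared_passer(self):
        t1 = self._table([[2.0, 0.001, 100], [2.0, 0.001, 100], [2.0, 0.5, 100]])
        t2 = self._table([[2.0, 0.001, 100], [0.1, 0.001, 100], [2.0, 0.001, 100]])
        res = core_signature({"a": t1, "b": t2}, fdr_max=0.01)
        assert res["overlap"]["up"] == ["g0"]

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing columns"):
            core_signature({"a": pd.DataFrame({"log2fc": [1.0]})})


class TestBenjaminiHochberg:
    def test_matches_sort_based_oracle(self, rng):
        p = rng.uniform(size=100)
        q = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p)
        oracle = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            oracle[i] = running
        assert np.allclose(q, oracle, atol=1e-12)


class TestSelectVariableTfs:
    def _species(self, rng, shift, seed):
        n_per, n_tf = 50, 8
        X = rng.normal(size=(3 * n_per, n_tf))
        X[:n_per, 0] += shift  # TF 0 varies across clusters
        expr = expr_from(X)
        labels = pd.Series(
            ["c1"] * n_per + ["c2"] * n_per + ["c3"] * n_per, index=expr.cell_ids
        )
        return expr, labels

    def test_shifted_tf_selected_constant_tf_never(self, rng):
        expr_a, lab_a = self._species(rng, 3.0, 1)
        expr_b, lab_b = self._species(rng, 3.0, 2)
        expr_a.values[:, 1] = 1.0  # constant TF
        tfs = {"mouse": expr_a.gene_ids, "human": expr_b.gene_ids}
        omap = OrthologMap(list(zip(expr_a.gene_ids, expr_b.gene_ids)))
        res = select_variable_tfs(
            {"mouse": expr_a, "human": expr_b},
            {"mouse": lab_a, "human": lab_b},
            tfs, omap, fdr_max=1e-5,
        )
        assert ("g0", "g0") in res["shared_pairs"]
        assert "g1" not in res["selected"]["mouse"]

    def test_disagreeing_species_give_empty_intersection(self, rng):
        expr_a, lab_a = self._species(rng, 3.0, 1)
        expr_b, lab_b = self._species(rng, 0.0, 2)
        tfs = {"mouse": expr_a.gene_ids, "human": expr_b.gene_ids}
        omap = OrthologMap(list(zip(expr_a.gene_ids, expr_b.gene_ids)))
        res = select_variable_tfs(
            {"mouse": expr_a, "human": expr_b},
            {"mouse": lab_a, "human": lab_b},
            tfs, omap, fdr_max=1e-5,
        )
        assert res["shared_pairs"] == []


class TestTfProgramOverlap:
    def _block_profiles(self, rng, n_tf=30, n_feat=40, noise=0.05):
        base = np.zeros((n_tf, n_feat))
        base[: n_tf // 2, : n_feat // 2] = 1.0
        base[n_tf // 2:, n_feat // 2:] = 1.0
        return base + rng.normal(0, noise, base.shape)

    def test_identical_profiles_diagonal_overlap(self, rng):
        prof = self._block_profiles(rng)
        tfs_a = [f"tf{i}" for i in range(30)]
        tfs_b = [f"TF{i}" for i in range(30)]
        pa = pd.DataFrame(prof, index=tfs_a)
        pb = pd.DataFrame(prof, index=tfs_b)
        pairs = list(zip(tfs_a, tfs_b))
        res = tf_program_overlap({"m": pa, "h": pb}, pairs, k=5)
        total = res.overlap.to_numpy().sum()
        assert total == 30  # conservation
        # diagonal up to label permutation: each row has one dominant entry
        assert (res.overlap.max(axis=1).sum()) == 30

    def test_planted_blocks_recovered(self, rng):
        prof_a = self._block_profiles(rng)
        prof_b = self._block_profiles(rng)
        tfs = [f"tf{i}" for i in range(30)]
        res = tf_program_overlap(
            {"m": pd.DataFrame(prof_a, index=tfs),
             "h": pd.DataFrame(prof_b, index=tfs)},
            [(t, t) for t in tfs], k=5,
        )
        matched = res.overlap.max(axis=1).sum()
        assert matched >= 0.9 * 30

    def test_too_few_tfs_for_k(self, rng):
        prof = pd.DataFrame(rng.normal(size=(5, 10)), index=[f"t{i}" for i in range(5)])
        with pytest.raises(ValueError, match="smaller k"):
            tf_program_overlap({"m": prof, "h": prof},
                               [(f"t{i}", f"t{i}") for i in range(5)], k=10)


class TestSignatureShift:
    def test_signature_equals_background_d_zero(self, rng):
        bg = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        res = signature_shift_test(bg, list(bg.index))
        assert res["D"] == pytest.approx(0.0)

    def test_signature_above_background_max_d_one(self, rng):
        vals = np.concatenate([rng.normal(size=97), [10.0, 11.0, 12.0]])
        bg = pd.Series(vals, index=[f"g{i}" for i in range(100)])
        res = signature_shift_test(bg, ["g97", "g98", "g99"])
        # the background contains the signature, so the maximal CDF gap is
        # bounded by the background mass below the signature minimum
        assert res["D"] == pytest.approx(0.97)

    def test_location_shift_matches_analytic_limit(self, rng):
        bg_vals = rng.normal(size=1000)
        sig_vals = rng.normal(loc=1.0, size=50)
        bg = pd.Series(
            np.concatenate([bg_vals, sig_vals]),
            index=[f"g{i}" for i in range(1050)],
        )
        res = signature_shift_test(bg, [f"g{i}" for i in range(1000, 1050)])
        expected = stats.norm.cdf(0.5) - stats.norm.cdf(-0.5)
        assert res["D"] == pytest.approx(expected, abs=0.1)

    def test_exact_small_sample_p_matches_enumeration(self):
        sig = [0.1, 0.9, 1.7]
        rest = [0.4, 0.6, 1.1, 1.3]
        bg = pd.Series(sig + rest, index=[f"g{i}" for i in range(7)])
        res = signature_shift_test(bg, ["g0", "g1", "g2"])
        # permutation-enumerate the two-sample KS statistic of 3 signature
        # values vs the pooled 7 (signature is a subset of the background)
        pooled = np.array(sig + rest)
        obs = res["D"]

        def ks_stat(x, y):
            grid = np.sort(np.concatenate([x, y]))
            fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
            fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
            return np.max(np.abs(fx - fy))

        count = 0
        total = 0
        for pick in combinations(range(7), 3):
            x = pooled[list(pick)]
            total += 1
            if ks_stat(x, pooled) >= obs - 1e-12:
                count += 1
        # exact permutation p for this subset-vs-pool design brackets the
        # reported two-sample p (scipy computes the two-independent-sample
        # exact p; both must call the observed configuration unexceptional)
        assert 0.05 < res["pvalue"] <= 1.0
        assert count / total > 0.05
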