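from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dc2scape import (
    GeneModel, MotifModel, annotate_peaks, build_atlas,
    differential_accessibility, exact_score_threshold,
    extract_window_sequences, filter_motifs, gene_peakset_test,
    lasso_association, scan_motifs, size_factors, top_motifs,
)
from dc2scape.atac import DATable, MotifHitMatrix


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "peak_id"])


class TestBuildAtlas:
    def test_size_filter_is_inclusive_at_boundary(self):
        rows = [
            ("chr1", 1000, 1076, 1040, "p76"),   # width 76 -> removed
            ("chr1", 2000, 2077, 2040, "p77"),   # width 77 -> kept
        ]
        atlas = build_atlas(peaks_df(rows), min_peak_size=76)
        assert list(atlas.windows["peak_id"]) == ["p77"]

    def test_nonstandard_chromosomes_removed(self):
        rows = [
            ("chr1", 1000, 2000, 1500, "a"),
            ("chrM", 1000, 2000, 1500, "b"),
            ("chr19", 1000, 2000, 1500, "c"),
            ("chrX", 1000, 2000, 1500, "d"),
            ("chr1_random", 1000, 2000, 1500, "e"),
        ]
        atlas = build_atlas(peaks_df(rows))
        assert list(atlas.windows["peak_id"]) == ["a", "c", "d"]

    def test_window_centering_convention(self):
        rows = [("chr1", 1000, 2000, 1500, "a")]
        atlas = build_atlas(peaks_df(rows), window=150)
        w = atlas.windows.iloc[0]
        assert (w.wstart, w.wend) == (1500 - 75, 1500 + 75)

    def test_summit_outside_peak_rejected(self):
        rows = [
            ("chr1", 1000, 2000, 2500, "bad"),
            ("chr1", 3000, 4000, 3500, "good"),
        ]
        atlas = build_atlas(peaks_df(rows))
        assert list(atlas.windows["peak_id"]) == ["good"]

    def test_clipping_flagged_at_chromosome_start(self):
        rows = [("chr1", 0, 400, 30, "edge")]
        atlas = build_atlas(peaks_df(rows), window=150)
        w = atlas.windows.iloc[0]
        assert w.clipped and w.wstart == 0


class TestAnnotatePeaks:
    def _genes(self):
        genes = pd.DataFrame(
            [
                {"gene_id": "gene_p", "chrom": "chr1", "strand": "+",
                 "start": 10_000, "end": 20_000},
                {"gene_id": "gene_e", "chrom": "chr1", "strand": "+",
                 "start": 50_000, "end": 80_000},
            ]
        )
        tss = pd.DataFrame(
            [{"gene_id": "gene_p", "pos": 10_000}, {"gene_id": "gene_e", "pos": 50_000}]
        )
        exons = pd.DataFrame(
            [{"gene_id": "gene_p", "start": 10_000, "end": 10_500},
             {"gene_id": "gene_e", "start": 60_000, "end": 61_000}]
        )
        return GeneModel(genes=genes, tss=tss, exons=exons)

    def _atlas(self, summits):
        rows = [("chr1", s - 200, s + 200, s, f"pk{i}") for i, s in enumerate(summits)]
        return build_atlas(peaks_df(rows))

    def test_classification_precedence(self):
        gm = self._genes()
        atlas = self._atlas([
            9_000,     # 1 kb upstream of gene_p TSS -> promoter
            60_500,    # overlaps gene_e exon, 10 kb from its TSS -> exonic
            70_000,    # inside gene_e body, no exon -> intronic
            25_000,    # 5 kb from gene_p end -> intergenic
            200_000,   # beyond 50 kb of anything -> unclassified
        ])
        ann = annotate_peaks(atlas, gm)
        assert list(ann["annotation"]) == [
            "promoter", "exonic", "intronic", "intergenic", "unclassified",
        ]
        assert ann.loc[4, "gene_id"] is None

    def test_every_peak_gets_exactly_one_class(self, rng):
        gm = self._genes()
        summits = rng.integers(1_000, 250_000, 60)
        atlas = self._atlas(sorted(summits))
        ann = annotate_peaks(atlas, gm)
        assert ann["annotation"].isin(
            ["promoter", "exonic", "intronic", "intergenic", "unclassified"]
        ).all()
        assert len(ann) == atlas.n_peaks

    def test_matches_bruteforce_rule_application(self, rng):
        gm = self._genes()
        summits = sorted(rng.integers(1_000, 250_000, 40))
        atlas = self._atlas(summits)
        ann = annotate_peaks(atlas, gm, promoter_radius=2000, max_gene_distance=50_000)
        for row, (_, a) in zip(atlas.windows.itertuples(index=False), ann.iterrows()):
            # brute-force re-application of the stated precedence
            near_tss = any(abs(t - row.summit) <= 2000 for t in gm.tss["pos"])
            in_exon = any(
                (e.start < row.wend) and (e.end > row.wstart)
                for e in gm.exons.itertuples(index=False)
            )
            in_body = any(
                (g.start < row.wend) and (g.end > row.wstart)
                for g in gm.genes.itertuples(index=False)
            )
            dists = []
            for g in gm.genes.itertuples(index=False):
                if g.end <= row.wstart:
                    dists.append(row.wstart - g.end + 1)
                elif g.start >= row.wend:
                    dists.append(g.start - row.wend + 1)
                else:
                    dists.append(0)
            near_gene = min(dists) <= 50_000
            if near_tss:
                expect = "promoter"
            elif in_exon:
                expect = "exonic"
            elif in_body:
                expect = "intronic"
            elif near_gene:
                expect = "intergenic"
            else:
                expect = "unclassified"
            assert a["annotation"] == expect


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_factor_ratio(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert sf["a"] * sf["b"] == pytest.approx(1.0)  # geometric centering

    def test_no_reference_rows_raise(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestDifferentialAccessibility:
    def _counts(self, rng, n=200):
        base = rng.lognormal(np.log(500), 0.4, n)
        data = {}
        fold = np.ones(n)
        fold[:20] = 4.0  # planted 4x more accessible in A
        for r in range(3):
            data[f"A_{r}"] = rng.poisson(base * fold)
            data[f"B_{r}"] = rng.poisson(base)
        return pd.DataFrame(data, index=[f"p{i}" for i in range(n)])

    def test_threshold_rule_both_conditions_required(self):
        tab = pd.DataFrame(
            {"log2fc": [0.4, 0.6, 0.6], "p": [0.001, 0.5, 0.001]},
            index=["a", "b", "c"],
        )
        da = differential_accessibility(None, external_table=tab)
        # fdr recomputed by BH; only peak c passes both fdr and |log2fc|
        assert not da.table.loc["a", "significant"]
        assert not da.table.loc["b", "significant"]
        assert bool(da.table.loc["c", "significant"])

    def test_reproducibility_in_winning_condition_required(self, rng):
        counts = self._counts(rng)
        rep = pd.DataFrame(
            {"A": [False] * 200, "B": [True] * 200}, index=counts.index
        )
        groups = {"A": ["A_0", "A_1", "A_2"], "B": ["B_0", "B_1", "B_2"]}
        da = differential_accessibility(counts, groups, reproducibility=rep)
        planted = da.table.iloc[:20]
        # planted peaks favor condition A, but A lacks reproducibility
        assert not planted["significant"].any()

    def test_planted_fold_changes_recovered(self, rng):
        counts = self._counts(rng)
        groups = {"A": ["A_0", "A_1", "A_2"], "B": ["B_0", "B_1", "B_2"]}
        da = differential_accessibility(counts, groups)
        called = da.table["significant"]
        sens = called.iloc[:20].mean()
        false_calls = called.iloc[20:].mean()
        assert sens >= 0.9
        assert false_calls <= 0.05


class TestMotifScanning:
    def test_exact_pvalues_match_bruteforce_enumeration(self, rng):
        # all 4^L sequences under a skewed background, L <= 6
        for L in (2, 4, 6):
            ppm = np.vstack([rng.dirichlet([2.0, 0.5, 0.5, 1.0]) for _ in range(L)])
            bg = np.array([0.3, 0.2, 0.2, 0.3])
            motif = MotifModel("m", ppm, background=bg)
            bin_width = 1e-3
            lodds = np.rint(motif.log_odds() / bin_width).astype(int)
            scores = {}
            for seq in product(range(4), repeat=L):
                s = sum(lodds[i, b] for i, b in enumerate(seq))
                p = np.prod([bg[b] for b in seq])
                scores[s] = scores.get(s, 0.0) + p
            grid = np.array(sorted(scores))
            sf_oracle = np.cumsum([scores[s] for s in grid][::-1])[::-1]
            threshold, dp = exact_score_threshold(motif, 0.05, bin_width)
            # survival function must agree exactly on the shared lattice
            dp_sf = dict(zip(np.rint(dp["scores"] / bin_width).astype(int), dp["sf"]))
            for s, p_or in zip(grid, sf_oracle):
                assert dp_sf[s] == pytest.approx(p_or, abs=1e-12)
            # the DP threshold may fall between attainable scores; it must
            # produce the same accept/reject decision for every attainable one
            for s, p_or in zip(grid, sf_oracle):
                assert (s * bin_width >= threshold - 1e-12) == (p_or < 0.05)

    def test_background_equal_pwm_yields_no_hits(self):
        ppm = np.full((4, 4), 0.25)
        motif = MotifModel("flat", ppm)
        hits = scan_motifs({"w1": "ACGTACGTACGT"}, [motif], p_threshold=5e-4)
        assert (hits.values.to_numpy() == 0).all()

    def test_single_base_motif_exact_quantile(self):
        ppm = np.array([[1.0, 0.0, 0.0, 0.0]])
        motif = MotifModel("a_only", ppm, floor=1e-3)
        _, dp = exact_score_threshold(motif, 0.25)
        top_score = dp["scores"].max()
        sf_at_top = dp["sf"][np.argmax(dp["scores"])]
        assert sf_at_top == pytest.approx(0.25)
        assert top_score == pytest.approx(np.log2((1 - 3e-3 / 1.003) / 0.25), abs=1e-2)

    def test_palindrome_scores_both_strands_identically(self):
        # reverse-complement palindromic PWM: strand-symmetric features
        half = np.array([[0.94, 0.02, 0.02, 0.02], [0.02, 0.94, 0.02, 0.02]])
        ppm = np.vstack([half, half[::-1, ::-1]])  # ACGT-palindrome
        motif = MotifModel("pal", ppm)
        seq = "ATACGTAATTACGTAT"
        from dc2scape.atac import _COMPLEMENT
        rc = "".join(_COMPLEMENT[b] for b in reversed(seq))
        h1 = scan_motifs({"w": seq}, [motif], p_threshold=0.05)
        h2 = scan_motifs({"w": rc}, [motif], p_threshold=0.05)
        assert h1.values.iloc[0, 0] == pytest.approx(h2.values.iloc[0, 0])

    def test_window_with_n_skips_affected_offsets(self):
        ppm = np.array([[0.97, 0.01, 0.01, 0.01]] * 2)
        motif = MotifModel("aa", ppm)
        clean = scan_motifs({"w": "AATT"}, [motif], p_threshold=0.2)
        with_n = scan_motifs({"w": "NATT"}, [motif], p_threshold=0.2)
        assert clean.values.iloc[0, 0] > 0
        # the N kills the only AA offset; TT on the reverse strand still hits
        assert with_n.values.iloc[0, 0] == clean.values.iloc[0, 0]


class TestFilterMotifs:
    def _hits(self, prevalences, n_peaks=200):
        data = {}
        for i, p in enumerate(prevalences):
            col = np.zeros(n_peaks)
            col[: int(round(p * n_peaks))] = 2.0
            data[f"m{i}"] = col
        return MotifHitMatrix(
            values=pd.DataFrame(data, index=[f"pk{j}" for j in range(n_peaks)]),
            p_threshold=5e-4,
        )

    def test_prevalence_band_boundaries_inclusive(self):
        hits = self._hits([0.005, 0.01, 0.20, 0.40, 0.50])
        out = filter_motifs(hits, min_prevalence=0.01, max_prevalence=0.40)
        assert list(out.values.columns) == ["m1", "m2", "m3"]

    def test_unexpressed_tf_motifs_removed(self):
        hits = self._hits([0.1, 0.1])
        out = filter_motifs(
            hits, expressed_tfs=["TFA"],
            motif_tf_map={"m0": ["TFA"], "m1": ["TFB"]},
        )
        assert list(out.values.columns) == ["m0"]

    def test_best_motif_per_tf_reduction(self):
        hits = self._hits([0.1, 0.1, 0.1])
        ranking = pd.Series({"m0": 5.0, "m1": 9.0, "m2": 1.0})
        out = filter_motifs(
            hits,
            motif_tf_map={"m0": ["T1"], "m1": ["T1"], "m2": ["T2"]},
            enrichment_ranking=ranking,
        )
        assert list(out.values.columns) == ["m1", "m2"]

    def test_everything_removed_raises(self):
        hits = self._hits([0.9])
        with pytest.raises(ValueError):
            filter_motifs(hits)


class TestLassoAssociation:
    def _da_hits(self, rng, n=500, p=30):
        X = rng.binomial(1, 0.2, size=(n, p)) * rng.uniform(1, 3, size=(n, p))
        y = 2.0 * X[:, 7]
        tab = pd.DataFrame(
            {"log2fc": y, "p": 0.5, "fdr": 0.5, "mean_count": rng.uniform(50, 150, n)},
            index=[f"pk{i}" for i in range(n)],
        )
        hits = MotifHitMatrix(
            values=pd.DataFrame(X, index=tab.index,
                                columns=[f"m{j}" for j in range(p)]),
            p_threshold=5e-4,
        )
        return DATable(tab, "A", "B"), hits

    def test_zero_response_rejected(self, rng):
        da, hits = self._da_hits(rng)
        da.table["log2fc"] = 0.0
        with pytest.raises(ValueError, match="constant"):
            lasso_association(da, hits, seed=0)

    def test_noiseless_single_motif_recovered(self, rng):
        da, hits = self._da_hits(rng)
        fit = lasso_association(da, hits, seed=0)
        top = top_motifs(fit, 1)
        assert top["motif"].iloc[0] == "m7"
        assert fit.mean_rho > 0.99

    def test_support_monotone_in_penalty(self, rng):
        from sklearn.linear_model import Lasso

        da, hits = self._da_hits(rng)
        y = da.table["log2fc"].to_numpy()
        X = hits.values.to_numpy()
        Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1)
        sizes = []
        for alpha in np.logspace(-3, 0.5, 8):
            m = Lasso(alpha=alpha, max_iter=20000).fit(Xs, y)
            sizes.append(int((m.coef_ != 0).sum()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_top_n_peak_selection_by_mean_count(self, rng):
        da, hits = self._da_hits(rng, n=300)
        fit = lasso_association(da, hits, top_n_peaks=100, seed=0)
        assert fit.n_peaks == 100


class TestTopMotifs:
    def _fit(self, coefs):
        from dc2scape.atac import LassoFit

        s = pd.Series(coefs)
        return LassoFit(
            coefficients=s, coefficients_destandardized=s, chosen_penalty=0.1,
            fold_rho=[0.5], mean_rho=0.5, n_peaks=10,
            feature_means=s * 0, feature_sds=s * 0 + 1,
        )

    def test_tie_broken_by_motif_id(self):
        fit = self._fit({"mB": -2.0, "mA": 2.0, "mC": 1.0})
        out = top_motifs(fit, 3)
        assert list(out["motif"]) == ["mA", "mB", "mC"]

    def test_signed_values_retained(self):
        fit = self._fit({"mA": -3.0, "mB": 1.0})
        out = top_motifs(fit, 2)
        assert out["coefficient"].iloc[0] == -3.0


class TestGenePeaksetTest:
    def _da(self, values):
        tab = pd.DataFrame(
            {"log2fc": values}, index=[f"pk{i}" for i in range(len(values))]
        )
        return DATable(tab, "A", "B")

    def test_matches_exact_enumeration_small_groups(self, rng):
        values = rng.normal(size=40)
        da = self._da(values)
        pmap = pd.DataFrame(
            {"peak_id": ["pk0", "pk1", "pk2"], "gene_id": ["g"] * 3}
        )
        res = gene_peakset_test(da, pmap, ["g"])
        x = values[:3]
        u_oracle = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in values)
        assert res["U"].iloc[0] == pytest.approx(u_oracle)
        oracle = stats.mannwhitneyu(x, values, alternative="two-sided", method="exact")
        assert res["p"].iloc[0] == pytest.approx(oracle.pvalue)

    def test_single_gene_q_equals_p(self, rng):
        da = self._da(rng.normal(size=30))
        pmap = pd.DataFrame({"peak_id": ["pk1", "pk2"], "gene_id": ["g", "g"]})
        res = gene_peakset_test(da, pmap, ["g"])
        assert res["q"].iloc[0] == res["p"].iloc[0]

    def test_null_gene_pvalues_uniform(self, rng):
        values = rng.normal(size=400)
        da = self._da(values)
        rows = []
        genes = []
        for g in range(200):
            picks = rng.choice(400, size=5, replace=False)
            genes.append(f"g{g}")
            rows += [{"peak_id": f"pk{i}", "gene_id": f"g{g}"} for i in picks]
        res = gene_peakset_test(da, pd.DataFrame(rows), genes)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_gene_without_peaks_excluded(self, rng):
        da = self._da(rng.normal(size=10))
        pmap = pd.DataFrame({"peak_id": ["pk0"], "gene_id": ["g1"]})
        res = gene_peakset_test(da, pmap, ["g1", "g_orphan"])
        assert list(res["gene_id"]) == ["g1"]
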