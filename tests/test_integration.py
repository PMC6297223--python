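import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from cnvhic.genome import build_genome_model, make_bins
from cnvhic.integration import (
    allele_specific_expression,
    assign_peaks_to_tss,
    bin_pair_signal_correlation,
    binned_enrichment,
    expression_chromatin_correlation,
    fish_nested_anova,
    group_permutation_test,
    normalize_fish_distances,
    simple_de_standin,
    zscore_differential_sites,
)
from cnvhic.simulate import CohortConfig, simulate_fish_measurements

GROUPS = {"del": ["d1", "d2", "d3"], "ctrl": ["c1", "c2", "c3"]}


def _signal(values):
    """values: list of per-site [d1 d2 d3 c1 c2 c3]."""
    n = len(values)
    df = pd.DataFrame({
        "site_id": [f"s{i}" for i in range(n)],
        "chrom": "c", "start": np.arange(n) * 1000,
        "end": np.arange(n) * 1000 + 500, "mark": "H3K27ac",
    })
    for j, col in enumerate(GROUPS["del"] + GROUPS["ctrl"]):
        df[col] = [v[j] for v in values]
    return df


class TestZscores:
    def test_site_at_mean_has_zero_z(self):
        sig = _signal([[2, 2, 2, 1, 1, 1],    # log2fc = 1
                       [4, 4, 4, 1, 1, 1],    # log2fc = 2
                       [8, 8, 8, 1, 1, 1]])   # log2fc = 3
        out = zscore_differential_sites(sig, GROUPS, 2.0, pseudocount=1e-9)
        assert out["zscore"].iloc[1] == pytest.approx(0.0, abs=1e-9)
        assert out["zscore"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["zscore"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_outlier_site_flagged(self, rng):
        vals = [[1 + e, 1 + e, 1 + e, 1, 1, 1] for e in rng.normal(0, 0.01, 50)]
        vals.append([16, 16, 16, 1, 1, 1])  # log2fc = 4, far above the rest
        out = zscore_differential_sites(_signal(vals), GROUPS, 2.0)
        assert bool(out["significant"].iloc[-1])
        assert out["significant"].iloc[:-1].sum() <= 5

    def test_constant_log2fc_rejected(self):
        sig = _signal([[2, 2, 2, 1, 1, 1]] * 3)
        with pytest.raises(ValueError, match="sd = 0"):
            zscore_differential_sites(sig, GROUPS, 2.0)

    def test_invariant_to_uniform_rescaling(self):
        sig = _signal([[2, 3, 2, 1, 1, 1], [4, 4, 5, 1, 2, 1], [8, 8, 8, 3, 1, 1]])
        a = zscore_differential_sites(sig, GROUPS, 2.0, pseudocount=1e-9)
        scaled = sig.copy()
        for c in GROUPS["del"] + GROUPS["ctrl"]:
            scaled[c] = scaled[c] * 100.0
        b = zscore_differential_sites(scaled, GROUPS, 2.0, pseudocount=1e-9)
        np.testing.assert_allclose(a["zscore"], b["zscore"], atol=1e-6)


class TestBinnedEnrichment:
    @pytest.fixture()
    def bins(self):
        return make_bins(build_genome_model({"c": 3_000_000}), 500_000)

    def test_spec_fisher_table(self, bins):
        """Bin with 5/24 significant vs 95/2476 elsewhere."""
        rows = [("c", 100, True)] * 5 + [("c", 100, False)] * 19
        rows += [("c", 2_600_000, True)] * 95 + [("c", 2_600_000, False)] * 2381
        feats = pd.DataFrame(rows, columns=["chrom", "pos", "significant"])
        out = binned_enrichment(feats, bins)
        expected = st.fisher_exact([[5, 19], [95, 2381]])[1]
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-12)

    def test_background_consistent_tiny_counts(self, bins):
        rows = [("c", 100, True)] * 1 + [("c", 100, False)] * 1
        rows += [("c", 2_600_000, True)] * 10 + [("c", 2_600_000, False)] * 10
        out = binned_enrichment(pd.DataFrame(rows, columns=["chrom", "pos",
                                                            "significant"]), bins)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_bin_is_na_and_totals_conserved(self, bins):
        feats = pd.DataFrame([("c", 100, True), ("c", 2_600_000, False)],
                             columns=["chrom", "pos", "significant"])
        out = binned_enrichment(feats, bins)
        assert np.isnan(out.loc[2, "p"])
        assert out["n_total"].sum() == len(feats)


class TestTssAssignment:
    def _genes(self, tss, strands=None):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(tss))],
            "chrom": "c", "tss": tss,
            "strand": strands or ["+"] * len(tss),
        })

    def _sites(self, mids, width=10):
        return pd.DataFrame({
            "site_id": [f"s{i}" for i in range(len(mids))],
            "chrom": "c",
            "start": [m - width // 2 for m in mids],
            "end": [m + width // 2 for m in mids],
        })

    def test_nearest_tss_signed_distance(self):
        out = assign_peaks_to_tss(self._sites([100]), self._genes([90, 300]), 1000)
        assert out.loc[0, "gene_id"] == "g0" and out.loc[0, "distance"] == 10

    def test_minus_strand_flips_sign(self):
        out = assign_peaks_to_tss(self._sites([100]), self._genes([90], ["-"]), 1000)
        assert out.loc[0, "distance"] == -10

    def test_gene_keeps_nearest_of_multiple_sites(self):
        out = assign_peaks_to_tss(self._sites([110, 150]), self._genes([100]), 1000)
        assert len(out) == 1 and out.loc[0, "site_id"] == "s0"

    def test_cutoff_drops_distant_sites(self):
        out = assign_peaks_to_tss(self._sites([1600]), self._genes([100]), 1000)
        assert out.empty

    def test_matches_brute_force_oracle(self, rng):
        genes = self._genes(sorted(rng.choice(1_000_000, 300, replace=False)))
        sites = self._sites(list(rng.integers(100, 999_000, 1000)))
        out = assign_peaks_to_tss(sites, genes, 5000).set_index("gene_id")
        # oracle: all-pairs nearest, same tie-handling via stable ordering
        tss = genes["tss"].to_numpy()
        best = {}
        for i, m in enumerate((sites["start"] + sites["end"]) // 2):
            d = np.abs(tss - m)
            g = int(np.argmin(d))
            if d[g] > 5000:
                continue
            key = f"g{g}"
            if key not in best or d[g] < best[key][1]:
                best[key] = (f"s{i}", d[g])
        assert len(out) == len(best)
        for g, (sid, dist) in best.items():
            assert abs(out.loc[g, "distance"]) == dist


class TestPermutationTest:
    def test_exact_enumeration_small_case(self):
        """A1={2}, B1={0,1}: 3 regroupings, |delta| >= obs in 2 of them."""
        obs, p = group_permutation_test([2.0], [0.0, 1.0])
        assert obs == pytest.approx(1.5)
        # deltas: pick {2}->1.5, {0}->-1.5, {1}->0: two as extreme as obs
        assert p == pytest.approx(2 / 3)

    def test_exact_matches_monte_carlo(self, rng):
        a = rng.normal(0, 1, 4)
        b = rng.normal(0.5, 1, 3)
        _, p_exact = group_permutation_test(a, b, exact=True)
        _, p_mc = group_permutation_test(a, b, n_perm=20_000, seed=0, exact=False)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_identical_values_p_one(self):
        _, p = group_permutation_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_monte_carlo_p_never_zero(self, rng):
        a = rng.normal(10, 0.1, 12)
        b = rng.normal(-10, 0.1, 12)
        _, p = group_permutation_test(a, b, n_perm=999, seed=1, exact=False)
        assert p >= 1 / 1000

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_permutation_test([], [1.0])

    def test_null_calibration_uniform(self):
        """Same-distribution groups give uniform p across seeds."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0, 1, 10)
            _, p = group_permutation_test(a, b, n_perm=199, seed=7, exact=False)
            ps.append(p)
        assert st.kstest(ps, "uniform").pvalue > 0.01


class TestExpressionChromatinCorrelation:
    def _tables(self, n_genes, coupled, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(8)]
        sig = rng.normal(5, 1, (n_genes, 8))
        fpkm = 0.8 * sig + rng.normal(0, 1, (n_genes, 8)) if coupled \
            else rng.normal(5, 1, (n_genes, 8))
        expr = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)]})
        signal = pd.DataFrame({"site_id": [f"p{i}" for i in range(n_genes)]})
        for j, s in enumerate(samples):
            expr[s] = fpkm[:, j]
            signal[s] = sig[:, j]
        assign = pd.DataFrame({"gene_id": expr["gene_id"],
                               "site_id": signal["site_id"], "distance": 0})
        return expr, assign, signal, samples

    def test_identical_tables_give_unit_correlation(self):
        expr, assign, signal, samples = self._tables(20, coupled=False)
        for s in samples:
            expr[s] = signal[s]
        res = expression_chromatin_correlation(expr, assign, signal, samples, seed=1)
        np.testing.assert_allclose(res["observed_r"], 1.0)

    def test_coupled_signal_detected(self):
        expr, assign, signal, samples = self._tables(150, coupled=True)
        res = expression_chromatin_correlation(expr, assign, signal, samples, seed=1)
        assert res["wilcoxon_p"] < 0.01
        assert np.mean(res["observed_r"]) > np.mean(res["background_r"])

    def test_uncoupled_p_uniform_across_seeds(self):
        ps = []
        for seed in range(40):
            expr, assign, signal, samples = self._tables(60, coupled=False,
                                                         seed=100 + seed)
            res = expression_chromatin_correlation(expr, assign, signal, samples,
                                                   seed=seed)
            ps.append(res["wilcoxon_p"])
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_samples_rejected(self):
        expr, assign, signal, samples = self._tables(10, coupled=False)
        with pytest.raises(ValueError):
            expression_chromatin_correlation(expr, assign, signal, samples[:3])


class TestAse:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "gene_id",
                                           "ref_count", "alt_count"])

    def test_balanced_snv_at_center_p_one(self):
        # p0 = 0.5 from many balanced SNVs; 6/12 is the symmetric center
        rows = [("s", "c", i, "g", 15, 15) for i in range(40)]
        rows.append(("s", "c", 999, "g", 6, 6))
        out = allele_specific_expression(self._counts(rows))
        assert out[out["pos"] == 999]["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_binomial_tail(self):
        """coverage 20, alt 2, p0=0.5 -> 2 * P(X <= 2) = 2*(1+20+190)/2^20."""
        rows = [("s", "c", i, "g", 15, 15) for i in range(200)]
        rows.append(("s", "c", 999, "g", 18, 2))
        out = allele_specific_expression(self._counts(rows))
        p = out[out["pos"] == 999]["p"].iloc[0]
        # p0 is pulled slightly off 0.5 by the test SNV itself; compare to
        # the exact binomial oracle at the realized p0
        p0 = out["background_p0"].iloc[0]
        expected = st.binomtest(2, 20, p0).pvalue
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(4.025e-4, rel=0.05)

    def test_low_coverage_excluded(self):
        rows = [("s", "c", i, "g", 15, 15) for i in range(5)]
        rows.append(("s", "c", 999, "g", 5, 5))  # coverage 10: excluded (>10 rule)
        out = allele_specific_expression(self._counts(rows))
        assert 999 not in out["pos"].to_numpy()

    def test_monoallelic_deletion_genes_detected(self):
        rows = [("s", "c", i, "g", 15, 15) for i in range(100)]
        rows += [("s", "c", 5000 + i, "del_gene", 0, 30) for i in range(3)]
        out = allele_specific_expression(self._counts(rows))
        assert (out[out["gene_id"] == "del_gene"]["p"] < 1e-6).all()


class TestBinPairCorrelation:
    def test_identical_and_negated_bins(self):
        bins = make_bins(build_genome_model({"c": 1_500_000}), 500_000)
        samples = ["s1", "s2", "s3", "s4"]
        sig = pd.DataFrame({
            "site_id": ["a", "b", "c"], "chrom": "c",
            "start": [100, 600_000, 1_100_000],
            "end": [200, 600_100, 1_100_100],
        })
        base = np.array([1.0, 2.0, 4.0, 3.0])
        for j, s in enumerate(samples):
            sig[s] = [base[j], base[j], 10 - base[j]]
        out = bin_pair_signal_correlation(sig, bins, samples)
        r01 = out[(out["bin1_id"] == 0) & (out["bin2_id"] == 1)]["r"].iloc[0]
        r02 = out[(out["bin1_id"] == 0) & (out["bin2_id"] == 2)]["r"].iloc[0]
        assert r01 == pytest.approx(1.0)
        assert r02 == pytest.approx(-1.0)

    def test_too_few_samples(self):
        bins = make_bins(build_genome_model({"c": 1_000_000}), 500_000)
        with pytest.raises(ValueError):
            bin_pair_signal_correlation(pd.DataFrame(), bins, ["a", "b"])


class TestFish:
    def test_product_normalization(self):
        f = pd.DataFrame({"distance": [12.0], "r_short": [3.0], "r_long": [4.0]})
        assert normalize_fish_distances(f)["norm_distance"].iloc[0] == 1.0
        g = normalize_fish_distances(f, "geometric")["norm_distance"].iloc[0]
        assert g == pytest.approx(12.0 / np.sqrt(12.0))

    def test_deletion_effect_detected(self):
        cfg = CohortConfig(seed=1, fish_effect=-0.3)
        f = simulate_fish_measurements(cfg, np.random.default_rng(5))
        res = fish_nested_anova(f)
        row = res.table[res.table["effect"] == "Deletion"].iloc[0]
        assert row["p"] < 0.05
        assert row["df1"] == 1 and row["df2"] == cfg.n_del + cfg.n_ctrl - 2

    def test_single_subject_group_rejected(self):
        f = pd.DataFrame({
            "subject": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "group": ["del"] * 3 + ["ctrl"] * 6,
            "gender": ["F"] * 9,
            "distance": np.arange(9.0) + 1,
            "r_short": 1.0, "r_long": 1.0,
        })
        with pytest.raises(ValueError):
            fish_nested_anova(f)

    def test_all_equal_distances_degenerate(self):
        f = pd.DataFrame({
            "subject": ["a"] * 2 + ["b"] * 2 + ["c"] * 2 + ["d"] * 2,
            "group": ["del"] * 4 + ["ctrl"] * 4,
            "gender": ["F", "F", "M", "M"] * 2,
            "distance": 5.0, "r_short": 1.0, "r_long": 1.0,
        })
        res = fish_nested_anova(f)
        assert (res.table["p"] == 1.0).all()


class TestSimpleDe:
    def _expr(self, rows, tss=None):
        n = len(rows)
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": "c", "tss": tss or list(range(0, 1000 * n, 1000)),
            "strand": "+",
        })
        for j, col in enumerate(GROUPS["del"] + GROUPS["ctrl"]):
            df[col] = [v[j] for v in rows]
        return df

    def test_low_expression_excluded(self):
        expr = self._expr([[0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
                           [9, 8, 10, 2, 2.5, 2]])
        out = simple_de_standin(expr, GROUPS)
        assert not out.loc[0, "expressed"]
        assert np.isnan(out.loc[0, "fdr"])

    def test_clear_effect_called(self, rng):
        rows = [list(rng.normal(5, 0.1, 6)) for _ in range(50)]
        rows += [[20, 21, 19, 5, 5, 5.2]] * 3
        out = simple_de_standin(self._expr(rows), GROUPS)
        assert out["de"].iloc[-3:].all()
        assert out["direction"].iloc[-1] == 1.0

    def test_null_rarely_calls(self, rng):
        calls = 0
        for _ in range(20):
            rows = [list(rng.normal(5, 1, 6)) for _ in range(40)]
            out = simple_de_standin(self._expr(rows), GROUPS)
            calls += int(out["de"].sum() > 0)
        assert calls <= 2
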