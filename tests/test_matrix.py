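import numpy as np
import pandas as pd
import pytest

from cnvhic.genome import build_genome_model, make_bins
from cnvhic.matrix import (
    ContactMatrix,
    bin_pairs_to_matrix,
    cis_window_fold_change_ranking,
    combine_group,
    depth_normalize,
    filter_pairs,
    fold_change_map,
)


@pytest.fixture()
def small_model():
    return build_genome_model({"cA": 4_000_000, "cB": 2_000_000}, cut_spacing=1000)


def _pairs(rows):
    cols = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df.insert(0, "read_id", np.arange(len(df)))
    df["strand1"] = "+"
    df["strand2"] = "-"
    return df


class TestFilterPairs:
    def test_exact_duplicates_removed(self, small_model):
        p = _pairs([("cA", 100, "cA", 900_000)] * 2)
        out, rep = filter_pairs(p, small_model, 500, "standard")
        assert len(out) == 1 and rep["duplicates"] == 1

    def test_self_ligation_removed(self, small_model):
        p = _pairs([("cA", 100, "cA", 300)])  # same 1-kbp fragment
        out, rep = filter_pairs(p, small_model, 500, "standard")
        assert len(out) == 0 and rep["self_ligation"] == 1

    def test_restriction_distance_sum_rule(self, small_model):
        # dist to nearest cut 300 on both ends: 600 > 500 -> removed
        p = _pairs([("cA", 1300, "cA", 900_300)])
        out, rep = filter_pairs(p, small_model, 500, "standard")
        assert len(out) == 0 and rep["restriction_distance"] == 1
        # 200+200 = 400 <= 500 -> kept
        p2 = _pairs([("cA", 1200, "cA", 900_200)])
        out2, _ = filter_pairs(p2, small_model, 500, "standard")
        assert len(out2) == 1

    def test_haplotype_mode_rules(self, small_model):
        # either end's distance > 1.5 x 300 = 450 -> removed
        p = _pairs([("cA", 1480, "cA", 900_000),      # dist1 480 > 450
                    ("cA", 1900, "cA", 2100),          # adjacent frags, span 200 < 450
                    ("cA", 1100, "cB", 1_900_100)])    # trans: span rule not applied
        out, rep = filter_pairs(p, small_model, 300, "haplotype")
        assert rep["restriction_distance"] == 1 and rep["short_span"] == 1
        assert len(out) == 1 and out.loc[0, "chrom2"] == "cB"

    def test_unknown_mode(self, small_model):
        with pytest.raises(ValueError):
            filter_pairs(_pairs([("cA", 1, "cA", 2)]), small_model, 500, "bogus")


class TestBinning:
    def test_single_pair_cell(self, small_model):
        bins = make_bins(small_model, 500_000)
        m = bin_pairs_to_matrix(_pairs([("cA", 100, "cA", 600_000)]), bins)
        assert m.data[0, 1] == 1 and m.total == 1

    def test_intra_bin_pair_on_diagonal(self, small_model):
        bins = make_bins(small_model, 500_000)
        m = bin_pairs_to_matrix(_pairs([("cA", 100, "cA", 200)]), bins)
        assert m.data[0, 0] == 1

    def test_mass_conservation(self, small_model, rng):
        bins = make_bins(small_model, 500_000)
        n = 10_000
        p = _pairs([("cA", int(a), "cA", int(b))
                    for a, b in rng.integers(0, 4_000_000, (n, 2))])
        assert bin_pairs_to_matrix(p, bins).total == n

    def test_unknown_chromosome(self, small_model):
        bins = make_bins(small_model, 500_000)
        with pytest.raises(ValueError):
            bin_pairs_to_matrix(_pairs([("cZ", 1, "cZ", 2)]), bins)


class TestDepthNormalize:
    def test_scales_to_target(self, small_model):
        bins = make_bins(small_model, 500_000)
        m = ContactMatrix.from_coo(bins, [0, 1], [1, 2], [2.0, 3.0])
        out = depth_normalize(m, 10.0)
        assert out.total == pytest.approx(10.0, rel=1e-9)
        assert out.data[0, 1] == pytest.approx(4.0)
        assert out.normalization == "depth_scaled"

    def test_double_normalization_rejected(self, small_model):
        bins = make_bins(small_model, 500_000)
        m = depth_normalize(ContactMatrix.from_coo(bins, [0], [1], [2.0]), 10.0)
        with pytest.raises(ValueError, match="already"):
            depth_normalize(m, 10.0)

    def test_empty_matrix_rejected(self, small_model):
        bins = make_bins(small_model, 500_000)
        with pytest.raises(ValueError, match="empty"):
            depth_normalize(ContactMatrix.from_coo(bins, [], [], []), 10.0)


class TestCombineGroup:
    def _mat(self, bins, cells, norm="depth_scaled"):
        b1, b2, v = zip(*cells)
        m = ContactMatrix.from_coo(bins, b1, b2, v)
        m.normalization = norm
        return m

    def test_identity(self, small_model):
        bins = make_bins(small_model, 500_000)
        m = self._mat(bins, [(0, 1, 2.0)])
        out = combine_group([m, m])
        assert out.data[0, 1] == 2.0

    def test_mean_and_zero_fill(self, small_model):
        bins = make_bins(small_model, 500_000)
        a = self._mat(bins, [(0, 1, 2.0), (1, 2, 6.0)])
        b = self._mat(bins, [(0, 1, 4.0)])
        out = combine_group([a, b])
        assert out.data[0, 1] == 3.0       # mean of {2, 4}
        assert out.data[1, 2] == 3.0       # missing cell treated as 0: 6/2

    def test_mixed_normalization_rejected(self, small_model):
        bins = make_bins(small_model, 500_000)
        a = self._mat(bins, [(0, 1, 2.0)])
        b = self._mat(bins, [(0, 1, 2.0)], norm="raw")
        with pytest.raises(ValueError, match="mixed"):
            combine_group([a, b])


class TestFoldChange:
    def _pair_of_means(self, small_model, d_cells, c_cells):
        bins = make_bins(small_model, 500_000)
        dm = ContactMatrix.from_coo(bins, *zip(*[(a, b) for a, b, _ in d_cells]),
                                    [v for *_, v in d_cells])
        cm = ContactMatrix.from_coo(bins, *zip(*[(a, b) for a, b, _ in c_cells]),
                                    [v for *_, v in c_cells])
        return dm, cm

    def test_equal_means_zero_both_modes(self, small_model):
        dm, cm = self._pair_of_means(small_model, [(0, 1, 8.0)], [(0, 1, 8.0)])
        for mode in ("relative_log2", "log2_ratio"):
            fc = fold_change_map(dm, cm, mode)
            assert fc.values[0, 1] == 0.0

    def test_log2_ratio_halving(self, small_model):
        dm, cm = self._pair_of_means(small_model, [(0, 1, 4.0)], [(0, 1, 8.0)])
        fc = fold_change_map(dm, cm, "log2_ratio", pseudocount=1e-9)
        assert fc.values[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_relative_log2_literal_formula(self, small_model):
        dm, cm = self._pair_of_means(small_model, [(0, 1, 4.0)], [(0, 1, 8.0)])
        fc = fold_change_map(dm, cm, "relative_log2", pseudocount=1e-9)
        assert fc.values[0, 1] == pytest.approx((2 - 3) / 3, abs=1e-6)

    def test_undefined_denominator_is_nan_and_counted(self, small_model):
        # c + eps = 1 -> log2 = 0 -> undefined relative fold change
        dm, cm = self._pair_of_means(small_model, [(0, 1, 4.0)], [(0, 2, 5.0)])
        fc = fold_change_map(dm, cm, "relative_log2", pseudocount=1.0)
        assert np.isnan(fc.values[0, 1])
        assert fc.n_undefined > 0
        assert not np.isinf(fc.values[np.isfinite(fc.values)]).any()

    def test_invalid_pseudocount(self, small_model):
        dm, cm = self._pair_of_means(small_model, [(0, 1, 1.0)], [(0, 1, 1.0)])
        with pytest.raises(ValueError):
            fold_change_map(dm, cm, "log2_ratio", pseudocount=0.0)


class TestCisWindowRanking:
    def test_all_equal_groups_give_unit_fold_change(self, small_model):
        bins = make_bins(small_model, 500_000)
        cells = [(i, j, 5.0) for i in range(8) for j in range(i, 8)]
        m = ContactMatrix.from_coo(bins, *zip(*[(a, b) for a, b, _ in cells]),
                                   [v for *_, v in cells])
        tab = cis_window_fold_change_ranking(m, m, "cA", (0, 500_000), 1_000_000)
        assert np.allclose(tab["fold_change"], 1.0)

    def test_short_last_window_reported(self, small_model):
        bins = make_bins(small_model, 500_000)
        m = ContactMatrix.from_coo(bins, [0], [1], [1.0])
        tab = cis_window_fold_change_ranking(m, m, "cA", (0, 500_000), 1_500_000)
        assert tab["end"].max() == 4_000_000
        spans = tab["end"] - tab["start"]
        assert spans.min() == 1_000_000  # 4 Mbp = 1.5 + 1.5 + short 1.0

    def test_anchor_wider_than_chromosome(self, small_model):
        bins = make_bins(small_model, 500_000)
        m = ContactMatrix.from_coo(bins, [0], [1], [1.0])
        with pytest.raises(ValueError):
            cis_window_fold_change_ranking(m, m, "cA", (0, 5_000_000), 1_000_000)


@pytest.fixture(scope="module")
def fc_cells(default_cohort, cohort_matrices):
    cfg = default_cohort.config
    bins = cohort_matrices["bins"]
    fc = fold_change_map(cohort_matrices["del_mean"],
                         cohort_matrices["ctrl_mean"], "log2_ratio")
    ch, ds, de = cfg.deletion
    res = bins.resolution
    off = bins.chrom_offsets[ch]
    n = bins.n_bins
    in_del = np.zeros(n, bool)
    in_del[off + ds // res: off + de // res] = True
    left = np.zeros(n, bool)
    left[off: off + ds // res] = True
    right = np.zeros(n, bool)
    right[off + de // res: off + bins.n_bins_chrom(ch)] = True
    chrom = bins.bin_chrom()
    iu, ju = np.triu_indices(n)
    return {
        "vals": fc.values[iu, ju],
        "cis": chrom[iu] == chrom[ju],
        "one_del": in_del[iu] ^ in_del[ju],
        "both_out": ~in_del[iu] & ~in_del[ju],
        "straddle": (left[iu] & right[ju]) | (right[iu] & left[ju]),
    }


class TestCohortFoldChangeProperties:
    """Copy-number signal on the simulated cohort (heterozygous halving)."""

    def test_one_deletion_endpoint_cis_cells_halved(self, fc_cells):
        m = np.nanmean(fc_cells["vals"][fc_cells["cis"] & fc_cells["one_del"]])
        assert -1.2 <= m <= -0.8

    def test_background_cis_cells_unchanged(self, fc_cells):
        sel = fc_cells["cis"] & fc_cells["both_out"] & ~fc_cells["straddle"]
        assert -0.1 <= np.nanmean(fc_cells["vals"][sel]) <= 0.1

    def test_trans_cells_with_deletion_endpoint_halved(self, fc_cells):
        m = np.nanmean(fc_cells["vals"][~fc_cells["cis"] & fc_cells["one_del"]])
        assert -1.2 <= m <= -0.8

    def test_flank_contacts_follow_distance_decay_prediction(
            self, default_cohort, cohort_matrices):
        """Deletion-straddling cells exceed control by the haplotype-frame
        distance-decay factor (1 + (d/(d-L))^alpha)/2, within 25% on the
        block aggregate."""
        cfg = default_cohort.config
        bins = cohort_matrices["bins"]
        d = cohort_matrices["del_mean"].dense_symmetric()
        c = cohort_matrices["ctrl_mean"].dense_symmetric()
        ch, ds, de = cfg.deletion
        res = bins.resolution
        off = bins.chrom_offsets[ch]
        L = de - ds
        pi = range(off + (ds - 2_000_000) // res, off + ds // res)
        pj = range(off + de // res, off + (de + 2_000_000) // res)
        obs = pred = base = 0.0
        for i in pi:
            for j in pj:
                s_ref = (j - i) * res
                f = (1 + (s_ref / (s_ref - L)) ** cfg.decay_exponent) / 2
                pred += f * c[i, j]
                obs += d[i, j]
                base += c[i, j]
        assert obs / base == pytest.approx(pred / base, rel=0.25)

    def test_telomeric_hotspot_ranks_among_top_windows(
            self, default_cohort, cohort_matrices):
        """The injected distal-flank <-> telomere interaction ranks within
        two places of the top (flank) window, as in the windowed ranking
        of cis fold changes."""
        cfg = default_cohort.config
        tab = cis_window_fold_change_ranking(
            cohort_matrices["del_mean"], cohort_matrices["ctrl_mean"],
            "chr22s", (21_500_000, 22_000_000), 1_000_000, default_cohort.genome)
        hot = tab[(tab["start"] == 49_000_000)]
        assert hot["rank"].iloc[0] <= 3
        flank_rank = tab[tab["start"].isin([17_000_000, 18_000_000])]["rank"].min()
        assert hot["rank"].iloc[0] - flank_rank <= 2
        assert tab[tab["start"] == 19_000_000]["overlaps_deletion"].iloc[0]
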