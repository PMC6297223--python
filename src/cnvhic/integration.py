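"""ChIP/RNA/FISH integration statistics.

Z-scored differential binding, binned Fisher enrichment against the
genome-wide background, peak-to-TSS assignment with per-mark distance
cutoffs, permutation tests coupling expression change to histone-mark
change, allele-specific expression by exact binomial tests, bin-pair
epigenetic correlation, and the nested ANOVA for 3D-FISH distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .genome import BinScheme

#: per-mark |Z| cutoffs for the TSS-side differential-binding partition
TSS_Z_CUTOFFS = {"H3K27ac": 1.0, "H3K27me3": 2.0}
#: per-mark TSS distance cutoffs (bp)
TSS_DISTANCE_CUTOFFS = {"H3K27ac": 1000, "H3K27me3": 5000}


def _group_columns(table: pd.DataFrame, groups: dict[str, list[str]]) -> None:
    for g, cols in groups.items():
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"missing sample columns for group {g!r}: {missing}")


def zscore_differential_sites(
    signal: pd.DataFrame,
    groups: dict[str, list[str]],
    z_cutoff: float = 2.0,
    pseudocount: float = 1e-3,
) -> pd.DataFrame:
    """Per-site log2 fold change, Z-scored over sites, flagged by cutoff.

    log2FC = log2((mean_del + e) / (mean_ctrl + e)); Z standardizes the
    log2FCs across the sites of the table (one mark at a time).
    """
    _group_columns(signal, groups)
    out = signal.copy()
    md = signal[groups["del"]].mean(axis=1).to_numpy()
    mc = signal[groups["ctrl"]].mean(axis=1).to_numpy()
    log2fc = np.log2(md + pseudocount) - np.log2(mc + pseudocount)
    sd = log2fc.std(ddof=1)
    if sd == 0:
        raise ValueError("all sites have identical log2FC (sd = 0)")
    z = (log2fc - log2fc.mean()) / sd
    out["log2fc"] = log2fc
    out["zscore"] = z
    out["significant"] = np.abs(z) > z_cutoff
    return out


def binned_enrichment(
    features: pd.DataFrame, bins: BinScheme, flag_col: str = "significant"
) -> pd.DataFrame:
    """Per-bin Fisher enrichment of flagged features vs the genome-wide rest.

    ``features`` needs chrom, a position column (``pos`` or midpoint of
    start/end) and a boolean flag.  Bins with no feature get p = NA; BH
    correction runs across tested bins.
    """
    feat = features.copy()
    if "pos" not in feat.columns:
        feat["pos"] = (feat["start"] + feat["end"]) // 2
    known = feat["chrom"].isin(bins.chrom_offsets)
    feat = feat[known]
    bid = bins.bin_id(feat["chrom"], feat["pos"].to_numpy())
    flags = feat[flag_col].to_numpy().astype(bool)
    n = bins.n_bins
    total = np.bincount(bid, minlength=n)
    sig = np.bincount(bid[flags], minlength=n)
    all_sig, all_total = int(flags.sum()), int(len(feat))
    pvals = np.full(n, np.nan)
    for b in np.where(total > 0)[0]:
        tab = [
            [int(sig[b]), int(total[b] - sig[b])],
            [all_sig - int(sig[b]), (all_total - int(total[b])) - (all_sig - int(sig[b]))],
        ]
        pvals[b] = st.fisher_exact(tab, alternative="two-sided")[1]
    out = bins.bins.copy()
    out["n_total"] = total
    out["n_sig"] = sig
    out["p"] = pvals
    tested = ~np.isnan(pvals)
    fdr = np.full(n, np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out["fdr"] = fdr
    return out


def assign_peaks_to_tss(
    sites: pd.DataFrame, genes: pd.DataFrame, cutoff: int
) -> pd.DataFrame:
    """Nearest-TSS assignment with a distance cutoff.

    Each site goes to its nearest TSS (same chromosome, midpoint distance,
    signed by gene strand); if a gene attracts several sites only the
    nearest is retained; assignments beyond ``cutoff`` are dropped.
    """
    recs = []
    for chrom, s in sites.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        tss = g["tss"].to_numpy()
        order = np.argsort(tss, kind="stable")
        tss_sorted = tss[order]
        mid = ((s["start"] + s["end"]) // 2).to_numpy()
        right = np.searchsorted(tss_sorted, mid)
        left = np.clip(right - 1, 0, tss_sorted.size - 1)
        right = np.clip(right, 0, tss_sorted.size - 1)
        d_left = np.abs(mid - tss_sorted[left])
        d_right = np.abs(mid - tss_sorted[right])
        pick = np.where(d_right < d_left, right, left)
        gi = order[pick]
        dist = mid - tss[gi]
        strand = g["strand"].to_numpy()[gi]
        signed = np.where(strand == "+", dist, -dist)
        recs.append(
            pd.DataFrame(
                {
                    "site_id": s["site_id"].to_numpy(),
                    "gene_id": g["gene_id"].to_numpy()[gi],
                    "distance": signed,
                }
            )
        )
    if not recs:
        return pd.DataFrame(columns=["site_id", "gene_id", "distance"])
    out = pd.concat(recs, ignore_index=True)
    out = out[np.abs(out["distance"]) <= cutoff]
    out = (
        out.assign(absd=np.abs(out["distance"]))
        .sort_values(["gene_id", "absd"], kind="stable")
        .drop_duplicates("gene_id", keep="first")
        .drop(columns="absd")
        .reset_index(drop=True)
    )
    return out


def group_permutation_test(
    a: np.ndarray, b: np.ndarray, n_perm: int = 9999, seed: int = 0,
    exact: bool | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test on the difference of group means.

    Monte Carlo p = (1 + #{|perm stat| >= |observed|}) / (n_perm + 1);
    membership is redistributed between the two compared groups only.
    When the number of distinct regroupings is small (or ``exact=True``),
    all of them are enumerated and the p value is exact.
    """
    from math import comb
    from itertools import combinations

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("a compared group is empty")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    if exact is None:
        exact = comb(pooled.size, a.size) <= 20_000
    if exact:
        hits = total = 0
        nb = b.size
        for idx in combinations(range(pooled.size), a.size):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            hits += abs(stat) >= abs(obs) - 1e-12
            total += 1
        return float(obs), hits / total
    rng = np.random.default_rng(seed)
    n = a.size
    total = pooled.sum()
    # vectorized: permute indices for all replicates at once
    stats = np.empty(n_perm)
    block = 500
    for s0 in range(0, n_perm, block):
        k = min(block, n_perm - s0)
        idx = np.argsort(rng.random((k, pooled.size)), axis=1)[:, :n]
        sums = pooled[idx].sum(axis=1)
        stats[s0:s0 + k] = sums / n - (total - sums) / b.size
    p = (1.0 + np.sum(np.abs(stats) >= abs(obs) - 1e-12)) / (n_perm + 1.0)
    return float(obs), float(p)


def expression_chromatin_correlation(
    expr: pd.DataFrame,
    assign: pd.DataFrame,
    signal: pd.DataFrame,
    samples: list[str],
    n_bg_perm: int = 10,
    seed: int = 0,
) -> dict:
    """Observed vs permuted-background FPKM/ChIP Pearson correlations.

    For each assigned gene, r between its FPKM and its TSS site's
    normalized counts across shared samples; background r values come from
    permuting that gene's FPKM across samples (``n_bg_perm`` draws per
    gene); the two distributions are compared by a two-sided Wilcoxon
    rank-sum test.
    """
    if len(samples) < 4:
        raise ValueError("need at least 4 shared samples")
    rng = np.random.default_rng(seed)
    e = expr.set_index("gene_id")
    s = signal.set_index("site_id")
    obs, bg = [], []
    n_excluded = 0
    for row in assign.itertuples(index=False):
        x = e.loc[row.gene_id, samples].to_numpy(dtype=np.float64)
        y = s.loc[row.site_id, samples].to_numpy(dtype=np.float64)
        if x.std() == 0 or y.std() == 0:
            n_excluded += 1
            continue
        obs.append(np.corrcoef(x, y)[0, 1])
        for _ in range(n_bg_perm):
            bg.append(np.corrcoef(rng.permutation(x), y)[0, 1])
    obs = np.asarray(obs)
    bg = np.asarray(bg)
    if obs.size == 0:
        raise ValueError("no testable genes")
    w = st.mannwhitneyu(obs, bg, alternative="two-sided")
    return {
        "observed_r": obs,
        "background_r": bg,
        "wilcoxon_p": float(w.pvalue),
        "n_genes": int(obs.size),
        "n_excluded": n_excluded,
    }


def allele_specific_expression(
    counts: pd.DataFrame, min_coverage: int = 10
) -> pd.DataFrame:
    """Exact binomial ASE tests against each sample's background frequency.

    Background p0 is the per-sample mean alternative-allele fraction over
    qualifying SNVs (coverage strictly above ``min_coverage``); each SNV's
    alt count is tested two-sided against Binomial(coverage, p0).
    """
    out = []
    for sample, sub in counts.groupby("sample", sort=False):
        cov = (sub["ref_count"] + sub["alt_count"]).to_numpy()
        keep = cov > min_coverage
        sub = sub[keep]
        cov = cov[keep]
        if len(sub) == 0:
            continue
        frac = sub["alt_count"].to_numpy() / cov
        p0 = float(frac.mean())
        if p0 <= 0.0 or p0 >= 1.0:
            raise ValueError(f"degenerate background frequency p0={p0} for {sample}")
        pvals = np.array(
            [
                st.binomtest(int(a), int(n), p0, alternative="two-sided").pvalue
                for a, n in zip(sub["alt_count"], cov)
            ]
        )
        res = sub.copy()
        res["coverage"] = cov
        res["alt_fraction"] = frac
        res["background_p0"] = p0
        res["p"] = pvals
        out.append(res)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def bin_pair_signal_correlation(
    signal: pd.DataFrame, bins: BinScheme, samples: list[str]
) -> pd.DataFrame:
    """Pearson r between same-chromosome 500-kbp bins of mean ChIP signal.

    Per bin and sample, the mean normalized count over the bin's sites;
    then r (and its t-transform p) across samples for every same-chromosome
    bin pair with data.  Constant bins yield r = NA.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    feat = signal.copy()
    feat["pos"] = (feat["start"] + feat["end"]) // 2
    feat = feat[feat["chrom"].isin(bins.chrom_offsets)]
    bid = bins.bin_id(feat["chrom"], feat["pos"].to_numpy())
    feat = feat.assign(bin_id=bid)
    means = feat.groupby("bin_id")[samples].mean()
    chrom_of = bins.bins.set_index("bin_id")["chrom"]
    nsamp = len(samples)
    rows = []
    for chrom in bins.chrom_offsets:
        ids = [b for b in means.index if chrom_of[b] == chrom]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                x = means.loc[ids[i], samples].to_numpy(dtype=np.float64)
                y = means.loc[ids[j], samples].to_numpy(dtype=np.float64)
                if x.std() == 0 or y.std() == 0:
                    r, p = np.nan, np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                    if abs(r) >= 1.0:
                        p = 0.0
                    else:
                        t = r * np.sqrt((nsamp - 2) / (1 - r * r))
                        p = float(2.0 * st.t.sf(abs(t), nsamp - 2))
                rows.append((chrom, ids[i], ids[j], r, p))
    return pd.DataFrame(rows, columns=["chrom", "bin1_id", "bin2_id", "r", "p"])


@dataclass
class FishAnovaResult:
    table: pd.DataFrame  # effect, df1, df2, F, p
    subject_means: pd.DataFrame


def normalize_fish_distances(fish: pd.DataFrame, mode: str = "product") -> pd.DataFrame:
    """Normalize raw probe distances by the nuclear radii.

    ``product`` divides by r_short * r_long (default); ``geometric`` by
    sqrt(r_short * r_long).
    """
    out = fish.copy()
    if mode == "product":
        out["norm_distance"] = out["distance"] / (out["r_short"] * out["r_long"])
    elif mode == "geometric":
        out["norm_distance"] = out["distance"] / np.sqrt(out["r_short"] * out["r_long"])
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out


def fish_nested_anova(fish: pd.DataFrame, mode: str = "product") -> FishAnovaResult:
    """Distance ~ Deletion + Gender + Subject nested within Deletion.

    Subject is a random effect: the Deletion contrast is tested against the
    between-subject mean square (one-way ANOVA on subject means, the
    expected-mean-squares solution), while Gender is tested against the
    cell-level residual after removing deletion, gender and subject terms.
    """
    fish = normalize_fish_distances(fish, mode)
    sm = fish.groupby(["subject", "group", "gender"], sort=True)["norm_distance"].mean().reset_index()
    counts = sm.groupby("group")["subject"].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 subjects per deletion group")
    groups = [sm.loc[sm["group"] == g, "norm_distance"].to_numpy() for g in counts.index]
    k = len(groups)
    nsubj = sm.shape[0]
    grand = sm["norm_distance"].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, nsubj - k
    if ss_within <= 1e-12 * (grand ** 2 + 1.0):
        f_del, p_del = 0.0, 1.0
    else:
        f_del = (ss_between / df1) / (ss_within / df2)
        p_del = float(st.f.sf(f_del, df1, df2))

    # sequential cell-level fit for the gender term
    y = fish["norm_distance"].to_numpy()
    d = pd.get_dummies(fish["group"], drop_first=True).to_numpy(dtype=np.float64)
    g = pd.get_dummies(fish["gender"], drop_first=True).to_numpy(dtype=np.float64)
    s = pd.get_dummies(fish["subject"], drop_first=True).to_numpy(dtype=np.float64)
    ones = np.ones((y.size, 1))

    def rss(X):
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fit = X @ beta
        return float(((y - fit) ** 2).sum()), int(rank)

    r1, k1 = rss(np.hstack([ones, d]))
    r2, k2 = rss(np.hstack([ones, d, g]))
    r3, k3 = rss(np.hstack([ones, d, g, s]))
    tol = 1e-12 * float(y @ y + 1.0)  # all-equal data leave ~0 residual
    df_gender = k2 - k1
    df_resid = y.size - k3
    if df_gender == 0 or r3 <= tol:
        f_gen, p_gen = 0.0, 1.0
    else:
        f_gen = ((r1 - r2) / df_gender) / (r3 / df_resid)
        p_gen = float(st.f.sf(f_gen, df_gender, df_resid))
    df_subj = k3 - k2
    if df_subj > 0 and r3 > tol:
        f_subj = ((r2 - r3) / df_subj) / (r3 / df_resid)
        p_subj = float(st.f.sf(f_subj, df_subj, df_resid))
    else:
        f_subj, p_subj = 0.0, 1.0
    table = pd.DataFrame(
        [
            ("Deletion", df1, df2, f_del, p_del),
            ("Gender", df_gender, df_resid, f_gen, p_gen),
            ("Subject(Deletion)", df_subj, df_resid, f_subj, p_subj),
        ],
        columns=["effect", "df1", "df2", "F", "p"],
    )
    return FishAnovaResult(table, sm)


def simple_de_standin(
    expr: pd.DataFrame,
    groups: dict[str, list[str]],
    fpkm_filter: float = 0.5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Plumbing-grade differential expression: Welch t on log2(FPKM+1), BH.

    Genes whose mean FPKM over all samples falls below ``fpkm_filter`` are
    excluded before testing (low-expression filter).
    """
    _group_columns(expr, groups)
    allcols = groups["del"] + groups["ctrl"]
    out = expr.copy()
    mean_fpkm = expr[allcols].mean(axis=1).to_numpy()
    out["mean_fpkm"] = mean_fpkm
    out["expressed"] = mean_fpkm >= fpkm_filter
    ld = np.log2(expr[groups["del"]].to_numpy(dtype=np.float64) + 1.0)
    lc = np.log2(expr[groups["ctrl"]].to_numpy(dtype=np.float64) + 1.0)
    nd, nc = ld.shape[1], lc.shape[1]
    md, mc = ld.mean(axis=1), lc.mean(axis=1)
    vd, vc = ld.var(axis=1, ddof=1), lc.var(axis=1, ddof=1)
    se2 = vd / nd + vc / nc
    import scipy.special as spsp

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (md - mc) / np.sqrt(se2)
        dfree = se2 ** 2 / ((vd / nd) ** 2 / (nd - 1) + (vc / nc) ** 2 / (nc - 1))
        p = 2.0 * spsp.stdtr(dfree, -np.abs(t))
    p[se2 == 0] = np.nan
    out["log2fc"] = md - mc
    out["p"] = p
    qv = np.full(len(out), np.nan)
    testable = out["expressed"].to_numpy() & ~np.isnan(p)
    if testable.any():
        qv[testable] = multipletests(p[testable], method="fdr_bh")[1]
    out["fdr"] = qv
    out["de"] = (qv < fdr) & testable
    out["direction"] = np.sign(out["log2fc"])
    return out
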