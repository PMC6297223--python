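"""Homolog-specific contact maps via phased heterozygous SNVs.

Reads covering phased SNVs are assigned to the homologous chromosome whose
alleles they carry; pairs are resolved to a haplotype when at least one end
is informative and no end conflicts; contacts involving the deletion region
are density-equalized by random position sampling so both homologs' maps are
built from comparable information content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinScheme, GenomeModel
from .matrix import ContactMatrix, bin_pairs_to_matrix


def assign_read_haplotype(tags: list[tuple[int, str]], variants: pd.DataFrame) -> tuple[str, int]:
    """Assign a single read from its (pos, observed allele) tags.

    Returns (haplotype, n_supporting_snvs) with haplotype in
    H1/H2/unknown/conflict.  A read is H1 if every covered SNV carries the
    hap1 allele (and at least one SNV is covered); symmetrically for H2; a
    mixed or non-matching allele is a conflict.
    """
    if not tags:
        return "unknown", 0
    by_pos = variants.set_index("pos")
    h1 = h2 = 0
    for pos, allele in tags:
        if pos not in by_pos.index:
            raise ValueError(f"tag position {pos} not in variant table")
        row = by_pos.loc[pos]
        if allele == row["hap1_allele"]:
            h1 += 1
        elif allele == row["hap2_allele"]:
            h2 += 1
        else:
            return "conflict", h1 + h2
    if h1 and h2:
        return "conflict", h1 + h2
    return ("H1", h1) if h1 else ("H2", h2)


def resolve_pair_haplotype(hap1: str, hap2: str) -> tuple[str, str]:
    """Combine the two ends' assignments into a pair haplotype.

    Returns (haplotype or 'discard', reason).  Concordant or one-sided
    evidence resolves; double-unknown, cross-haplotype and any conflict
    are discarded with a counted reason.
    """
    if "conflict" in (hap1, hap2):
        return "discard", "conflict"
    known = {h for h in (hap1, hap2) if h != "unknown"}
    if not known:
        return "discard", "both_unknown"
    if len(known) == 2:
        return "discard", "cross_haplotype"
    return known.pop(), "ok"


def assign_pairs(
    pairs: pd.DataFrame, tags: pd.DataFrame, variants: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Vectorized haplotype assignment of a whole pair table.

    ``tags`` holds per-end SNV observations (read_id, end, snv_chrom,
    snv_pos, allele).  Adds hap1/hap2 end calls and a ``pair_hap`` column;
    returns the table plus discard counts by reason.
    """
    merged = tags.merge(
        variants.rename(columns={"chrom": "snv_chrom", "pos": "snv_pos"}),
        on=["snv_chrom", "snv_pos"],
        how="left",
        validate="many_to_one",
    )
    if merged["hap1_allele"].isna().any():
        raise ValueError("tag position not in variant table")
    m1 = (merged["allele"] == merged["hap1_allele"]).to_numpy()
    m2 = (merged["allele"] == merged["hap2_allele"]).to_numpy()
    bad = ~(m1 | m2)
    rid_index = pd.Index(pairs["read_id"])
    code = rid_index.get_indexer(merged["read_id"])
    if (code < 0).any():
        raise ValueError("tag read_id not present in pair table")
    key = code * 2 + (merged["end"].to_numpy() == 2)
    n2 = 2 * len(pairs)
    s1 = np.zeros(n2, dtype=bool)
    s2 = np.zeros(n2, dtype=bool)
    sbad = np.zeros(n2, dtype=bool)
    np.logical_or.at(s1, key, m1)
    np.logical_or.at(s2, key, m2)
    np.logical_or.at(sbad, key, bad)
    call = np.select(
        [sbad | (s1 & s2), s1, s2], ["conflict", "H1", "H2"], default="unknown"
    )
    out = pairs.copy()
    out["hap1"] = call[0::2]
    out["hap2"] = call[1::2]

    h1, h2 = out["hap1"].to_numpy(), out["hap2"].to_numpy()
    conflict = (h1 == "conflict") | (h2 == "conflict")
    known1 = np.isin(h1, ("H1", "H2"))
    known2 = np.isin(h2, ("H1", "H2"))
    cross = known1 & known2 & (h1 != h2)
    both_unknown = ~known1 & ~known2 & ~conflict
    pair_hap = np.where(known1, h1, h2)
    pair_hap = np.where(conflict | cross | both_unknown, "discard", pair_hap)
    out["pair_hap"] = pair_hap
    report = {
        "conflict": int(conflict.sum()),
        "cross_haplotype": int((cross & ~conflict).sum()),
        "both_unknown": int(both_unknown.sum()),
        "assigned": int((pair_hap != "discard").sum()),
    }
    return out, report


@dataclass
class RegionSampling:
    """Density-equalization sampling of the deletion region."""

    region: tuple[str, int, int]
    expected: int
    replicates: list[np.ndarray]  # sorted bp positions per replicate


def equalize_snv_density(
    variants: pd.DataFrame,
    model: GenomeModel,
    region: tuple[str, int, int],
    n_samplings: int = 10,
    rng: np.random.Generator | None = None,
) -> RegionSampling:
    """Sample random single-bp positions in ``region`` to the expected
    phased-SNV count implied by the rest of the chromosome's density.

    expected = round(region length x density), with density the phased-SNV
    count outside the region divided by the chromosome length minus the
    region length.  Each replicate is a uniform draw without replacement.
    """
    rng = rng or np.random.default_rng()
    chrom, start, end = region
    length = model.chromosomes[chrom]
    region_len = end - start
    if region_len >= length:
        raise ValueError("region covers the whole chromosome; no density basis")
    on_chrom = variants[variants["chrom"] == chrom]
    pos = on_chrom["pos"].to_numpy()
    outside = int(((pos < start) | (pos >= end)).sum())
    if outside == 0:
        raise ValueError("no phased SNVs outside the region")
    density = outside / (length - region_len)
    expected = int(round(region_len * density))
    if expected > region_len:
        raise ValueError("expected count exceeds region length")
    reps = [
        np.sort(rng.choice(region_len, size=expected, replace=False) + start)
        for _ in range(n_samplings)
    ]
    return RegionSampling((chrom, start, end), expected, reps)


@dataclass
class HaplotypeMatrixSet:
    """Per-homolog contact matrices (one set per sampling replicate)."""

    h1: ContactMatrix
    h2: ContactMatrix
    replicate: int = 0
    expected_snvs: int | None = None


def build_haplotype_matrix(
    pairs: pd.DataFrame,
    bins: BinScheme,
    sampling: RegionSampling | None = None,
    model: GenomeModel | None = None,
    sample_id: str = "",
) -> list[HaplotypeMatrixSet]:
    """Bin haplotype-resolved pairs into per-homolog matrices.

    Pairs must carry a ``pair_hap`` column.  When a region sampling is
    given, contacts with an endpoint inside the region are retained only if
    that endpoint's restriction fragment contains a sampled position (a
    contact is a fragment-level event, so fragment membership is what
    "involving a sampled position" means operationally); the rule applies
    to both homologs symmetrically, so region rows of the two maps are
    built from comparable information.  One matrix set per replicate.
    """
    if "pair_hap" not in pairs.columns:
        raise ValueError("pairs lack haplotype resolution (run assign_pairs first)")
    resolved = pairs[pairs["pair_hap"].isin(("H1", "H2"))]
    if sampling is None:
        return [_one_matrix_set(resolved, bins, 0, None, sample_id)]
    if model is None:
        raise ValueError("region sampling requires the genome model (fragment map)")
    chrom, start, end = sampling.region
    cuts = model.fragment_map[chrom]
    in1 = ((resolved["chrom1"] == chrom) & (resolved["pos1"] >= start)
           & (resolved["pos1"] < end)).to_numpy()
    in2 = ((resolved["chrom2"] == chrom) & (resolved["pos2"] >= start)
           & (resolved["pos2"] < end)).to_numpy()
    frag1 = np.searchsorted(cuts, resolved["pos1"].to_numpy(), side="right")
    frag2 = np.searchsorted(cuts, resolved["pos2"].to_numpy(), side="right")
    sets = []
    for r, sampled in enumerate(sampling.replicates):
        sampled_frags = np.unique(np.searchsorted(cuts, sampled, side="right"))
        keep = np.ones(len(resolved), dtype=bool)
        keep[in1] &= np.isin(frag1[in1], sampled_frags)
        keep[in2] &= np.isin(frag2[in2], sampled_frags)
        sets.append(_one_matrix_set(resolved.loc[keep], bins, r, sampling.expected, sample_id))
    return sets


def _one_matrix_set(resolved, bins, replicate, expected, sample_id) -> HaplotypeMatrixSet:
    mats = {}
    for hap in ("H1", "H2"):
        sub = resolved[resolved["pair_hap"] == hap]
        mats[hap] = bin_pairs_to_matrix(sub, bins, sample_id=f"{sample_id}:{hap}")
    return HaplotypeMatrixSet(mats["H1"], mats["H2"], replicate, expected)


def mean_matrix_set(sets: list[HaplotypeMatrixSet]) -> HaplotypeMatrixSet:
    """Average the per-replicate homolog matrices (reported default)."""
    import scipy.sparse as sp

    def _mean(ms):
        acc = ms[0].data.copy()
        for m in ms[1:]:
            acc = acc + m.data
        acc = acc / len(ms)
        out = ContactMatrix(ms[0].bin_scheme, sp.csr_matrix(acc),
                            sample_id=ms[0].sample_id,
                            normalization=ms[0].normalization,
                            total_raw_pairs=float(np.mean([m.total_raw_pairs for m in ms])))
        return out

    return HaplotypeMatrixSet(
        _mean([s.h1 for s in sets]), _mean([s.h2 for s in sets]),
        replicate=-1, expected_snvs=sets[0].expected_snvs,
    )


def haplotype_difference_map(
    mset: HaplotypeMatrixSet, deleted_hap: str = "H1"
) -> tuple[np.ndarray, dict]:
    """Deleted-homolog minus intact-homolog contacts, per cell.

    Both homolog matrices are scaled to equal assigned-pair totals before
    subtraction; returns the dense signed difference and scaling metadata.
    """
    a = mset.h1 if deleted_hap == "H1" else mset.h2
    b = mset.h2 if deleted_hap == "H1" else mset.h1
    if a.bin_scheme.n_bins != b.bin_scheme.n_bins:
        raise ValueError("bin schemes differ")
    ta, tb = a.total, b.total
    target = (ta + tb) / 2.0
    da = a.dense_symmetric() * (target / ta if ta else 1.0)
    db = b.dense_symmetric() * (target / tb if tb else 1.0)
    return da - db, {"scale_deleted": target / ta if ta else 1.0,
                     "scale_intact": target / tb if tb else 1.0}


def detect_phasing_switches(
    pairs: pd.DataFrame, chrom: str, chrom_length: int, window: int, bin_size: int = 0
) -> pd.DataFrame:
    """Flag candidate haplotype switch points from cross-haplotype pairs.

    A phasing switch (e.g. an unmodeled recombination) flips haplotype
    labels distal of some position, so genuinely intra-homolog contacts
    spanning that position look cross-haplotype.  For every candidate
    breakpoint on a ``window`` grid, the both-ends-informative cis pairs
    straddling it are counted: candidates where cross-haplotype straddlers
    outnumber concordant ones are flagged (report only, no correction).
    """
    if bin_size and window < bin_size:
        raise ValueError("window smaller than bin size")
    cis = pairs[(pairs["chrom1"] == chrom) & (pairs["chrom2"] == chrom)]
    h1 = cis["hap1"].to_numpy()
    h2 = cis["hap2"].to_numpy()
    known = np.isin(h1, ("H1", "H2")) & np.isin(h2, ("H1", "H2"))
    cross = known & (h1 != h2)
    concord = known & (h1 == h2)
    p1 = cis["pos1"].to_numpy()
    p2 = cis["pos2"].to_numpy()
    lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
    flagged = []
    for b in range(window, chrom_length, window):
        straddle = (lo < b) & (hi >= b)
        c = int((straddle & cross).sum())
        k = int((straddle & concord).sum())
        if c > k:
            flagged.append((chrom, max(0, b - window // 2),
                            min(b + window // 2, chrom_length), b, c, k))
    return pd.DataFrame(
        flagged,
        columns=["chrom", "start", "end", "breakpoint", "n_cross", "n_concordant"],
    )
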