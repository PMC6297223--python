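"""Binned contact matrices: pair filtering, binning, depth normalization,
group means and fold-change maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import BinScheme, GenomeModel


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts, stored as the upper triangle.

    ``normalization`` is ``raw`` straight after binning and ``depth_scaled``
    after per-sample scaling to a fixed total; ``total_raw_pairs`` is always
    the pre-scaling pair count.
    """

    bin_scheme: BinScheme
    data: sp.csr_matrix  # upper-triangular (bin1 <= bin2)
    sample_id: str = ""
    normalization: str = "raw"
    total_raw_pairs: float = 0.0
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_coo(cls, scheme: BinScheme, bin1, bin2, values, **kw):
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        lo = np.minimum(bin1, bin2)
        hi = np.maximum(bin1, bin2)
        n = scheme.n_bins
        m = sp.coo_matrix((np.asarray(values, dtype=np.float64), (lo, hi)), shape=(n, n))
        kw.setdefault("total_raw_pairs", float(m.sum()))
        return cls(scheme, m.tocsr(), **kw)

    @property
    def total(self) -> float:
        return float(self.data.sum())

    def to_coo_frame(self) -> pd.DataFrame:
        coo = self.data.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return pd.DataFrame(
            {"bin1_id": coo.row[order], "bin2_id": coo.col[order], "value": coo.data[order]}
        )

    def dense_symmetric(self) -> np.ndarray:
        d = self.data.toarray()
        full = d + d.T
        full[np.diag_indices_from(full)] = np.diag(d)
        return full

    def cis_dense(self, chrom: str) -> np.ndarray:
        sl = self.bin_scheme.chrom_slice(chrom)
        return self.dense_symmetric()[sl, sl]


@dataclass
class FoldChangeMap:
    """Bin-pair fold-change contrast between two group-mean matrices."""

    bin_scheme: BinScheme
    values: np.ndarray  # dense symmetric, NaN where undefined
    mode: str
    pseudocount: float
    n_undefined: int = 0


def filter_pairs(
    pairs: pd.DataFrame,
    model: GenomeModel,
    library_fragment_length: float = 500.0,
    mode: str = "standard",
) -> tuple[pd.DataFrame, dict]:
    """Remove duplicate, self-ligation and off-fragment read pairs.

    ``standard`` mode removes pairs whose summed distances from mapped
    positions to the nearest restriction site exceed the Hi-C library
    fragment length.  ``haplotype`` mode (used for homolog-specific maps)
    instead removes pairs with either distance above 1.5x the fragment
    length, or a same-chromosome end-to-end span below 1.5x the fragment
    length.  Returns the retained table plus a per-category report.
    """
    if mode not in ("standard", "haplotype"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if not model.fragment_map:
        raise ValueError("genome model has no fragment map")
    report = {"input": len(pairs)}
    key = pairs[["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]]
    dup = key.duplicated(keep="first").to_numpy()
    report["duplicates"] = int(dup.sum())
    pairs = pairs.loc[~dup]

    frag1 = np.empty(len(pairs), dtype=np.int64)
    frag2 = np.empty(len(pairs), dtype=np.int64)
    dist1 = np.empty(len(pairs), dtype=np.int64)
    dist2 = np.empty(len(pairs), dtype=np.int64)
    for chrom in pd.unique(pairs["chrom1"]):
        m = (pairs["chrom1"] == chrom).to_numpy()
        frag1[m], dist1[m] = model.assign_to_fragment(chrom, pairs.loc[m, "pos1"].to_numpy())
    for chrom in pd.unique(pairs["chrom2"]):
        m = (pairs["chrom2"] == chrom).to_numpy()
        frag2[m], dist2[m] = model.assign_to_fragment(chrom, pairs.loc[m, "pos2"].to_numpy())

    same_chrom = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    selflig = same_chrom & (frag1 == frag2)
    report["self_ligation"] = int(selflig.sum())
    keep = ~selflig
    if mode == "standard":
        bad = (dist1 + dist2) > library_fragment_length
        report["restriction_distance"] = int((bad & keep).sum())
        keep &= ~bad
    else:
        bad_dist = (dist1 > 1.5 * library_fragment_length) | (dist2 > 1.5 * library_fragment_length)
        span = np.abs(pairs["pos2"].to_numpy() - pairs["pos1"].to_numpy())
        bad_span = same_chrom & (span < 1.5 * library_fragment_length)
        report["restriction_distance"] = int((bad_dist & keep).sum())
        keep &= ~bad_dist
        report["short_span"] = int((bad_span & keep).sum())
        keep &= ~bad_span
    out = pairs.loc[keep].copy()
    out["frag1"] = frag1[keep]
    out["frag2"] = frag2[keep]
    report["retained"] = len(out)
    return out.reset_index(drop=True), report


def bin_pairs_to_matrix(pairs: pd.DataFrame, bins: BinScheme, sample_id: str = "") -> ContactMatrix:
    """Accumulate each retained pair into one (bin1, bin2) cell."""
    for c in pd.unique(pairs["chrom1"]).tolist() + pd.unique(pairs["chrom2"]).tolist():
        if c not in bins.chrom_offsets:
            raise ValueError(f"chromosome {c!r} not in bin scheme")
    b1 = bins.bin_id(pairs["chrom1"], pairs["pos1"].to_numpy())
    b2 = bins.bin_id(pairs["chrom2"], pairs["pos2"].to_numpy())
    return ContactMatrix.from_coo(
        bins, b1, b2, np.ones(len(pairs)), sample_id=sample_id, normalization="raw"
    )


def counts_to_matrix(scheme: BinScheme, counts, sample_id: str = "") -> ContactMatrix:
    """Wrap a dense/sparse symmetric count array (upper triangle taken)."""
    if sp.issparse(counts):
        counts = counts.toarray()
    upper = np.triu(np.asarray(counts, dtype=np.float64))
    m = sp.csr_matrix(upper)
    return ContactMatrix(scheme, m, sample_id=sample_id, normalization="raw",
                         total_raw_pairs=float(upper.sum()))


def depth_normalize(matrix: ContactMatrix, target_total: float = 1e7) -> ContactMatrix:
    """Scale a raw matrix so its total contact count equals ``target_total``."""
    if matrix.normalization != "raw":
        raise ValueError("matrix already depth-scaled")
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    total = matrix.total
    if total == 0:
        raise ValueError("empty matrix")
    return ContactMatrix(
        matrix.bin_scheme,
        matrix.data * (target_total / total),
        sample_id=matrix.sample_id,
        normalization="depth_scaled",
        total_raw_pairs=matrix.total_raw_pairs or total,
        meta=dict(matrix.meta),
    )


def combine_group(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Element-wise mean of depth-scaled matrices (missing cells are 0)."""
    if not matrices:
        raise ValueError("no matrices")
    states = {m.normalization for m in matrices}
    if len(states) > 1:
        raise ValueError(f"mixed normalization states: {states}")
    schemes = {id(m.bin_scheme) for m in matrices}
    if len(schemes) > 1 and len({m.bin_scheme.n_bins for m in matrices}) > 1:
        raise ValueError("bin schemes differ")
    acc = matrices[0].data.copy()
    for m in matrices[1:]:
        acc = acc + m.data
    acc = acc / len(matrices)
    return ContactMatrix(
        matrices[0].bin_scheme, sp.csr_matrix(acc),
        sample_id=f"mean_of_{len(matrices)}",
        normalization=matrices[0].normalization,
        total_raw_pairs=float(np.mean([m.total_raw_pairs for m in matrices])),
    )


def fold_change_map(
    del_mean: ContactMatrix,
    ctrl_mean: ContactMatrix,
    mode: str = "relative_log2",
    pseudocount: float = 1.0,
) -> FoldChangeMap:
    """Bin-pair fold change between deletion and control group means.

    ``relative_log2`` is the literal (deletion - control)/control contrast of
    log2-transformed mean contacts; ``log2_ratio`` is log2((d+e)/(c+e)).
    Cells whose relative_log2 denominator log2(c+e) is not positive are NaN.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if del_mean.bin_scheme.n_bins != ctrl_mean.bin_scheme.n_bins:
        raise ValueError("bin schemes differ")
    d = del_mean.dense_symmetric() + pseudocount
    c = ctrl_mean.dense_symmetric() + pseudocount
    n_undef = 0
    if mode == "log2_ratio":
        fc = np.log2(d) - np.log2(c)
    elif mode == "relative_log2":
        ld, lc = np.log2(d), np.log2(c)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = (ld - lc) / lc
        bad = lc <= 0
        n_undef = int(bad.sum())
        fc[bad] = np.nan
    else:
        raise ValueError(f"unknown fold-change mode {mode!r}")
    return FoldChangeMap(del_mean.bin_scheme, fc, mode, pseudocount, n_undef)


def cis_window_fold_change_ranking(
    del_mean: ContactMatrix,
    ctrl_mean: ContactMatrix,
    chrom: str,
    anchor: tuple[int, int],
    partner_width: int = 1_000_000,
    model: GenomeModel | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank fixed-width cis windows by their contact fold change to an anchor.

    Contacts are summed over the anchor x partner rectangle of each group
    mean; the table reports d/c per partner window (pseudocount-protected),
    sorted descending, with deletion-overlapping partners flagged.
    """
    scheme = del_mean.bin_scheme
    length = scheme.chromosomes[chrom]
    a_start, a_end = anchor
    if a_end - a_start > length:
        raise ValueError("anchor wider than chromosome")
    res = scheme.resolution
    sl = scheme.chrom_slice(chrom)
    dmat = del_mean.dense_symmetric()[sl, sl]
    cmat = ctrl_mean.dense_symmetric()[sl, sl]
    ai, aj = a_start // res, -(-a_end // res)
    dels = model.deletions_on(chrom, "H1") + model.deletions_on(chrom, "H2") if model else []
    rows = []
    for w_start in range(0, length, partner_width):
        w_end = min(w_start + partner_width, length)
        if w_start < a_end and a_start < w_end:
            continue  # skip the anchor itself
        wi, wj = w_start // res, -(-w_end // res)
        d_sum = float(dmat[ai:aj, wi:wj].sum())
        c_sum = float(cmat[ai:aj, wi:wj].sum())
        fc = (d_sum + pseudocount) / (c_sum + pseudocount)
        overlaps = any(w_start < d.end and d.start < w_end for d in dels)
        rows.append((chrom, w_start, w_end, d_sum, c_sum, fc, overlaps))
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "del_sum", "ctrl_sum", "fold_change",
                 "overlaps_deletion"],
    ).sort_values("fold_change", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
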