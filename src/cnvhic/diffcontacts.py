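"""Differential trans-contact testing, strongest-contact enrichment and
label-permutation controls.

Each inter-chromosomal bin pair with at least one supporting raw read pair
in every sample is tested by a two-sided unequal-variance (Welch) t test on
the depth-scaled values, at a fixed p threshold with no multiple-testing
correction; significant pairs are then tested for enrichment among the top
5% strongest contacts by Fisher's exact test, and the whole analysis is
re-run under label swaps and within-group splits as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special as spsp
import scipy.stats as st

from .matrix import ContactMatrix


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Two-sided Welch t test: statistic, Welch-Satterthwaite df, p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance")
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * st.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fisher_exact_test(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (exact hypergeometric)."""
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(st.fisher_exact(tab, alternative="two-sided")[1])


@dataclass
class DifferentialContactResult:
    table: pd.DataFrame   # bin1_id, bin2_id, mean_del, mean_ctrl, t, df, p, strength
    n_tested: int
    n_significant: int
    p_threshold: float
    n_candidate: int = 0  # inter-chromosomal cells before the inclusion filter


def _stack_values(matrices: list[ContactMatrix]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union of nonzero upper-triangle cells across samples -> value stack."""
    keys = set()
    for m in matrices:
        coo = m.data.tocoo()
        keys.update(zip(coo.row.tolist(), coo.col.tolist()))
    b1 = np.fromiter((k[0] for k in sorted(keys)), dtype=np.int64)
    b2 = np.fromiter((k[1] for k in sorted(keys)), dtype=np.int64)
    vals = np.zeros((len(matrices), b1.size))
    for s, m in enumerate(matrices):
        vals[s] = np.asarray(m.data[b1, b2]).ravel()
    return b1, b2, vals


def differential_trans_contacts(
    matrices: list[ContactMatrix],
    raw_matrices: list[ContactMatrix],
    labels: list[str],
    p_threshold: float = 1e-4,
) -> DifferentialContactResult:
    """Welch-test every included inter-chromosomal bin pair.

    ``matrices`` are depth-scaled values (tested), ``raw_matrices`` the
    corresponding raw counts (inclusion filter: >= 1 raw pair in every
    sample).  ``labels`` assigns each sample to 'del' or 'ctrl'.
    """
    labels = np.asarray(labels)
    for g in ("del", "ctrl"):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    scheme = matrices[0].bin_scheme
    chrom = scheme.bin_chrom()
    b1, b2, raw = _stack_values(raw_matrices)
    trans = chrom[b1] != chrom[b2]
    b1, b2, raw = b1[trans], b2[trans], raw[:, trans]
    included = (raw >= 1).all(axis=0)
    b1, b2 = b1[included], b2[included]
    vals = np.zeros((len(matrices), b1.size))
    for s, m in enumerate(matrices):
        vals[s] = np.asarray(m.data[b1, b2]).ravel()

    gd = vals[labels == "del"]
    gc = vals[labels == "ctrl"]
    nd, nc = gd.shape[0], gc.shape[0]
    md, mc = gd.mean(axis=0), gc.mean(axis=0)
    vd, vc = gd.var(axis=0, ddof=1), gc.var(axis=0, ddof=1)
    se2 = vd / nd + vc / nc
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (md - mc) / np.sqrt(se2)
        df = se2 ** 2 / ((vd / nd) ** 2 / (nd - 1) + (vc / nc) ** 2 / (nc - 1))
        p = 2.0 * spsp.stdtr(df, -np.abs(t))
    degenerate = se2 == 0
    p[degenerate] = np.nan
    strength = vals.mean(axis=0)
    table = pd.DataFrame(
        {
            "bin1_id": b1, "bin2_id": b2,
            "mean_del": md, "mean_ctrl": mc,
            "t": t, "df": df, "p": p,
            "strength": strength,
            "excluded_zero_variance": degenerate,
        }
    )
    tested = ~degenerate
    nsig = int((p[tested] < p_threshold).sum())
    return DifferentialContactResult(
        table, int(tested.sum()), nsig, p_threshold, n_candidate=int(trans.sum())
    )


def strongest_contact_enrichment(
    result: DifferentialContactResult, quantile: float = 0.95
) -> tuple[np.ndarray, float]:
    """Fisher test of significant pairs among the top-(1-q) strongest.

    Strength is the mean depth-scaled value across all samples; the 2x2
    table crosses significance with top-strength membership.
    """
    tab = result.table[~result.table["excluded_zero_variance"]]
    if len(tab) < 20:
        raise ValueError("fewer than 20 included pairs")
    strength = tab["strength"].to_numpy()
    cut = np.quantile(strength, quantile)
    top = strength >= cut
    sig = tab["p"].to_numpy() < result.p_threshold
    table = np.array(
        [
            [int((sig & top).sum()), int((sig & ~top).sum())],
            [int((~sig & top).sum()), int((~sig & ~top).sum())],
        ]
    )
    return table, fisher_exact_test(table)


@dataclass
class LabelSwapResult:
    scheme: str
    replicates: pd.DataFrame  # replicate, n_significant, enrichment_p


def label_swap_analysis(
    matrices: list[ContactMatrix],
    raw_matrices: list[ContactMatrix],
    labels: list[str],
    scheme: str = "swap10",
    p_threshold: float = 1e-4,
    seed: int = 0,
    top_quantile: float = 0.95,
) -> LabelSwapResult:
    """Re-run the differential analysis under permuted or split labels.

    ``swap10`` permutes deletion/control status ten times; ``within_ctrl3``
    and ``within_del3`` randomly split one group into two pseudo-groups
    three times.  Reports significant-pair counts and enrichment p per
    replicate.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    reps = []
    if scheme == "swap10":
        n_rep = 10
        for r in range(n_rep):
            reps.append(rng.permutation(labels))
    elif scheme in ("within_ctrl3", "within_del3"):
        g = "ctrl" if scheme == "within_ctrl3" else "del"
        idx = np.where(labels == g)[0]
        if idx.size < 4:
            raise ValueError(f"group {g!r} too small to split")
        half = idx.size // 2
        for r in range(3):
            sh = rng.permutation(idx)
            lab = np.array(["drop"] * labels.size, dtype=object)
            lab[sh[:half]] = "del"
            lab[sh[half:]] = "ctrl"
            reps.append(lab)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rows = []
    for r, lab in enumerate(reps):
        keep = [i for i, v in enumerate(lab) if v in ("del", "ctrl")]
        res = differential_trans_contacts(
            [matrices[i] for i in keep],
            [raw_matrices[i] for i in keep],
            [lab[i] for i in keep],
            p_threshold,
        )
        try:
            _, ep = strongest_contact_enrichment(res, top_quantile)
        except ValueError:
            ep = np.nan
        rows.append((r, res.n_significant, ep))
    return LabelSwapResult(
        scheme, pd.DataFrame(rows, columns=["replicate", "n_significant", "enrichment_p"])
    )
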