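"""A/B compartments and directionality-index TAD calling.

Compartments follow the classic eigenvector recipe: distance-normalize the
cis matrix (observed/expected), correlate its columns, and take the sign of
the leading eigenvector, oriented so bins with higher gene density are A.
TADs are called from the directionality index (DI), a signed chi-square-like
contrast of upstream vs downstream contact sums, segmented by a penalized
three-state dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def observed_over_expected(
    cis: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """O/E-normalize a dense cis matrix.

    ``mask`` marks bins to exclude (deletion bins); all-zero rows are masked
    automatically.  expected(s) is the mean observed value at separation s
    over unmasked cells; masked rows/columns are NaN in the output.
    Returns (oe, final mask).
    """
    cis = np.asarray(cis, dtype=np.float64)
    n = cis.shape[0]
    mask = np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).copy()
    mask |= cis.sum(axis=1) == 0
    if mask.all():
        raise ValueError("all bins masked")
    valid = ~mask
    i, j = np.indices(cis.shape)
    sep = np.abs(i - j)
    cellok = valid[:, None] & valid[None, :]
    sepv = sep[cellok]
    sums = np.bincount(sepv, weights=cis[cellok], minlength=n)
    cnts = np.bincount(sepv, minlength=n)
    with np.errstate(invalid="ignore"):
        exp = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = cis / exp[sep]
    oe[~np.isfinite(oe)] = 0.0
    oe[mask, :] = np.nan
    oe[:, mask] = np.nan
    return oe, mask


@dataclass
class CompartmentTrack:
    eigenvector: np.ndarray      # e1 per bin, NaN for masked
    labels: np.ndarray           # 'A' / 'B' / 'NA'
    mask: np.ndarray


def compartment_pc1(
    oe: np.ndarray, orientation: np.ndarray, mask: np.ndarray | None = None
) -> CompartmentTrack:
    """Leading eigenvector of the O/E correlation matrix, A/B labelled.

    ``orientation`` is a per-bin track (e.g. gene density) used to fix the
    eigenvector's sign: positive values become the A compartment on the
    side correlating with high track values.
    """
    n = oe.shape[0]
    if mask is None:
        mask = np.all(np.isnan(oe), axis=1)
    valid = np.where(~mask)[0]
    if valid.size < 10:
        raise ValueError("need at least 10 unmasked bins")
    sub = oe[np.ix_(valid, valid)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    if not np.isfinite(corr).all():
        corr = np.nan_to_num(corr, nan=0.0)
    if np.allclose(corr, corr[0, 0]):
        raise ValueError("no compartment signal (degenerate correlation matrix)")
    w, v = np.linalg.eigh(corr)
    e1 = v[:, -1]
    track = np.asarray(orientation, dtype=np.float64)[valid]
    # orient so that high-track bins have positive e1
    sign = np.sign(np.corrcoef(e1, track)[0, 1]) or 1.0
    e1 = e1 * sign
    full = np.full(n, np.nan)
    full[valid] = e1
    labels = np.full(n, "NA", dtype=object)
    labels[valid] = np.where(e1 >= 0, "A", "B")
    return CompartmentTrack(full, labels, mask)


@dataclass
class DirectionalityTrack:
    di: np.ndarray
    upstream: np.ndarray      # A sums
    downstream: np.ndarray    # B sums
    truncated: np.ndarray     # chromosome-edge bins with short windows


def directionality_index(cis: np.ndarray, window_bins: int) -> DirectionalityTrack:
    """Dixon-style DI per bin.

    A = contacts to the upstream ``window_bins`` bins, B = downstream;
    E = (A+B)/2; DI = sign(B-A) * ((A-E)^2/E + (B-E)^2/E), 0 where A=B=0.
    Edge bins use truncated windows and are flagged.
    """
    if window_bins < 2:
        raise ValueError("window must span at least 2 bins")
    cis = np.asarray(cis, dtype=np.float64)
    n = cis.shape[0]
    a = np.zeros(n)
    b = np.zeros(n)
    for k in range(n):
        lo = max(0, k - window_bins)
        hi = min(n, k + window_bins + 1)
        a[k] = cis[k, lo:k].sum()
        b[k] = cis[k, k + 1:hi].sum()
    e = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = (a - e) ** 2 / e + (b - e) ** 2 / e
    di = np.sign(b - a) * chi
    di[(a == 0) & (b == 0)] = 0.0
    di[a == b] = 0.0
    truncated = np.zeros(n, dtype=bool)
    truncated[:window_bins] = True
    truncated[n - window_bins:] = True
    return DirectionalityTrack(di, a, b, truncated)


def _segment_states(di: np.ndarray, penalty: float) -> np.ndarray:
    """Penalized three-state (-1/0/+1) segmentation of the DI track.

    Maximizes sum of per-bin state scores minus ``penalty`` per state
    change; scores are the DI scaled by its mean absolute value, so the
    penalty is in units of typical DI magnitude.  Deterministic (ties favor
    the lower state index: -1, then 0, then +1).
    """
    n = di.size
    scale = np.mean(np.abs(di))
    if scale == 0:
        return np.zeros(n, dtype=int)
    # clip extreme DI so single very strong bins cannot absorb the penalty
    # budget of their neighbours; the margin makes zero-DI stretches prefer
    # the neutral state instead of riding along in a biased one for free
    d = np.clip(di / scale, -3.0, 3.0)
    margin = 0.2
    states = (-1, 0, 1)
    emit = np.stack([-d - margin, np.zeros(n), d - margin])
    score = emit[:, 0].copy()
    back = np.zeros((3, n), dtype=int)
    for t in range(1, n):
        for s in range(3):
            cand = score + np.where(np.arange(3) == s, 0.0, -penalty)
            best = int(np.argmax(cand))
            back[s, t] = best
            emit[s, t] += cand[best]
        score = emit[:, t].copy()
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[path[t], t]
    return np.array(states)[path]


def call_domains(
    di: DirectionalityTrack | np.ndarray,
    bin_size: int,
    min_size: int = 120_000,
    penalty: float = 1.0,
) -> pd.DataFrame:
    """Topological domains from the DI track.

    A domain opens at the start of a sustained downstream-biased (+) run and
    closes at the end of the following upstream-biased (-) run; domains
    shorter than ``min_size`` are discarded.  Returns (start, end) in bp.
    """
    d = di.di if isinstance(di, DirectionalityTrack) else np.asarray(di, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty DI track")
    states = _segment_states(d, penalty)
    domains = []
    open_start = None
    last_minus = None
    for k in range(d.size):
        s = states[k]
        if s == 1:
            if open_start is None:
                open_start = k
            elif last_minus is not None:
                domains.append((open_start, last_minus + 1))
                open_start = k
                last_minus = None
        elif s == -1 and open_start is not None:
            last_minus = k
    if open_start is not None and last_minus is not None:
        domains.append((open_start, last_minus + 1))
    rows = []
    for s_bin, e_bin in domains:
        start, end = s_bin * bin_size, e_bin * bin_size
        if end - start >= min_size:
            rows.append((start, end))
    return pd.DataFrame(rows, columns=["start", "end"])


def boundary_positions(domains: pd.DataFrame) -> np.ndarray:
    """Unique internal boundary positions implied by a domain set."""
    if domains.empty:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate([domains["start"].to_numpy(),
                                     domains["end"].to_numpy()]))
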