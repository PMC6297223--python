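"""Synthetic diploid cohort generator.

Emulates the study design every downstream stage assumes: a cohort of
deletion (one haplotype carrying a multi-megabase heterozygous deletion) and
control lymphoblastoid-like cell lines, with

* intra-chromosomal Hi-C contacts following power-law distance decay
  modulated by checkerboard A/B compartments and block TADs,
* constant-rate trans contacts with optional injected hotspots,
* Poisson counts materialized as read pairs anchored near restriction sites,
* phased heterozygous SNVs and allele-tagged reads,
* ChIP signal tables with reciprocal H3K27ac-down / H3K27me3-up shifts in
  deletion-flanking regions,
* FPKM tables with expression halved inside the deletion, and
* 3D-FISH distance tables with subject-level random effects.

The deleted homolog's geometry is driven by haplotype-frame coordinates
(the deleted sequence is excised before distances are computed), so the
increase of contacts between deletion-flanking regions is an emergent
prediction of the distance-decay model, not an injected effect.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome import Deletion, GenomeModel, build_genome_model

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class Hotspot:
    """Multiplicative contact-rate change injected in deletion samples."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    multiplier: float


@dataclass
class CohortConfig:
    """Generator parameters.  Defaults emulate a 22q-like experiment:

    a 50-Mbp chromosome carrying a 3-Mbp heterozygous deletion at
    18.5-21.5 Mbp in 5 patient lines versus 6 controls, plus two 20-Mbp
    decoy chromosomes for trans-contact statistics.
    """

    n_del: int = 5
    n_ctrl: int = 6
    seed: int = 0
    # genome
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr22s": 50_000_000, "chrD1": 20_000_000, "chrD2": 20_000_000}
    )
    main_chrom: str = "chr22s"
    deletion: tuple[str, int, int] = ("chr22s", 18_500_000, 21_500_000)
    cut_spacing: int = 5000
    # contacts
    decay_exponent: float = 1.0        # alpha; power-law slope of cis decay
    cis_scale: float = 20.0            # expected counts at 1 sim-bin separation
    decoy_cis_scale: float = 40.0
    sim_resolution: int = 50_000       # main-chromosome simulation bin
    decoy_resolution: int = 250_000
    trans_rate: float = 5.0            # expected counts per trans cell (both haplotypes)
    trans_resolution: int = 500_000
    compartment_strength: float = 2.0  # kappa >= 1
    tad_strength: float = 3.0          # tau >= 1
    compartment_block: int = 2_500_000
    tad_sizes: tuple[int, ...] = (800_000, 1_200_000, 1_000_000)
    hotspots: tuple[Hotspot, ...] = (
        Hotspot("chr22s", 21_500_000, 22_000_000, "chr22s", 49_000_000, 50_000_000, 1.8),
        Hotspot("chrD1", 5_000_000, 5_500_000, "chrD2", 10_000_000, 10_500_000, 3.0),
    )
    # reads
    read_length: int = 101
    library_fragment_length: float = 500.0
    restriction_offset_max: int = 300
    snv_density: float = 6e-4
    # ChIP
    n_peaks_per_mark: int = 600
    chip_log2_mu: float = 5.0
    chip_log2_mu_sd: float = 1.0
    chip_sigma: float = 0.25           # per-sample log2 noise sd
    flank_delta: float = 1.0           # reciprocal flank shift (log2)
    n_flank_pairs: int = 20
    chip_de_shift: float = 0.8         # histone shift coupled to DE direction
    # expression
    n_genes: int = 400
    n_de_genes: int = 30
    de_log2fc: float = 1.0
    n_low_expr: int = 20
    expr_sigma: float = 0.25
    coupling: float = 0.5              # latent corr between FPKM and TSS H3K27ac
    # FISH
    fish_cells: tuple[int, int] = (16, 33)
    fish_mean: float = 1.0
    fish_effect: float = -0.2
    fish_gender_effect: float = 0.05
    fish_sigma_subject: float = 0.08
    fish_sigma_resid: float = 0.25

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.cis_scale < 0 or self.trans_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.compartment_strength < 1 or self.tad_strength < 1:
            raise ValueError("compartment/tad strengths must be >= 1")
        self.hotspots = tuple(
            h if isinstance(h, Hotspot) else Hotspot(*h) for h in self.hotspots
        )

    # -- derived -----------------------------------------------------------

    def genome_model(self) -> GenomeModel:
        chrom, start, end = self.deletion
        return build_genome_model(
            self.chromosomes, [(chrom, start, end, "H1")], cut_spacing=self.cut_spacing
        )

    def sample_ids(self) -> list[tuple[str, str]]:
        out = [(f"del{i + 1}", "del") for i in range(self.n_del)]
        out += [(f"ctrl{i + 1}", "ctrl") for i in range(self.n_ctrl)]
        return out

    def chrom_sim_resolution(self, chrom: str) -> int:
        return self.sim_resolution if chrom == self.main_chrom else self.decoy_resolution

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hotspots"] = [list(asdict(h).values()) for h in self.hotspots]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "deletion" in d:
            d["deletion"] = tuple(d["deletion"])
        for k in ("tad_sizes", "fish_cells"):
            if k in d:
                d[k] = tuple(d[k])
        if "hotspots" in d:
            d["hotspots"] = tuple(Hotspot(*h) for h in d["hotspots"])
        return cls(**d)


def small_config(seed: int = 0) -> CohortConfig:
    """A scaled-down cohort for smoke tests and the CLI pipeline demo."""
    return CohortConfig(
        seed=seed,
        chromosomes={"chr22s": 20_000_000, "chrD1": 8_000_000, "chrD2": 8_000_000},
        deletion=("chr22s", 8_000_000, 11_000_000),
        cis_scale=8.0,
        decoy_cis_scale=16.0,
        trans_rate=5.0,
        compartment_block=2_000_000,
        hotspots=(
            Hotspot("chr22s", 11_000_000, 11_500_000, "chr22s", 19_000_000, 20_000_000, 1.8),
            Hotspot("chrD1", 2_000_000, 2_500_000, "chrD2", 4_000_000, 4_500_000, 3.0),
        ),
        n_peaks_per_mark=300,
        n_genes=250,
        n_de_genes=24,
    )


def capture_config(seed: int = 0) -> CohortConfig:
    """Deep single-chromosome settings emulating a capture Hi-C library
    targeted at the deletion chromosome (used for haplotype-resolved maps)."""
    return CohortConfig(
        seed=seed,
        n_del=1,
        n_ctrl=1,
        chromosomes={"chr22s": 50_000_000},
        cis_scale=40.0,
        snv_density=1e-3,
        trans_rate=0.0,
        hotspots=(),
    )


def trans_config(seed: int = 0) -> CohortConfig:
    """Deep trans-contact settings for differential-contact statistics.

    Per-cell trans counts around 120 put the strongest trans contacts in
    the regime where a fixed p < 1e-4 Welch test on 5-vs-6 samples has
    power; rewired blocks (x3 in deletion samples) span several 500-kbp
    cells, as a coordinated contact change would.
    """
    return CohortConfig(
        seed=seed,
        trans_rate=120.0,
        hotspots=(
            Hotspot("chrD1", 4_000_000, 6_000_000, "chrD2", 9_000_000, 11_000_000, 3.0),
            Hotspot("chr22s", 30_000_000, 32_000_000, "chrD1", 12_000_000, 14_000_000, 3.0),
        ),
    )


@dataclass
class TruthSet:
    """Generative ground truth for parameter-recovery tests."""

    compartment_labels: dict[str, np.ndarray]  # per chrom, +1 (A) / -1 (B) per sim bin
    tad_boundaries: dict[str, np.ndarray]      # bp positions of internal boundaries
    deletion: tuple[str, int, int]
    hotspots: tuple[Hotspot, ...]
    chip_truth: pd.DataFrame | None = None     # per site true log2FC
    expr_truth: pd.DataFrame | None = None     # per gene true fold change, DE status
    fish_effect: float = 0.0
    orientation_track: pd.DataFrame | None = None  # gene-density proxy per bin


# -- structural tracks -----------------------------------------------------

def compartment_labels(length: int, resolution: int, block: int) -> np.ndarray:
    """Alternating A/B labels (+1/-1) in fixed-size blocks, A first."""
    n = -(-length // resolution)
    centers = np.minimum((np.arange(n) + 0.5) * resolution, length - 1)
    return np.where((centers // block) % 2 == 0, 1, -1).astype(np.int8)


def tad_partition(length: int, sizes: tuple[int, ...]) -> np.ndarray:
    """Internal TAD boundary positions from a repeating size pattern."""
    bounds = []
    pos = 0
    i = 0
    while True:
        pos += sizes[i % len(sizes)]
        if pos >= length:
            break
        bounds.append(pos)
        i += 1
    return np.asarray(bounds, dtype=np.int64)


def _domain_index(length: int, resolution: int, boundaries: np.ndarray) -> np.ndarray:
    n = -(-length // resolution)
    centers = np.minimum((np.arange(n) + 0.5) * resolution, length - 1)
    return np.searchsorted(boundaries, centers, side="right")


# -- contact rates ---------------------------------------------------------

def cis_lambda(
    config: CohortConfig,
    chrom: str,
    deleted: bool = False,
    resolution: int | None = None,
    structured: bool | None = None,
) -> np.ndarray:
    """Expected cis contact counts per bin pair for one haplotype.

    lambda_ij = scale * s^-alpha * comp(i,j) * tad(i,j) with s the
    haplotype-frame separation in bins (clamped at 1); bins inside the
    deletion on a deleted haplotype have rate 0.  Compartment and TAD
    identity stay on the reference frame: the deleted homolog keeps the
    intact homolog's domain structure, only its distances change.
    """
    length = config.chromosomes[chrom]
    res = resolution or config.chrom_sim_resolution(chrom)
    if structured is None:
        structured = chrom == config.main_chrom
    scale = config.cis_scale if chrom == config.main_chrom else config.decoy_cis_scale
    n = -(-length // res)
    centers = np.minimum((np.arange(n) + 0.5) * res, length - 1).astype(np.int64)
    dchrom, dstart, dend = config.deletion
    inside = np.zeros(n, dtype=bool)
    mapped = centers.astype(np.float64)
    if deleted:
        if chrom != dchrom:
            raise ValueError(f"no deletion on chromosome {chrom!r}")
        inside = (centers >= dstart) & (centers < dend)
        mapped = np.where(centers >= dend, centers - (dend - dstart), centers).astype(np.float64)
    s = np.abs(mapped[:, None] - mapped[None, :]) / res
    np.maximum(s, 1.0, out=s)
    lam = scale * s ** (-config.decay_exponent)
    if structured:
        labels = compartment_labels(length, res, config.compartment_block)
        same = labels[:, None] == labels[None, :]
        k = config.compartment_strength
        lam *= np.where(same, k, 1.0 / k)
        dom = _domain_index(length, res, tad_partition(length, config.tad_sizes))
        lam *= np.where(dom[:, None] == dom[None, :], config.tad_strength, 1.0)
    if deleted:
        lam[inside, :] = 0.0
        lam[:, inside] = 0.0
    return lam


def _apply_cis_hotspots(lam: np.ndarray, config: CohortConfig, chrom: str, res: int) -> None:
    n = lam.shape[0]
    centers = np.minimum((np.arange(n) + 0.5) * res, config.chromosomes[chrom] - 1)
    for h in config.hotspots:
        if h.chrom1 != chrom or h.chrom2 != chrom:
            continue
        m1 = (centers >= h.start1) & (centers < h.end1)
        m2 = (centers >= h.start2) & (centers < h.end2)
        lam[np.ix_(m1, m2)] *= h.multiplier
        lam[np.ix_(m2, m1)] *= h.multiplier


def sample_cis_lambda(
    config: CohortConfig, chrom: str, group: str, haplotype: str, resolution: int | None = None
) -> np.ndarray:
    """Per-sample, per-haplotype cis rate matrix (hotspots included)."""
    if group not in ("del", "ctrl"):
        raise ValueError(f"unknown group {group!r}")
    deleted = group == "del" and haplotype == "H1" and chrom == config.deletion[0]
    lam = cis_lambda(config, chrom, deleted=deleted, resolution=resolution)
    if group == "del":
        _apply_cis_hotspots(lam, config, chrom, resolution or config.chrom_sim_resolution(chrom))
    return lam


def trans_lambda(
    config: CohortConfig, chrom1: str, chrom2: str, group: str, haplotype: str
) -> np.ndarray:
    """Constant-rate trans contacts per 500-kbp cell for one haplotype,
    zeroed for deletion bins on the deleted haplotype, hotspot-multiplied
    in deletion samples."""
    res = config.trans_resolution
    n1 = -(-config.chromosomes[chrom1] // res)
    n2 = -(-config.chromosomes[chrom2] // res)
    lam = np.full((n1, n2), config.trans_rate / 2.0)
    dchrom, dstart, dend = config.deletion
    if group == "del" and haplotype == "H1":
        for ax, chrom, nn in ((0, chrom1, n1), (1, chrom2, n2)):
            if chrom != dchrom:
                continue
            centers = np.minimum((np.arange(nn) + 0.5) * res, config.chromosomes[chrom] - 1)
            inside = (centers >= dstart) & (centers < dend)
            if ax == 0:
                lam[inside, :] = 0.0
            else:
                lam[:, inside] = 0.0
    if group == "del":
        for h in config.hotspots:
            for c1, s1, e1, c2, s2, e2 in (
                (h.chrom1, h.start1, h.end1, h.chrom2, h.start2, h.end2),
                (h.chrom2, h.start2, h.end2, h.chrom1, h.start1, h.end1),
            ):
                if c1 != chrom1 or c2 != chrom2:
                    continue
                centers1 = np.minimum((np.arange(n1) + 0.5) * res, config.chromosomes[chrom1] - 1)
                centers2 = np.minimum((np.arange(n2) + 0.5) * res, config.chromosomes[chrom2] - 1)
                m1 = (centers1 >= s1) & (centers1 < e1)
                m2 = (centers2 >= s2) & (centers2 < e2)
                lam[np.ix_(m1, m2)] *= h.multiplier
    return lam


# -- read materialization --------------------------------------------------

def _positions_in_bins(
    rng: np.random.Generator, bin_idx: np.ndarray, bin_start0: int, res: int,
    config: CohortConfig, chrom: str,
) -> np.ndarray:
    """Draw read positions inside the given bins, anchored just downstream
    of a restriction cut so realistic restriction-distance filters retain
    most reads."""
    spacing = config.cut_spacing
    per_bin = res // spacing
    cut = bin_idx * res + rng.integers(0, per_bin, size=bin_idx.size) * spacing
    offset = rng.integers(0, config.restriction_offset_max, size=bin_idx.size)
    pos = cut + offset
    return np.minimum(pos, config.chromosomes[chrom] - config.read_length - 1)


def _counts_to_pairs(
    rng: np.random.Generator,
    counts: np.ndarray,
    chrom1: str,
    chrom2: str,
    res1: int,
    res2: int,
    config: CohortConfig,
    haplotype: str,
    cis: bool,
) -> pd.DataFrame:
    if cis:
        iu, ju = np.triu_indices_from(counts)
        c = counts[iu, ju].astype(np.int64)
    else:
        iu, ju = np.indices(counts.shape)
        iu, ju, c = iu.ravel(), ju.ravel(), counts.ravel().astype(np.int64)
    nz = c > 0
    iu, ju, c = iu[nz], ju[nz], c[nz]
    i = np.repeat(iu, c)
    j = np.repeat(ju, c)
    pos1 = _positions_in_bins(rng, i, 0, res1, config, chrom1)
    pos2 = _positions_in_bins(rng, j, 0, res2, config, chrom2)
    strands = np.array(["+", "-"])
    return pd.DataFrame(
        {
            "chrom1": chrom1,
            "pos1": pos1,
            "strand1": strands[rng.integers(0, 2, pos1.size)],
            "chrom2": chrom2,
            "pos2": pos2,
            "strand2": strands[rng.integers(0, 2, pos2.size)],
            "true_hap": haplotype,
        }
    )


def simulate_sample_pairs(
    config: CohortConfig, sample_id: str, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    """All read pairs of one sample: Poisson cis counts per haplotype at the
    simulation resolution plus trans counts, materialized at restriction-
    anchored positions."""
    frames = []
    chroms = list(config.chromosomes)
    for chrom in chroms:
        res = config.chrom_sim_resolution(chrom)
        for hap in ("H1", "H2"):
            lam = sample_cis_lambda(config, chrom, group, hap)
            counts = rng.poisson(np.triu(lam))
            frames.append(
                _counts_to_pairs(rng, counts, chrom, chrom, res, res, config, hap, cis=True)
            )
    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            for hap in ("H1", "H2"):
                lam = trans_lambda(config, chroms[a], chroms[b], group, hap)
                counts = rng.poisson(lam)
                frames.append(
                    _counts_to_pairs(
                        rng, counts, chroms[a], chroms[b],
                        config.trans_resolution, config.trans_resolution,
                        config, hap, cis=False,
                    )
                )
    pairs = pd.concat(frames, ignore_index=True)
    # canonical mate order (genome order is fixed by the config)
    rank = {c: i for i, c in enumerate(chroms)}
    k1 = pairs["chrom1"].map(rank).to_numpy()
    k2 = pairs["chrom2"].map(rank).to_numpy()
    p1, p2 = pairs["pos1"].to_numpy(), pairs["pos2"].to_numpy()
    swap = (k1 > k2) | ((k1 == k2) & (p1 > p2))
    for a_, b_ in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        va, vb = pairs[a_].to_numpy().copy(), pairs[b_].to_numpy().copy()
        pairs.loc[swap, a_] = vb[swap]
        pairs.loc[swap, b_] = va[swap]
    pairs.insert(0, "read_id", np.arange(len(pairs), dtype=np.int64))
    return pairs


def simulate_trans_count_matrices(
    config: CohortConfig, seed: int, labels: list[str] | None = None
):
    """Genome-wide raw count matrices per sample at the trans resolution.

    A fast, count-level route (no read materialization) for trans-contact
    statistics: cis cells are left empty, trans cells are Poisson draws from
    the per-group trans rates.  Returns (matrices, labels).
    """
    from .genome import make_bins
    from .matrix import ContactMatrix

    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    model = config.genome_model()
    bins = make_bins(model, config.trans_resolution)
    if labels is None:
        labels = [g for _, g in config.sample_ids()]
    chroms = list(config.chromosomes)
    mats = []
    for s_i, grp in enumerate(labels):
        n = bins.n_bins
        full = np.zeros((n, n))
        for a in range(len(chroms)):
            for b in range(a + 1, len(chroms)):
                lam = sum(
                    trans_lambda(config, chroms[a], chroms[b], grp, hap)
                    for hap in ("H1", "H2")
                )
                counts = rng.poisson(lam)
                sa, sb = bins.chrom_slice(chroms[a]), bins.chrom_slice(chroms[b])
                full[sa, sb] = counts
        mats.append(ContactMatrix.from_coo(
            bins, *np.nonzero(full), full[np.nonzero(full)],
            sample_id=f"s{s_i}", normalization="raw",
        ))
    return mats, list(labels)


# -- phased SNVs and allele tags -------------------------------------------

def simulate_phased_snvs(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Phased heterozygous SNVs at uniform density on the reference frame.

    SNVs inside the deletion are kept in the table (phasable through
    inheritance); reads from the deleted haplotype simply never cover them
    because that DNA emits no reads.
    """
    if config.snv_density <= 0:
        raise ValueError("snv_density must be > 0")
    recs = []
    for chrom, length in config.chromosomes.items():
        n = rng.poisson(config.snv_density * length)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False))
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        alt_on_h1 = rng.integers(0, 2, size=pos.size).astype(bool)
        ref, alt = BASES[ref_idx], BASES[alt_idx]
        recs.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref_allele": ref,
                    "alt_allele": alt,
                    "hap1_allele": np.where(alt_on_h1, alt, ref),
                    "hap2_allele": np.where(alt_on_h1, ref, alt),
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def tag_reads_with_alleles(
    pairs: pd.DataFrame, variants: pd.DataFrame, read_length: int
) -> pd.DataFrame:
    """Per read end, the (pos, allele) tags of the SNVs the read covers.

    The observed allele is the read's true haplotype's allele (error-free
    sequencing); returns columns read_id, end, snv_chrom, snv_pos, allele.
    """
    out = []
    for end in (1, 2):
        chrom_col, pos_col = f"chrom{end}", f"pos{end}"
        for chrom, var in variants.groupby("chrom", sort=False):
            vpos = var["pos"].to_numpy()
            sel = pairs[chrom_col] == chrom
            if not sel.any():
                continue
            rpos = pairs.loc[sel, pos_col].to_numpy()
            rid = pairs.loc[sel, "read_id"].to_numpy()
            hap = pairs.loc[sel, "true_hap"].to_numpy()
            lo = np.searchsorted(vpos, rpos, side="left")
            hi = np.searchsorted(vpos, rpos + read_length, side="left")
            counts = hi - lo
            has = counts > 0
            if not has.any():
                continue
            reps = counts[has]
            cum = np.cumsum(reps)
            flat = np.arange(cum[-1])
            within = flat - np.repeat(cum - reps, reps)
            vidx = np.repeat(lo[has], reps) + within
            h = np.repeat(hap[has], reps)
            allele = np.where(
                h == "H1",
                var["hap1_allele"].to_numpy()[vidx],
                var["hap2_allele"].to_numpy()[vidx],
            )
            out.append(
                pd.DataFrame(
                    {
                        "read_id": np.repeat(rid[has], reps),
                        "end": end,
                        "snv_chrom": chrom,
                        "snv_pos": vpos[vidx],
                        "allele": allele,
                    }
                )
            )
    if not out:
        return pd.DataFrame(columns=["read_id", "end", "snv_chrom", "snv_pos", "allele"])
    return pd.concat(out, ignore_index=True)


# -- ChIP / expression / FISH / ASE ----------------------------------------

def _orientation_bias(config: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """TSS positions on the main chromosome, 3:1 biased toward A bins."""
    length = config.chromosomes[config.main_chrom]
    res = config.sim_resolution
    labels = compartment_labels(length, res, config.compartment_block)
    w = np.where(labels == 1, 3.0, 1.0)
    w /= w.sum()
    bins = rng.choice(labels.size, size=n, p=w)
    return np.minimum(bins * res + rng.integers(0, res, size=n), length - 1)


def simulate_expression_table(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Per-gene, per-sample FPKM table plus per-gene truth.

    Genes inside the deletion are halved in deletion samples; a configured
    set of genome-wide DE genes carries +-de_log2fc effects; a set of
    low-expression genes (mean FPKM 0.1) exercises the FPKM filter.
    Returns (table, latent) where latent holds the per-gene-per-sample
    factor shared with the TSS ChIP signal.
    """
    samples = config.sample_ids()
    n = config.n_genes
    n_main = int(round(n * 0.6))
    tss_main = _orientation_bias(config, rng, n_main)
    chroms = [config.main_chrom] * n_main
    decoys = [c for c in config.chromosomes if c != config.main_chrom]
    n_rest = n - n_main
    for k in range(n_rest):
        chroms.append(decoys[k % len(decoys)] if decoys else config.main_chrom)
    tss_rest = np.array(
        [rng.integers(0, config.chromosomes[c]) for c in chroms[n_main:]], dtype=np.int64
    )
    tss = np.concatenate([tss_main, tss_rest]) if n_rest else tss_main
    strand = np.where(rng.integers(0, 2, n) == 0, "+", "-")
    base_log2 = rng.normal(3.0, 1.5, size=n)
    low = rng.choice(n, size=config.n_low_expr, replace=False)
    base_log2[low] = np.log2(0.1)

    dchrom, dstart, dend = config.deletion
    in_del = (np.asarray(chroms) == dchrom) & (tss >= dstart) & (tss < dend)
    eligible = np.where(~in_del & ~np.isin(np.arange(n), low))[0]
    de_idx = rng.choice(eligible, size=config.n_de_genes, replace=False)
    de_dir = np.zeros(n)
    de_dir[de_idx] = np.where(rng.integers(0, 2, de_idx.size) == 0, 1.0, -1.0)

    z = rng.standard_normal((n, len(samples)))  # latent coupling factor
    e = rng.standard_normal((n, len(samples)))
    rho = math.sqrt(config.coupling)
    noise = config.expr_sigma * (rho * z + math.sqrt(1 - config.coupling) * e)
    log2fpkm = base_log2[:, None] + noise
    for s_i, (sid, grp) in enumerate(samples):
        if grp == "del":
            log2fpkm[in_del, s_i] -= 1.0
            log2fpkm[:, s_i] += de_dir * config.de_log2fc
    gene_ids = [f"g{i:04d}" for i in range(n)]
    table = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chroms, "tss": tss, "strand": strand}
    )
    for s_i, (sid, _) in enumerate(samples):
        table[sid] = np.round(2.0 ** log2fpkm[:, s_i], 6)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "in_deletion": in_del,
            "de_direction": de_dir,
            "true_fold_change": 2.0 ** (de_dir * config.de_log2fc) * np.where(in_del, 0.5, 1.0),
            "low_expression": np.isin(np.arange(n), low),
        }
    )
    return table, truth, z


def simulate_chip_tables(
    config: CohortConfig,
    rng: np.random.Generator,
    expression: pd.DataFrame | None = None,
    expr_truth: pd.DataFrame | None = None,
    latent: np.ndarray | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Normalized-count tables for H3K27ac, H3K27me3 and CTCF.

    Peaks inside the deletion lose one log2 unit in deletion samples
    (heterozygous halving); configured deletion-flanking peak pairs shift
    reciprocally (-delta for H3K27ac, +delta for H3K27me3); TSS-proximal
    histone peaks share a latent per-sample factor with expression so the
    expression-chromatin coupling statistics have signal to find.
    """
    if config.chip_sigma <= 0:
        raise ValueError("chip_sigma must be > 0")
    samples = config.sample_ids()
    dchrom, dstart, dend = config.deletion
    length_main = config.chromosomes[config.main_chrom]
    flank_windows = [(max(0, dstart - 1_500_000), dstart), (dend, min(length_main, dend + 2_000_000))]
    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    rho = math.sqrt(config.coupling)

    for mark in ("H3K27ac", "H3K27me3", "CTCF"):
        width = 2000 if mark == "H3K27me3" else 500
        site_chrom: list[str] = []
        site_mid: list[int] = []
        gene_of_site: list[int] = []
        if expression is not None and mark in ("H3K27ac", "H3K27me3"):
            p_site = 0.85 if mark == "H3K27ac" else 0.6
            span = 800 if mark == "H3K27ac" else 4000
            for g_i, row in enumerate(expression.itertuples(index=False)):
                if rng.random() < p_site:
                    mid = int(row.tss + rng.integers(-span, span + 1))
                    mid = max(width, min(mid, config.chromosomes[row.chrom] - width))
                    site_chrom.append(row.chrom)
                    site_mid.append(mid)
                    gene_of_site.append(g_i)
        n_bg = max(0, config.n_peaks_per_mark - len(site_mid))
        lengths = np.array(list(config.chromosomes.values()), dtype=np.float64)
        probs = lengths / lengths.sum()
        bg_chrom_idx = rng.choice(len(lengths), size=n_bg, p=probs)
        names = list(config.chromosomes)
        for ci in bg_chrom_idx:
            site_chrom.append(names[ci])
            site_mid.append(int(rng.integers(width, config.chromosomes[names[ci]] - width)))
            gene_of_site.append(-1)
        mid = np.asarray(site_mid)
        chrom_arr = np.asarray(site_chrom)
        gene_arr = np.asarray(gene_of_site)
        n_sites = mid.size
        mu = rng.normal(config.chip_log2_mu, config.chip_log2_mu_sd, size=n_sites)
        in_del = (chrom_arr == dchrom) & (mid >= dstart) & (mid < dend)

        # reciprocal flank shifts: pick flank sites once per mark (seeded)
        flank_mask = np.zeros(n_sites, dtype=bool)
        for ws, we in flank_windows:
            flank_mask |= (chrom_arr == config.main_chrom) & (mid >= ws) & (mid < we)
        flank_idx = np.where(flank_mask & ~in_del)[0]
        if flank_idx.size > config.n_flank_pairs:
            flank_idx = rng.choice(flank_idx, size=config.n_flank_pairs, replace=False)
        flank_effect = np.zeros(n_sites)
        if mark == "H3K27ac":
            flank_effect[flank_idx] = -config.flank_delta
        elif mark == "H3K27me3":
            flank_effect[flank_idx] = config.flank_delta

        de_effect = np.zeros(n_sites)
        if expr_truth is not None and mark in ("H3K27ac", "H3K27me3"):
            linked = gene_arr >= 0
            dirs = np.zeros(n_sites)
            dirs[linked] = expr_truth["de_direction"].to_numpy()[gene_arr[linked]]
            sign = 1.0 if mark == "H3K27ac" else -1.0
            de_effect = sign * dirs * config.chip_de_shift

        log2c = np.tile(mu[:, None], (1, len(samples))).astype(np.float64)
        eps = rng.standard_normal((n_sites, len(samples)))
        if latent is not None and mark in ("H3K27ac", "H3K27me3"):
            sign = 1.0 if mark == "H3K27ac" else -1.0
            zsite = np.zeros((n_sites, len(samples)))
            linked = gene_arr >= 0
            zsite[linked] = sign * latent[gene_arr[linked]]
            log2c += config.chip_sigma * (rho * zsite + math.sqrt(1 - config.coupling) * eps)
        else:
            log2c += config.chip_sigma * eps
        for s_i, (sid, grp) in enumerate(samples):
            if grp == "del":
                log2c[in_del, s_i] -= 1.0
                log2c[:, s_i] += flank_effect + de_effect

        site_ids = [f"{mark}_{i:04d}" for i in range(n_sites)]
        tab = pd.DataFrame(
            {
                "site_id": site_ids,
                "chrom": chrom_arr,
                "start": mid - width // 2,
                "end": mid + width // 2,
                "mark": mark,
            }
        )
        for s_i, (sid, _) in enumerate(samples):
            tab[sid] = np.round(2.0 ** log2c[:, s_i], 6)
        tables[mark] = tab
        truth_rows.append(
            pd.DataFrame(
                {
                    "site_id": site_ids,
                    "mark": mark,
                    "gene_idx": gene_arr,
                    "true_log2fc": -1.0 * in_del + flank_effect + de_effect,
                    "in_deletion": in_del,
                    "is_flank": np.isin(np.arange(n_sites), flank_idx),
                }
            )
        )
    return tables, pd.concat(truth_rows, ignore_index=True)


def simulate_fish_measurements(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell FISH probe distances with subject random intercepts.

    normalized truth = mean + deletion effect + gender effect + subject
    intercept + residual; the emitted raw distance is the truth multiplied
    back by r_short * r_long so the analysis side must normalize.
    """
    rows = []
    lo, hi = config.fish_cells
    for sid, grp in config.sample_ids():
        gender = "F" if rng.integers(0, 2) == 0 else "M"
        subj_eff = rng.normal(0.0, config.fish_sigma_subject)
        n_cells = int(rng.integers(lo, hi + 1))
        for c in range(n_cells):
            mu = (
                config.fish_mean
                + (config.fish_effect if grp == "del" else 0.0)
                + (config.fish_gender_effect if gender == "M" else 0.0)
                + subj_eff
            )
            norm = max(mu + rng.normal(0.0, config.fish_sigma_resid), 0.01)
            r_short = rng.uniform(4.0, 5.0)
            r_long = r_short + rng.uniform(0.2, 1.0)
            rows.append(
                (sid, grp, gender, f"{sid}_c{c}", norm * r_short * r_long, r_short, r_long)
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "gender", "cell_id", "distance", "r_short", "r_long"],
    )


def simulate_ase_counts(
    config: CohortConfig,
    rng: np.random.Generator,
    expression: pd.DataFrame,
    expr_truth: pd.DataFrame,
    snvs_per_gene: int = 2,
    mean_coverage: float = 30.0,
) -> pd.DataFrame:
    """RNA-seq allele counts at heterozygous coding SNVs.

    Genes outside the deletion are biallelic (alt fraction ~ background);
    deletion genes in deletion samples are monoallelic for the intact
    haplotype's allele.
    """
    rows = []
    in_del = expr_truth["in_deletion"].to_numpy()
    for g_i, row in enumerate(expression.itertuples(index=False)):
        for k in range(snvs_per_gene):
            pos = int(row.tss + 200 + 150 * k)
            alt_on_intact = bool(rng.integers(0, 2))
            for sid, grp in config.sample_ids():
                cov = int(rng.poisson(mean_coverage))
                if cov == 0:
                    continue
                if in_del[g_i] and grp == "del":
                    alt = cov if alt_on_intact else 0
                else:
                    alt = int(rng.binomial(cov, 0.5))
                rows.append((sid, row.chrom, pos, f"{row.gene_id}", cov - alt, alt,
                             bool(in_del[g_i])))
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "gene_id", "ref_count", "alt_count", "in_deletion"],
    )


# -- cohort driver ---------------------------------------------------------

@dataclass
class CohortData:
    config: CohortConfig
    genome: GenomeModel
    samples: list[tuple[str, str]]
    pairs: dict[str, pd.DataFrame]
    tags: dict[str, pd.DataFrame]
    variants: dict[str, pd.DataFrame]
    chip: dict[str, pd.DataFrame]
    chip_truth: pd.DataFrame
    expression: pd.DataFrame
    expr_truth: pd.DataFrame
    fish: pd.DataFrame
    ase: pd.DataFrame
    truth: TruthSet


def simulate_cohort(config: CohortConfig, with_tags: bool = True) -> CohortData:
    """Generate the full cohort.  Byte-identical for a fixed config seed."""
    root = np.random.SeedSequence(config.seed)
    keys = ["pairs", "snv", "chip", "expr", "fish", "ase"]
    streams = {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}
    genome = config.genome_model()
    samples = config.sample_ids()

    pairs: dict[str, pd.DataFrame] = {}
    tags: dict[str, pd.DataFrame] = {}
    variants: dict[str, pd.DataFrame] = {}
    pair_seeds = np.random.SeedSequence((config.seed, 1)).spawn(len(samples))
    snv_seeds = np.random.SeedSequence((config.seed, 2)).spawn(len(samples))
    for (sid, grp), ps, vs in zip(samples, pair_seeds, snv_seeds):
        prng = np.random.default_rng(ps)
        vrng = np.random.default_rng(vs)
        pairs[sid] = simulate_sample_pairs(config, sid, grp, prng)
        variants[sid] = simulate_phased_snvs(config, vrng)
        if with_tags:
            tags[sid] = tag_reads_with_alleles(pairs[sid], variants[sid], config.read_length)

    expression, expr_truth, latent = simulate_expression_table(config, streams["expr"])
    chip, chip_truth = simulate_chip_tables(
        config, streams["chip"], expression, expr_truth, latent
    )
    fish = simulate_fish_measurements(config, streams["fish"])
    ase = simulate_ase_counts(config, streams["ase"], expression, expr_truth)

    main = config.main_chrom
    res = config.sim_resolution
    labels = {
        c: compartment_labels(config.chromosomes[c], config.chrom_sim_resolution(c),
                              config.compartment_block)
        for c in config.chromosomes
    }
    tads = {main: tad_partition(config.chromosomes[main], config.tad_sizes)}
    n_main = -(-config.chromosomes[main] // res)
    gene_density = np.zeros(n_main)
    on_main = expression["chrom"] == main
    np.add.at(gene_density, expression.loc[on_main, "tss"].to_numpy() // res, 1.0)
    orientation = pd.DataFrame(
        {
            "chrom": main,
            "start": np.arange(n_main) * res,
            "end": np.minimum((np.arange(n_main) + 1) * res, config.chromosomes[main]),
            "value": gene_density,
        }
    )
    truth = TruthSet(
        compartment_labels=labels,
        tad_boundaries=tads,
        deletion=config.deletion,
        hotspots=config.hotspots,
        chip_truth=chip_truth,
        expr_truth=expr_truth,
        fish_effect=config.fish_effect,
        orientation_track=orientation,
    )
    return CohortData(
        config, genome, samples, pairs, tags, variants, chip, chip_truth,
        expression, expr_truth, fish, ase, truth,
    )
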