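"""Genome coordinate model: chromosomes, haplotype deletions, fragments, bins.

All in-memory coordinates are 0-based, half-open.  Heterozygous multi-megabase
deletions are represented as haplotype-level intervals on the reference frame
(boundary inference from data is out of scope); positions on a deleted
haplotype live in a "haplotype frame" obtained by excising the deleted
sequence, which is what determines that homolog's contact geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HAPLOTYPES = ("H1", "H2")


@dataclass(frozen=True)
class Deletion:
    """A heterozygous deletion on one haplotype, reference coordinates."""

    chrom: str
    start: int
    end: int
    haplotype: str = "H1"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """Chromosome sizes, per-haplotype deletions and restriction-fragment map.

    Parameters
    ----------
    chromosomes
        Ordered mapping of chromosome name to length in bp.
    deletions
        Haplotype-tagged deletion intervals (reference frame).
    fragment_map
        Per-chromosome sorted internal restriction-cut positions (bp).
    """

    chromosomes: dict[str, int]
    deletions: list[Deletion] = field(default_factory=list)
    fragment_map: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        by_hap: dict[tuple[str, str], list[Deletion]] = {}
        for d in self.deletions:
            if d.haplotype not in HAPLOTYPES:
                raise ValueError(f"unknown haplotype {d.haplotype!r}")
            if d.chrom not in self.chromosomes:
                raise ValueError(f"deletion on unknown chromosome {d.chrom!r}")
            if not (0 <= d.start < d.end <= self.chromosomes[d.chrom]):
                raise ValueError(
                    f"deletion ({d.start}, {d.end}) outside chromosome "
                    f"{d.chrom!r} of length {self.chromosomes[d.chrom]}"
                )
            by_hap.setdefault((d.chrom, d.haplotype), []).append(d)
        for (chrom, hap), dels in by_hap.items():
            dels = sorted(dels, key=lambda d: d.start)
            for a, b in zip(dels, dels[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping deletions on {chrom}/{hap}: "
                        f"({a.start},{a.end}) and ({b.start},{b.end})"
                    )
        for chrom, cuts in self.fragment_map.items():
            cuts = np.asarray(cuts, dtype=np.int64)
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"fragment cuts on {chrom!r} not strictly increasing")
            self.fragment_map[chrom] = cuts

    # -- deletions ---------------------------------------------------------

    def deletions_on(self, chrom: str, haplotype: str) -> list[Deletion]:
        if haplotype not in HAPLOTYPES:
            raise ValueError(f"unknown haplotype {haplotype!r}")
        return sorted(
            (d for d in self.deletions if d.chrom == chrom and d.haplotype == haplotype),
            key=lambda d: d.start,
        )

    def map_reference_to_haplotype(self, haplotype: str, chrom: str, pos):
        """Map reference positions to the haplotype frame.

        Positions left of all deletions are unchanged; positions right of a
        deletion shift left by the total deleted length upstream; positions
        inside a deletion have no image (returned as -1 in the vectorized
        form, ``None`` for scalars).
        """
        dels = self.deletions_on(chrom, haplotype)
        arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if np.any(arr < 0) or np.any(arr >= self.chromosomes[chrom]):
            raise ValueError("position outside chromosome")
        out = arr.copy()
        removed = np.zeros(arr.shape, dtype=np.int64)
        inside = np.zeros(arr.shape, dtype=bool)
        for d in dels:
            inside |= (arr >= d.start) & (arr < d.end)
            removed += np.where(arr >= d.end, d.length, 0)
        out = out - removed
        out[inside] = -1
        if np.isscalar(pos) or np.asarray(pos).ndim == 0:
            return None if inside[0] else int(out[0])
        return out

    def haplotype_length(self, chrom: str, haplotype: str) -> int:
        return self.chromosomes[chrom] - sum(
            d.length for d in self.deletions_on(chrom, haplotype)
        )

    # -- fragments ---------------------------------------------------------

    def assign_to_fragment(self, chrom: str, pos):
        """Fragment id and distance to the nearest cut (or chromosome end).

        Fragment ``i`` spans cut[i-1]..cut[i]; a position exactly on a cut
        belongs to the right-hand fragment (distance 0).  Chromosome ends
        count as cut sites for the distance.
        """
        cuts = self.fragment_map.get(chrom)
        if cuts is None:
            raise ValueError(f"no fragment map for chromosome {chrom!r}")
        arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if np.any(arr < 0) or np.any(arr >= self.chromosomes[chrom]):
            raise ValueError("position outside chromosome")
        frag = np.searchsorted(cuts, arr, side="right")
        bounds = np.concatenate(([0], cuts, [self.chromosomes[chrom]]))
        left = bounds[frag]
        right = bounds[frag + 1]
        dist = np.minimum(arr - left, right - arr)
        if np.isscalar(pos) or np.asarray(pos).ndim == 0:
            return int(frag[0]), int(dist[0])
        return frag, dist

    def fragment_length(self, chrom: str, frag_id) -> np.ndarray:
        cuts = self.fragment_map[chrom]
        bounds = np.concatenate(([0], cuts, [self.chromosomes[chrom]]))
        fid = np.atleast_1d(np.asarray(frag_id, dtype=np.int64))
        return bounds[fid + 1] - bounds[fid]


def build_genome_model(
    chromosomes: dict[str, int],
    deletions: list[tuple[str, int, int, str]] | list[Deletion] | None = None,
    cut_spacing: int = 4000,
    explicit_cuts: dict[str, np.ndarray] | None = None,
) -> GenomeModel:
    """Build a :class:`GenomeModel` from a structured description.

    Restriction cuts are generated at a fixed spacing (default 4 kbp,
    HindIII-like) unless explicit per-chromosome cut arrays are given.
    """
    dels = []
    for d in deletions or []:
        dels.append(d if isinstance(d, Deletion) else Deletion(d[0], int(d[1]), int(d[2]), d[3]))
    frag_map = {}
    for name, length in chromosomes.items():
        if explicit_cuts and name in explicit_cuts:
            frag_map[name] = np.asarray(explicit_cuts[name], dtype=np.int64)
        else:
            frag_map[name] = np.arange(cut_spacing, length, cut_spacing, dtype=np.int64)
    return GenomeModel(dict(chromosomes), dels, frag_map)


@dataclass
class BinScheme:
    """Fixed-resolution genome tiling with dense ids 0..N-1.

    Bins tile each chromosome without gaps or overlaps; the last bin of a
    chromosome may be short.
    """

    resolution: int
    bins: pd.DataFrame  # columns: bin_id, chrom, start, end
    chrom_offsets: dict[str, int]
    chromosomes: dict[str, int]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def n_bins_chrom(self, chrom: str) -> int:
        length = self.chromosomes[chrom]
        return -(-length // self.resolution)

    def bin_id(self, chrom, pos):
        """Vectorized (chrom, pos) -> dense bin id."""
        if isinstance(chrom, str):
            return self.chrom_offsets[chrom] + int(pos) // self.resolution
        offsets = pd.Series(chrom).map(self.chrom_offsets).to_numpy(dtype=np.int64)
        return offsets + np.asarray(pos, dtype=np.int64) // self.resolution

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.n_bins_chrom(chrom))

    def bin_chrom(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()


def make_bins(model: GenomeModel, resolution: int) -> BinScheme:
    """Tile every chromosome of ``model`` at ``resolution`` bp."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rows = []
    offsets = {}
    bid = 0
    for chrom, length in model.chromosomes.items():
        offsets[chrom] = bid
        n = -(-length // resolution)
        starts = np.arange(n, dtype=np.int64) * resolution
        ends = np.minimum(starts + resolution, length)
        for s, e in zip(starts, ends):
            rows.append((bid, chrom, int(s), int(e)))
            bid += 1
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])
    return BinScheme(resolution, bins, offsets, dict(model.chromosomes))
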