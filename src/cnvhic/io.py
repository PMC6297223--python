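"""Readers and writers for the on-disk text formats.

Disk conventions follow the field's standards: ``.pairs``-style contact files
and the VCF-like variant file are 1-based on disk, BED/bedGraph are 0-based
half-open.  In memory everything is 0-based half-open.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import BinScheme, GenomeModel

log = logging.getLogger("cnvhic")

PAIR_COLUMNS = [
    "read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2",
    "frag1", "frag2", "hap1", "hap2",
]
_HAP_TO_DISK = {"H1": "H1", "H2": "H2", "unknown": ".", "conflict": "!"}
_HAP_FROM_DISK = {v: k for k, v in _HAP_TO_DISK.items()}


def canonicalize_pairs(pairs: pd.DataFrame, chrom_order: list[str] | None = None) -> pd.DataFrame:
    """Mate-order records so (chrom1, pos1) <= (chrom2, pos2).

    Chromosomes compare by their position in ``chrom_order`` when given,
    otherwise lexicographically by name.
    """
    if chrom_order is None:
        key1 = pairs["chrom1"].astype(str)
        key2 = pairs["chrom2"].astype(str)
        swap = (key1 > key2) | ((key1 == key2) & (pairs["pos1"] > pairs["pos2"]))
    else:
        rank = {c: i for i, c in enumerate(chrom_order)}
        k1 = pairs["chrom1"].map(rank).to_numpy()
        k2 = pairs["chrom2"].map(rank).to_numpy()
        swap = (k1 > k2) | ((k1 == k2) & (pairs["pos1"].to_numpy() > pairs["pos2"].to_numpy()))
    swap = np.asarray(swap, dtype=bool)
    if not swap.any():
        return pairs
    out = pairs.copy()
    for a, b in [("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2"),
                 ("frag1", "frag2"), ("hap1", "hap2")]:
        if a in out.columns:
            va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
            out.loc[swap, a] = vb[swap]
            out.loc[swap, b] = va[swap]
    return out


def write_pairs(pairs: pd.DataFrame, path, genome: GenomeModel | None = None) -> None:
    """Write a pair table in the ``.pairs`` dialect (1-based positions)."""
    with_tags = {"frag1", "frag2", "hap1", "hap2"}.issubset(pairs.columns)
    cols = "readID chr1 pos1 chr2 pos2 strand1 strand2"
    if with_tags:
        cols += " frag1 frag2 hap1 hap2"
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        if genome is not None:
            for name, length in genome.chromosomes.items():
                fh.write(f"#chromsize: {name} {length}\n")
        fh.write("#columns: " + cols + "\n")
        out = pairs.copy()
        out["pos1"] = out["pos1"] + 1
        out["pos2"] = out["pos2"] + 1
        fields = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
        if with_tags:
            out["hap1"] = out["hap1"].map(_HAP_TO_DISK)
            out["hap2"] = out["hap2"].map(_HAP_TO_DISK)
            fields += ["frag1", "frag2", "hap1", "hap2"]
        out[fields].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a ``.pairs``-dialect file into a 0-based, mate-ordered table."""
    rows = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (7, 11):
                raise ValueError(
                    f"{path}:{lineno}: expected 7 or 11 columns, got {len(parts)}"
                )
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            rows.append((lineno, parts))
    if not rows:
        return pd.DataFrame(columns=PAIR_COLUMNS[: (11 if n_cols == 11 else 7)])
    recs = []
    for lineno, p in rows:
        try:
            pos1, pos2 = int(p[2]) - 1, int(p[4]) - 1
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer position") from exc
        if genome is not None:
            for c, pos in ((p[1], pos1), (p[3], pos2)):
                if c not in genome.chromosomes:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {c!r}")
                if not (0 <= pos < genome.chromosomes[c]):
                    raise ValueError(f"{path}:{lineno}: position {pos + 1} outside {c}")
        rec = [p[0], p[1], pos1, p[3], pos2, p[5], p[6]]
        if n_cols == 11:
            try:
                rec += [int(p[7]), int(p[8]), _HAP_FROM_DISK[p[9]], _HAP_FROM_DISK[p[10]]]
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: bad haplotype code") from exc
        recs.append(rec)
    cols = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    if n_cols == 11:
        cols += ["frag1", "frag2", "hap1", "hap2"]
    df = pd.DataFrame(recs, columns=cols)
    order = list(genome.chromosomes) if genome is not None else None
    return canonicalize_pairs(df, order).reset_index(drop=True)


# -- phased variants -------------------------------------------------------

def write_phased_variants(variants: pd.DataFrame, path) -> None:
    """Write a minimal VCF-like file (phased GT reconstructed from alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2-like\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for row in variants.itertuples(index=False):
            gt = "0|1" if row.hap1_allele == row.ref_allele else "1|0"
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref_allele}\t{row.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_phased_variants(path) -> pd.DataFrame:
    """Read phased heterozygous SNVs from a VCF-like file.

    Only phased heterozygous records (GT ``0|1`` / ``1|0``) are retained;
    homozygous and unphased records are counted and skipped with a log
    message.  Returns columns chrom, pos (0-based), ref_allele, alt_allele,
    hap1_allele, hap2_allele.
    """
    recs = []
    skipped = {"unphased": 0, "homozygous": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 10:
                raise ValueError(f"{path}:{lineno}: missing genotype column")
            fmt = p[8].split(":")
            if not fmt or fmt[0] != "GT":
                raise ValueError(f"{path}:{lineno}: GT not first in FORMAT")
            gt = p[9].split(":")[0]
            if "/" in gt:
                skipped["unphased"] += 1
                continue
            alleles = gt.split("|")
            if len(alleles) != 2 or alleles[0] == alleles[1]:
                skipped["homozygous"] += 1
                continue
            ref, alt = p[3], p[4]
            amap = {"0": ref, "1": alt}
            recs.append((p[0], int(p[1]) - 1, ref, alt, amap[alleles[0]], amap[alleles[1]]))
    if any(skipped.values()):
        log.info("read_phased_variants: skipped %(unphased)d unphased, "
                 "%(homozygous)d homozygous records", skipped)
    df = pd.DataFrame(
        recs,
        columns=["chrom", "pos", "ref_allele", "alt_allele", "hap1_allele", "hap2_allele"],
    )
    df.attrs["skipped"] = skipped
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# -- BED / bedGraph --------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file into (chrom, start, end, name), 0-based half-open."""
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            start, end = int(p[1]), int(p[2])
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval ({start}, {end})")
            recs.append((p[0], start, end, p[3] if len(p) > 3 else ""))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "name", "") or "."
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\n")


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a (chrom, start, end, value) track, values to 6 sig. digits."""
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.rstrip("\n").split("\t")
            start, end = int(p[1]), int(p[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval")
            recs.append((p[0], start, end, float(p[3])))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "value"])


# -- binned matrices (bins TSV + COO TSV) ----------------------------------

def write_matrix(matrix, bins_path, coo_path) -> None:
    """Write a ContactMatrix as a bins table plus COO triplets."""
    matrix.bin_scheme.bins.to_csv(bins_path, sep="\t", index=False)
    coo = matrix.to_coo_frame()
    with open(coo_path, "w") as fh:
        fh.write(f"# resolution={matrix.bin_scheme.resolution} "
                 f"normalization={matrix.normalization} "
                 f"total_raw_pairs={matrix.total_raw_pairs}\n")
        coo.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_matrix(bins_path, coo_path):
    from .matrix import ContactMatrix  # local import to avoid cycle

    bins = pd.read_csv(bins_path, sep="\t")
    meta = {}
    with open(coo_path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
            coo = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            coo = pd.read_csv(fh, sep="\t")
    resolution = int(meta.get("resolution", bins["end"].sub(bins["start"]).max()))
    chroms: dict[str, int] = {}
    offsets: dict[str, int] = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        chroms[chrom] = int(grp["end"].max())
        offsets[chrom] = int(grp["bin_id"].min())
    scheme = BinScheme(resolution, bins, offsets, chroms)
    return ContactMatrix.from_coo(
        scheme,
        coo["bin1_id"].to_numpy(),
        coo["bin2_id"].to_numpy(),
        coo["value"].to_numpy(),
        normalization=meta.get("normalization", "raw"),
        total_raw_pairs=float(meta.get("total_raw_pairs", coo["value"].sum())),
    )
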