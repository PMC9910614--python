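"""Readers and writers for the formats the scan touches.

VCF parsing goes through cyvcf2; everything else (genetic maps, BED masks,
gene tables, ancestral-allele tables) is plain whitespace/tab-separated text
handled with pandas.  All coordinates become 0-based on read (see
:mod:`sweepscan.panel`); 1-based conventions are restored on write where the
format demands them (VCF, ancestral tables).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GeneticMapTable, PhasedPanel, SiteMask, validate_gene_table

logger = logging.getLogger("sweepscan")

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "polarize",
    "read_ancestral_table",
    "write_ancestral_table",
    "ancestral_from_fasta",
    "read_genetic_map",
    "apply_site_mask",
    "filter_missing_sites",
    "harmonize_panels",
    "read_regions_bed",
    "write_regions_bed",
    "read_gene_table",
    "write_gene_table",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str,
    samples: Sequence[str],
    population: str = "pop",
) -> PhasedPanel:
    """Load phased biallelic SNPs for ``samples`` into a :class:`PhasedPanel`.

    Non-SNP and multiallelic records are skipped (count logged).  Unphased or
    half-missing genotypes are marked missing for *both* haplotypes of that
    individual — haplotype statistics need complete cores, so a half-called
    phased pair carries no usable phase information.

    Raises
    ------
    ValueError
        If any requested sample is absent, or no usable site remains.
    """
    from cyvcf2 import VCF

    samples = list(samples)
    vcf = VCF(path, samples=samples)
    absent = [s for s in samples if s not in vcf.samples]
    if absent:
        raise ValueError(f"samples not present in {path}: {absent}")
    order = [vcf.samples.index(s) for s in samples]

    positions, refs, alts, columns, miss_cols = [], [], [], [], []
    chrom = None
    n_skipped = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            n_skipped += 1
            continue
        chrom = var.CHROM
        col = np.zeros(2 * len(samples), dtype=np.uint8)
        mis = np.zeros(2 * len(samples), dtype=bool)
        gts = var.genotypes
        for out_i, vcf_i in enumerate(order):
            a, b, phased = gts[vcf_i][0], gts[vcf_i][1], gts[vcf_i][2]
            het = a != b
            if a < 0 or b < 0 or (het and not phased):
                mis[2 * out_i] = mis[2 * out_i + 1] = True
            else:
                col[2 * out_i] = a
                col[2 * out_i + 1] = b
        positions.append(var.POS - 1)  # to 0-based
        refs.append(var.REF)
        alts.append(var.ALT[0])
        columns.append(col)
        miss_cols.append(mis)
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not positions:
        raise ValueError(f"no usable biallelic SNP records in {path}")

    hap_ids = [f"{s}|{k}" for s in samples for k in (0, 1)]
    return PhasedPanel(
        chrom=chrom,
        positions=np.array(positions),
        alleles=np.column_stack(columns),
        missing=np.column_stack(miss_cols),
        haplotype_ids=hap_ids,
        population=population,
        ref=np.array(refs),
        alt=np.array(alts),
    )


def write_phased_vcf(panels: Sequence[PhasedPanel], path: str) -> None:
    """Write one or more panels (same chromosome & sites) as a phased VCF 4.2.

    Sample columns are concatenated across panels in order.  Missing cells
    become ``.|.``.
    """
    first = panels[0]
    for p in panels[1:]:
        if not np.array_equal(p.positions, first.positions):
            raise ValueError("panels must share an identical site list")
    sample_names = []
    for p in panels:
        sample_names.extend(h.rsplit("|", 1)[0] for h in p.haplotype_ids[::2])
    ref = first.ref if first.ref is not None else np.full(first.n_sites, "A")
    alt = first.alt if first.alt is not None else np.full(first.n_sites, "T")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={first.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for j in range(first.n_sites):
            cells = []
            for p in panels:
                a, m = p.alleles[:, j], p.missing[:, j]
                for i in range(0, p.n_haplotypes, 2):
                    if m[i] or m[i + 1]:
                        cells.append(".|.")
                    else:
                        cells.append(f"{a[i]}|{a[i + 1]}")
            fh.write(f"{first.chrom}\t{first.positions[j] + 1}\t.\t{ref[j]}\t{alt[j]}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Ancestral alleles & polarization
# ---------------------------------------------------------------------------

def read_ancestral_table(path: str) -> dict[int, str]:
    """Two-column table ``position<TAB>base`` (1-based) -> {0-based pos: base}."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["pos", "base"], comment="#")
    return {int(p) - 1: str(b) for p, b in zip(df["pos"], df["base"])}


def write_ancestral_table(positions0: np.ndarray, bases: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for p, b in zip(positions0, bases):
            fh.write(f"{int(p) + 1}\t{b}\n")


def ancestral_from_fasta(path: str, chrom: str, positions0: np.ndarray) -> np.ndarray:
    """Per-site ancestral base looked up from an indexed FASTA (1000G AA dialect:
    lower case marks low-confidence calls, '.'/'-'/'N' unknown)."""
    from pyfaidx import Fasta

    fa = Fasta(path)
    seq = str(fa[chrom][:])
    return np.array([seq[p] if p < len(seq) else "." for p in positions0])


_UNKNOWN = {".", "-", "N", "n", ""}


def polarize(
    panel: PhasedPanel,
    ancestral: Mapping[int, str] | Sequence[str] | np.ndarray,
    drop_low_confidence: bool = False,
) -> PhasedPanel:
    """Recode alleles to 0=ancestral / 1=derived.

    Sites whose ancestral call equals ALT are flipped; sites where it matches
    neither REF nor ALT, or is unknown, are dropped (logged).  Lower-case
    calls (low confidence in the 1000G ancestral-allele dialect) are accepted
    unless ``drop_low_confidence``.
    """
    if panel.ref is None or panel.alt is None:
        raise ValueError("panel lacks REF/ALT metadata needed for polarization")
    if isinstance(ancestral, Mapping):
        anc = np.array([ancestral.get(int(p), ".") for p in panel.positions])
    else:
        anc = np.asarray(ancestral, dtype=object)
        if anc.size != panel.n_sites:
            raise ValueError("per-site ancestral array length mismatch")

    keep, flip = [], []
    for j, a in enumerate(anc):
        a = str(a)
        if a in _UNKNOWN or (drop_low_confidence and a.islower()):
            continue
        au = a.upper()
        if au == str(panel.ref[j]).upper():
            keep.append(j)
            flip.append(False)
        elif au == str(panel.alt[j]).upper():
            keep.append(j)
            flip.append(True)
        # else: matches neither -> dropped
    n_dropped = panel.n_sites - len(keep)
    if n_dropped:
        logger.info("polarize: dropped %d sites with unusable ancestral calls", n_dropped)
    if not keep:
        raise ValueError("polarization left no usable sites")

    out = panel.take_sites(np.array(keep))
    flip = np.array(flip)
    if flip.any():
        sub = out.alleles[:, flip]
        out.alleles[:, flip] = np.where(out.missing[:, flip], sub, 1 - sub)
        ref_f, alt_f = out.ref[flip].copy(), out.alt[flip].copy()
        out.ref[flip], out.alt[flip] = alt_f, ref_f
    out.polarized = True
    return out


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------

def read_genetic_map(path: str, chrom: str | None = None) -> GeneticMapTable:
    """Auto-detect HapMap-style (``pos rate cM``) or 4-column
    (``chrom pos rate cM``) whitespace-separated map text; an optional header
    line is skipped.  File positions are 1-based."""
    with open(path) as fh:
        first = fh.readline().split()

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in first[max(0, len(first) - 3):])
    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None)
    df.columns = range(df.shape[1])
    if df.shape[1] >= 4 and not _numeric(str(df.iloc[0, 0])):
        file_chrom = str(df.iloc[0, 0])
        pos, cm = df[1], df[3]
        chrom = chrom or file_chrom
    elif df.shape[1] >= 3:
        pos, cm = df[0], df[2]
        if chrom is None:
            raise ValueError("map file has no chromosome column; pass chrom=")
    else:
        raise ValueError("unrecognized genetic-map layout")
    return GeneticMapTable(
        chrom=chrom,
        anchor_positions=pos.to_numpy(dtype=np.int64) - 1,
        anchor_cM=cm.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Masks & missingness
# ---------------------------------------------------------------------------

def apply_site_mask(panel: PhasedPanel, mask: SiteMask, mode: str = "remove") -> PhasedPanel:
    """Drop (``mode='remove'``) or exclusively retain (``mode='keep'``) the
    panel sites that fall inside the mask intervals."""
    if mode not in ("remove", "keep"):
        raise ValueError("mode must be 'remove' or 'keep'")
    inside = mask.contains(panel.chrom, panel.positions)
    keep = ~inside if mode == "remove" else inside
    logger.info("apply_site_mask(%s, %s): %d -> %d sites",
                mask.label, mode, panel.n_sites, int(keep.sum()))
    if not keep.any():
        raise ValueError(f"mask '{mask.label}' ({mode}) removed every site")
    return panel.take_sites(np.flatnonzero(keep))


def filter_missing_sites(panels: Sequence[PhasedPanel], max_missing: float = 0.10,
                         ) -> list[PhasedPanel]:
    """Drop sites whose missing-haplotype fraction exceeds ``max_missing`` in
    any analyzed population.  Panels must share a site list."""
    bad = np.zeros(panels[0].n_sites, dtype=bool)
    for p in panels:
        if p.n_sites != panels[0].n_sites:
            raise ValueError("panels must share a site list (harmonize first)")
        bad |= p.missing_fraction() > max_missing
    if bad.any():
        logger.info("filter_missing_sites: dropped %d of %d sites", bad.sum(), bad.size)
    keep = np.flatnonzero(~bad)
    if keep.size == 0:
        raise ValueError("missingness filter removed every site")
    return [p.take_sites(keep) for p in panels]


def harmonize_panels(panels: Sequence[PhasedPanel]) -> list[PhasedPanel]:
    """Subset every panel to the intersection of their site positions."""
    shared = panels[0].positions
    for p in panels[1:]:
        shared = np.intersect1d(shared, p.positions)
    if shared.size == 0:
        raise ValueError("panels share no sites")
    return [p.take_sites(np.searchsorted(p.positions, shared)) for p in panels]


# ---------------------------------------------------------------------------
# BED & gene tables
# ---------------------------------------------------------------------------

def write_regions_bed(regions: pd.DataFrame, path: str) -> None:
    """Write BED3+ (0-based half-open).  Unsorted input is sorted with a
    warning; the empty set yields a header-comment-only file."""
    cols = [c for c in ["chrom", "start", "end"] if c in regions.columns]
    if len(cols) < 3:
        raise ValueError("regions need chrom/start/end columns")
    extra = [c for c in regions.columns if c not in ("chrom", "start", "end")]
    df = regions[["chrom", "start", "end"] + extra]
    if not df[["chrom", "start"]].equals(df.sort_values(["chrom", "start"])[["chrom", "start"]]):
        logger.warning("write_regions_bed: input unsorted; sorting on write")
        df = df.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend" + ("\t" + "\t".join(extra) if extra else "") + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_regions_bed(path: str) -> pd.DataFrame:
    """Read BED3+ written by :func:`write_regions_bed` (or any BED3)."""
    rows = []
    names = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                names = line.lstrip("#").split("\t")
                continue
            if not line or line.startswith(("track", "browser")):
                continue
            rows.append(line.split("\t"))
    if names is None or len(names) < 3:
        names = ["chrom", "start", "end"]
    if not rows:
        return pd.DataFrame(columns=names).astype({"start": np.int64, "end": np.int64},
                                                  errors="ignore")
    df = pd.DataFrame(rows, columns=names + [f"col{i}" for i in range(len(rows[0]) - len(names))])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    for c in df.columns[3:]:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df


def read_gene_table(path: str) -> pd.DataFrame:
    """Tab-separated gene table with header gene_id/chrom/start/end/strand
    (0-based half-open transcript spans)."""
    return validate_gene_table(pd.read_csv(path, sep="\t"))


def write_gene_table(genes: pd.DataFrame, path: str) -> None:
    validate_gene_table(genes).to_csv(path, sep="\t", index=False)
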