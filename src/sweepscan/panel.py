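"""Core in-memory containers shared across the pipeline.

Coordinate convention: every position and interval in memory is 0-based,
intervals half-open — the BED convention.  VCF positions (1-based) are
converted on read and restored on write, which removes the off-by-one
ambiguity between the variant and interval worlds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["PhasedPanel", "GeneticMapTable", "SiteMask", "validate_gene_table"]


@dataclass
class PhasedPanel:
    """Phased biallelic haplotypes for one population on one chromosome.

    ``alleles`` is a (n_haplotypes, n_sites) uint8 matrix.  Before
    polarization codes are 0=REF, 1=ALT; after :func:`sweepscan.io.polarize`
    they are 0=ancestral, 1=derived.  ``missing`` marks haplotype/site cells
    that carry no usable call (unphased or ancestry-masked genotypes).
    """

    chrom: str
    positions: np.ndarray          # 0-based bp, strictly increasing
    alleles: np.ndarray            # (n_hap, n_sites) uint8 in {0,1}
    haplotype_ids: list[str]
    population: str
    ref: np.ndarray | None = None  # per-site REF base (pre-polarization bookkeeping)
    alt: np.ndarray | None = None
    missing: np.ndarray | None = None  # (n_hap, n_sites) bool
    polarized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype-by-site matrix")
        n_hap, n_sites = self.alleles.shape
        if n_sites != self.positions.size:
            raise ValueError("positions / alleles shape mismatch")
        if n_hap % 2 != 0:
            raise ValueError("haplotype count must be even (phased diploids)")
        if len(self.haplotype_ids) != n_hap:
            raise ValueError("haplotype_ids length mismatch")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be unique and strictly increasing")
        if self.missing is None:
            self.missing = np.zeros_like(self.alleles, dtype=bool)
        else:
            self.missing = np.ascontiguousarray(self.missing, dtype=bool)
            if self.missing.shape != self.alleles.shape:
                raise ValueError("missing mask shape mismatch")
        if not np.all((self.alleles == 0) | (self.alleles == 1) | self.missing):
            raise ValueError("allele codes must be 0/1 or flagged missing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-site frequency of allele 1 among non-missing haplotypes."""
        ok = ~self.missing
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, (self.alleles * ok).sum(axis=0) / n, np.nan)

    def missing_fraction(self) -> np.ndarray:
        return self.missing.mean(axis=0)

    def take_sites(self, index: np.ndarray) -> "PhasedPanel":
        """Subset to the given site indices (order-preserving)."""
        index = np.asarray(index)
        return replace(
            self,
            positions=self.positions[index],
            alleles=self.alleles[:, index],
            missing=self.missing[:, index],
            ref=None if self.ref is None else np.asarray(self.ref)[index],
            alt=None if self.alt is None else np.asarray(self.alt)[index],
        )


@dataclass
class GeneticMapTable:
    """Physical-to-genetic map anchors for one chromosome (cM non-decreasing)."""

    chrom: str
    anchor_positions: np.ndarray  # 0-based bp
    anchor_cM: np.ndarray

    def __post_init__(self) -> None:
        self.anchor_positions = np.asarray(self.anchor_positions, dtype=np.int64)
        self.anchor_cM = np.asarray(self.anchor_cM, dtype=float)
        if self.anchor_positions.size != self.anchor_cM.size:
            raise ValueError("anchor arrays must have equal length")
        if self.anchor_positions.size < 2:
            raise ValueError("a genetic map needs at least 2 anchors")
        if not np.all(np.diff(self.anchor_positions) > 0):
            raise ValueError("anchor positions must be strictly increasing")
        if np.any(np.diff(self.anchor_cM) < 0):
            raise ValueError("anchor cM must be non-decreasing")

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """Piecewise-linear cM at ``positions``; constant terminal-rate
        extrapolation beyond the outermost anchors."""
        pos = np.asarray(positions, dtype=float)
        p, c = self.anchor_positions.astype(float), self.anchor_cM
        out = np.interp(pos, p, c)
        rate_lo = (c[1] - c[0]) / (p[1] - p[0])
        rate_hi = (c[-1] - c[-2]) / (p[-1] - p[-2])
        lo, hi = pos < p[0], pos > p[-1]
        out[lo] = c[0] + (pos[lo] - p[0]) * rate_lo
        out[hi] = c[-1] + (pos[hi] - p[-1]) * rate_hi
        return out


@dataclass
class SiteMask:
    """A set of genomic intervals (0-based, half-open), e.g. an accessibility
    strict mask or conserved elements.  Normalized: sorted, non-overlapping."""

    intervals: pd.DataFrame  # columns: chrom, start, end
    label: str = "mask"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"]).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.intervals = _merge_intervals(df)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean per position: inside any interval of this mask."""
        pos = np.asarray(positions, dtype=np.int64)
        sub = self.intervals[self.intervals["chrom"] == chrom]
        out = np.zeros(pos.size, dtype=bool)
        if len(sub) == 0:
            return out
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # intervals are sorted & disjoint: searchsorted gives the candidate
        idx = np.searchsorted(starts, pos, side="right") - 1
        valid = idx >= 0
        out[valid] = pos[valid] < ends[idx[valid]]
        return out

    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/touching intervals per chromosome."""
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Check the gene-table schema (0-based half-open transcript spans)."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("gene table requires start < end")
    return genes
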