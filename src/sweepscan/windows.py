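"""Fisher's combined score, 50-kb window calling, and candidate regions.

The three per-SNP statistics are reduced to genome-wide ranks, converted to
empirical p-values p = rank/(N+1), and combined per site as
FCS = -2 * sum(ln p).  Windows tiling the genome are then called as outliers
by two summarization approaches (outlier-SNP count, window median FCS),
collapsed into nonoverlapping candidate regions, and annotated with genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .panel import SiteMask, validate_gene_table

__all__ = [
    "FCSParams", "ranks_to_fcs", "tile_windows", "annotate_windows",
    "WindowCallParams", "call_outlier_windows", "collapse_regions",
    "region_median_fcs", "annotate_genes", "trait_enrichment_hypergeom",
    "enrichment_table",
]

#: default ranking directions: sweeps give extreme |iHS|, positive XP-EHH,
#: large PBS in the focal population
DEFAULT_DIRECTIONS = {"ihs_std": "absolute", "xpehh_std": "upper", "pbs": "upper"}


@dataclass
class FCSParams:
    directions: dict | None = None
    min_stats: int = 3


def ranks_to_fcs(scan: pd.DataFrame, params: FCSParams = FCSParams()) -> pd.DataFrame:
    """Per-site Fisher's combined score from genome-wide ranks.

    For each statistic, valid sites are ranked extreme-first (rank 1 = most
    extreme; ties get the average rank) in its configured direction, giving
    p = rank/(N_valid + 1).  Sites with fewer than ``min_stats`` valid
    statistics are dropped (all three by default, keeping the FCS scale
    comparable across sites).
    """
    directions = params.directions or DEFAULT_DIRECTIONS
    out = scan[["chrom", "pos"]].copy()
    n_used = np.zeros(len(scan), dtype=int)
    log_p_sum = np.zeros(len(scan))
    any_stat = False
    for col, direction in directions.items():
        if col not in scan.columns:
            continue
        any_stat = True
        vcol = {"ihs_std": "ihs_valid", "xpehh_std": "xpehh_valid",
                "pbs": "pbs_valid"}.get(col)
        valid = scan[vcol].to_numpy(dtype=bool) if vcol in scan.columns \
            else np.isfinite(scan[col].to_numpy(dtype=float))
        vals = scan[col].to_numpy(dtype=float)
        valid = valid & np.isfinite(vals)
        score = np.abs(vals) if direction == "absolute" else \
            (vals if direction == "upper" else -vals)
        ranks = np.full(len(scan), np.nan)
        if valid.sum() == 0:
            continue
        ranks[valid] = rankdata(-score[valid], method="average")
        p = ranks / (valid.sum() + 1.0)
        short = col.replace("_std", "")
        out[f"rank_{short}"] = ranks
        out[f"p_{short}"] = np.where(valid, p, np.nan)
        n_used += valid.astype(int)
        log_p_sum += np.where(valid, np.log(np.where(valid, p, 1.0)), 0.0)
    if not any_stat or n_used.max() == 0:
        raise ValueError("no valid statistics available for FCS")
    out["n_stats_used"] = n_used
    out["fcs"] = np.where(n_used >= params.min_stats, -2.0 * log_p_sum, np.nan)
    kept = out[out["n_stats_used"] >= params.min_stats].reset_index(drop=True)
    if kept.empty:
        raise ValueError("every site failed the min_stats requirement")
    return kept


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def tile_windows(chrom_lengths: dict[str, int], window_size: int = 50_000,
                 ) -> pd.DataFrame:
    """Half-open fixed tiling of each chromosome; the final partial window
    (if any) is kept and flagged."""
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        start = 0
        while start < length:
            end = min(start + window_size, length)
            rows.append((chrom, start, end, end - start < window_size))
            start = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def annotate_windows(windows: pd.DataFrame, fcs: pd.DataFrame,
                     conserved: SiteMask | None = None,
                     gmap=None) -> pd.DataFrame:
    """Add per-window summaries: n_snps (valid-FCS sites), n_conserved_snps,
    mean recombination rate (cM/Mb over the window span), and median FCS.

    ``gmap`` may be a single GeneticMapTable or a dict chrom -> table.
    Windows without sites carry NaN median (excluded from pools downstream).
    """
    win = windows.copy().reset_index(drop=True)
    n_snps = np.zeros(len(win), dtype=int)
    n_cons = np.zeros(len(win), dtype=int)
    med = np.full(len(win), np.nan)
    rate = np.full(len(win), np.nan)
    for chrom, sub in win.groupby("chrom"):
        sites = fcs[(fcs["chrom"] == chrom) & np.isfinite(fcs["fcs"])]
        pos = sites["pos"].to_numpy()
        vals = sites["fcs"].to_numpy()
        cons = conserved.contains(chrom, pos) if conserved is not None else \
            np.zeros(pos.size, dtype=bool)
        gm = gmap.get(chrom) if isinstance(gmap, dict) else gmap
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        for k, widx in enumerate(sub.index):
            sl = slice(lo[k], hi[k])
            n_snps[widx] = hi[k] - lo[k]
            n_cons[widx] = int(cons[sl].sum())
            if hi[k] > lo[k]:
                med[widx] = float(np.median(vals[sl]))
            if gm is not None:
                span_cm = gm.interpolate([ends[k]])[0] - gm.interpolate([starts[k]])[0]
                rate[widx] = span_cm / ((ends[k] - starts[k]) / 1e6)
    win["n_snps"] = n_snps
    win["n_conserved_snps"] = n_cons
    win["mean_recomb_rate"] = rate
    win["median_fcs"] = med
    return win


@dataclass
class WindowCallParams:
    """Outlier-window thresholds.

    q_site : genome-wide top quantile defining FCS outlier SNPs (approach A).
    q_winA : top quantile of per-window outlier-SNP counts (approach A).
    q_winB : top quantile of window median FCS (approach B).
    min_window_snps : windows with fewer valid-FCS sites are ineligible.
    """

    q_site: float = 0.01
    q_winA: float = 0.01
    q_winB: float = 0.005
    min_window_snps: int = 10


def call_outlier_windows(windows: pd.DataFrame, fcs: pd.DataFrame,
                         approach: str = "union",
                         params: WindowCallParams = WindowCallParams(),
                         ) -> pd.DataFrame:
    """Call outlier windows by approach ``'A'`` (outlier-SNP count),
    ``'B'`` (median FCS) or their ``'union'`` (with per-window provenance).

    Quantile thresholds are strict (a window must *exceed* the cutoff), so a
    degenerate constant FCS field yields no calls.
    """
    win = windows.copy().reset_index(drop=True)
    if "median_fcs" not in win.columns:
        win = annotate_windows(win, fcs)
    eligible = win["n_snps"] >= params.min_window_snps
    if not eligible.any():
        raise ValueError("no window satisfies min_window_snps")

    fvals = fcs.loc[np.isfinite(fcs["fcs"]), ["chrom", "pos", "fcs"]]
    site_thr = np.quantile(fvals["fcs"], 1.0 - params.q_site)
    outlier_sites = fvals[fvals["fcs"] > site_thr]
    counts = np.zeros(len(win), dtype=int)
    for chrom, sub in win.groupby("chrom"):
        pos = np.sort(outlier_sites.loc[outlier_sites["chrom"] == chrom, "pos"].to_numpy())
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        counts[sub.index] = hi - lo
    win["n_fcs_outlier_snps"] = counts

    elig_counts = counts[eligible.to_numpy()]
    thrA = np.quantile(elig_counts, 1.0 - params.q_winA)
    calledA = eligible & (counts > thrA)
    elig_med = win.loc[eligible, "median_fcs"].to_numpy()
    thrB = np.quantile(elig_med, 1.0 - params.q_winB)
    calledB = eligible & (win["median_fcs"] > thrB)

    win["called_A"] = calledA
    win["called_B"] = calledB
    if approach == "A":
        sel = calledA
    elif approach == "B":
        sel = calledB
    elif approach == "union":
        sel = calledA | calledB
    else:
        raise ValueError("approach must be 'A', 'B' or 'union'")
    return win[sel].reset_index(drop=True)


def collapse_regions(outliers: pd.DataFrame, merge_adjacent: bool = True,
                     ) -> pd.DataFrame:
    """Merge overlapping (and, by default, book-ended) outlier windows into
    sorted nonoverlapping candidate regions.  Idempotent."""
    if outliers.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows"])
    rows = []
    df = outliers.sort_values(["chrom", "start"])
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        n = 0
        for s, e in zip(sub["start"], sub["end"]):
            joined = cur_s is not None and \
                (s <= cur_e if merge_adjacent else s < cur_e)
            if joined:
                cur_e = max(cur_e, e)
                n += 1
            else:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        rows.append((chrom, cur_s, cur_e, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])


def region_median_fcs(regions: pd.DataFrame, fcs: pd.DataFrame) -> pd.DataFrame:
    """Median FCS over the valid sites inside each candidate region."""
    out = regions.copy().reset_index(drop=True)
    med = np.full(len(out), np.nan)
    for i, row in out.iterrows():
        sel = fcs[(fcs["chrom"] == row["chrom"]) & (fcs["pos"] >= row["start"])
                  & (fcs["pos"] < row["end"]) & np.isfinite(fcs["fcs"])]
        if len(sel):
            med[i] = float(np.median(sel["fcs"]))
    out["median_fcs"] = med
    return out


def annotate_genes(regions: pd.DataFrame, genes: pd.DataFrame,
                   flank: int = 250_000) -> pd.DataFrame:
    """Attach overlapping and nearby genes to each region.

    Overlap = any bp intersection with the transcript span.  Nearby = either
    transcript boundary (start, or end taken as the half-open end coordinate)
    within ``flank`` bp of the region, boundary inclusive.
    """
    genes = validate_gene_table(genes)
    out = regions.copy().reset_index(drop=True)
    overlapping, nearby = [], []
    for _, row in out.iterrows():
        g = genes[genes["chrom"] == row["chrom"]]
        ov = g[(g["start"] < row["end"]) & (g["end"] > row["start"])]
        ends_near = ((g["start"] >= row["start"] - flank) & (g["start"] <= row["end"] + flank)) | \
                    ((g["end"] >= row["start"] - flank) & (g["end"] <= row["end"] + flank))
        overlapping.append(sorted(ov["gene_id"].tolist()))
        nearby.append(sorted(g.loc[ends_near, "gene_id"].tolist()))
    out["overlapping_genes"] = overlapping
    out["nearby_genes"] = nearby
    return out


# ---------------------------------------------------------------------------
# GWAS-trait gene enrichment
# ---------------------------------------------------------------------------

def trait_enrichment_hypergeom(universe_genes: int, candidate_genes: int,
                               trait_genes: int, overlap: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap): probability that at least
    ``overlap`` of the ``candidate_genes`` drawn from ``universe_genes``
    belong to the ``trait_genes`` class."""
    if not (0 <= overlap <= min(candidate_genes, trait_genes)
            and max(candidate_genes, trait_genes) <= universe_genes):
        raise ValueError("inconsistent hypergeometric counts")
    return float(hypergeom.sf(overlap - 1, universe_genes, trait_genes,
                              candidate_genes))


def enrichment_table(counts: pd.DataFrame, fdr: float = 0.10,
                     min_trait_genes: int = 7) -> pd.DataFrame:
    """Hypergeometric enrichment across traits with BH adjustment.

    ``counts`` columns: trait, universe, candidate, trait_genes, overlap.
    Only traits with at least ``min_trait_genes`` associated genes are tested
    (the remainder get NaN p/q).  Adds p, q and a ``significant`` call at the
    requested FDR.
    """
    from statsmodels.stats.multitest import multipletests

    out = counts.copy().reset_index(drop=True)
    p = np.full(len(out), np.nan)
    for i, row in out.iterrows():
        if row["trait_genes"] >= min_trait_genes:
            p[i] = trait_enrichment_hypergeom(row["universe"], row["candidate"],
                                              row["trait_genes"], row["overlap"])
    out["p"] = p
    q = np.full(len(out), np.nan)
    tested = np.isfinite(p)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out["q"] = q
    out["significant"] = q <= fdr
    return out
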