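"""Polygenic selection tests: trait-window sets against matched null draws.

A trait is represented by the 50-kb windows that contain its associated loci
(GWAS hits below a significance threshold, or the coding span +/- 10 kb of
virus-interacting genes).  The observed statistic is the median over those
windows of the window median FCS.  The null replaces each trait window with
a random non-trait window from the same joint quartile stratum of
(n_snps, n_conserved_snps, mean_recomb_rate) — scheme 1 — or resamples genes
and re-expands them to windows — scheme 2.  Empirical p is the proportion of
null draws whose median is strictly higher than observed (the strict rule;
an optional (k+1)/(n+1) correction is available but off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import validate_gene_table
from .windows import annotate_windows  # re-exported convenience

logger = logging.getLogger("sweepscan")

__all__ = [
    "annotate_windows", "build_trait_windows", "build_virus_windows",
    "MatchingStrata", "EnrichmentResult", "matched_window_permutation",
    "matched_gene_permutation", "adjust_fdr", "flag_outlier_traits",
]

_COVARIATES = ["n_snps", "n_conserved_snps", "mean_recomb_rate"]


# ---------------------------------------------------------------------------
# Trait window sets
# ---------------------------------------------------------------------------

def build_trait_windows(windows: pd.DataFrame, gwas_hits: pd.DataFrame,
                        p_threshold: float = 5e-8) -> np.ndarray:
    """Indices (into ``windows``) containing >=1 GWAS hit with p strictly
    below ``p_threshold``.  ``gwas_hits`` columns: chrom, pos, p."""
    hits = gwas_hits[gwas_hits["p"] < p_threshold]
    idx = set()
    for chrom, sub in windows.groupby("chrom"):
        pos = hits.loc[hits["chrom"] == chrom, "pos"].to_numpy()
        if pos.size == 0:
            continue
        pos = np.sort(pos)
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        idx.update(np.asarray(sub.index)[hi > lo].tolist())
    if not idx:
        logger.warning("build_trait_windows: no windows pass; trait should be skipped")
    return np.array(sorted(idx), dtype=int)


def build_virus_windows(windows: pd.DataFrame, genes: pd.DataFrame,
                        virus_gene_ids, flank: int = 10_000) -> np.ndarray:
    """Windows intersecting [start - flank, end + flank) of any listed gene
    (coding span plus 10-kb putative regulatory regions).  Unknown ids warn
    and are skipped; duplicates are deduplicated."""
    genes = validate_gene_table(genes)
    wanted = list(dict.fromkeys(virus_gene_ids))
    known = set(genes["gene_id"])
    unknown = [g for g in wanted if g not in known]
    if unknown:
        logger.warning("build_virus_windows: unknown gene ids skipped: %s", unknown)
    sub = genes[genes["gene_id"].isin(wanted)]
    idx = set()
    for _, g in sub.iterrows():
        s, e = g["start"] - flank, g["end"] + flank
        hit = windows[(windows["chrom"] == g["chrom"])
                      & (windows["start"] < e) & (windows["end"] > s)]
        idx.update(np.asarray(hit.index).tolist())
    return np.array(sorted(idx), dtype=int)


# ---------------------------------------------------------------------------
# Matching strata
# ---------------------------------------------------------------------------

@dataclass
class MatchingStrata:
    """Joint quartile bins over the window covariates.

    Quartile edges are computed over *all* eligible windows (trait and
    non-trait alike), so strata are stable across traits.  ``codes`` maps
    each eligible window to a tuple of per-covariate quartile indices.
    """

    edges: dict[str, np.ndarray]
    codes: pd.DataFrame  # per-covariate quartile index, indexed like windows

    @classmethod
    def from_windows(cls, annotated: pd.DataFrame,
                     covariates=tuple(_COVARIATES)) -> "MatchingStrata":
        eligible = annotated[np.isfinite(annotated["median_fcs"])]
        edges, codes = {}, {}
        for c in covariates:
            v = eligible[c].to_numpy(dtype=float)
            e = np.quantile(v, [0.25, 0.5, 0.75])
            edges[c] = e
            codes[c] = np.searchsorted(e, eligible[c].to_numpy(dtype=float),
                                       side="right")
        return cls(edges=edges, codes=pd.DataFrame(codes, index=eligible.index))

    def key(self, window_index: int, covariates=None) -> tuple:
        cov = covariates or list(self.codes.columns)
        return tuple(int(self.codes.loc[window_index, c]) for c in cov)


# ---------------------------------------------------------------------------
# Permutation schemes
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    trait_id: str
    n_windows: int
    observed_median_fcs: float
    null_medians: np.ndarray
    empirical_p: float
    scheme: str
    seed: int | None = None
    bh_q: float = np.nan
    notes: list = field(default_factory=list)


def _empirical_p(null: np.ndarray, observed: float, plus_one: bool) -> float:
    k = int((null > observed).sum())
    if plus_one:
        return (k + 1) / (null.size + 1)
    return k / null.size


def matched_window_permutation(trait_id: str, trait_idx: np.ndarray,
                               annotated: pd.DataFrame,
                               n_samples: int = 10_000,
                               seed: int | None = None,
                               min_pool: int = 5,
                               plus_one: bool = False,
                               rng: np.random.Generator | None = None,
                               ) -> EnrichmentResult:
    """Scheme 1: replace each trait window with a random non-trait window
    from the same covariate stratum.

    Sampling is without replacement within one draw and with replacement
    across draws.  A stratum whose non-trait pool is smaller than
    ``min_pool`` times its trait-window count falls back to matching on 2 of
    the 3 covariates (logged); if still unfillable, a hard error names it.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    strata = MatchingStrata.from_windows(annotated)
    eligible_idx = strata.codes.index
    trait_set = set(trait_idx.tolist())
    trait_elig = [i for i in trait_idx if i in set(eligible_idx)]
    if not trait_elig:
        raise ValueError(f"trait {trait_id}: no eligible (median-FCS) windows")
    med = annotated["median_fcs"]
    observed = float(np.median(med.loc[trait_elig].to_numpy()))

    elig_arr = np.asarray(eligible_idx)
    codes_np = strata.codes.to_numpy()            # (n_eligible, 3)
    nontrait_mask = ~np.isin(elig_arr, np.asarray(trait_idx))
    trait_pos = {i: t for t, i in enumerate(elig_arr)}
    notes = []
    # group trait windows by full stratum, with per-stratum fallback
    full_keys: dict[tuple, list[int]] = {}
    for i in trait_elig:
        full_keys.setdefault(tuple(codes_np[trait_pos[i]]), []).append(i)
    groups = []  # (pool_values, k_needed)
    for key, members in full_keys.items():
        k = len(members)
        sel = (codes_np == np.array(key)).all(axis=1) & nontrait_mask
        pool = elig_arr[sel]
        if pool.size < min_pool * k:
            matched = None
            for drop in reversed(range(3)):  # relax least-important covariate first
                keep_cols = [t for t in range(3) if t != drop]
                want = np.array([key[t] for t in keep_cols])
                sel2 = (codes_np[:, keep_cols] == want).all(axis=1) & nontrait_mask
                cand = elig_arr[sel2]
                if cand.size >= min_pool * k:
                    matched = cand
                    notes.append(f"stratum {key}: relaxed to "
                                 f"{[_COVARIATES[t] for t in keep_cols]}")
                    logger.info("matched_window_permutation(%s): %s", trait_id, notes[-1])
                    break
            if matched is None:
                raise ValueError(
                    f"trait {trait_id}: stratum {key} has only {pool.size} "
                    f"non-trait windows for {k} trait windows")
            pool = matched
        groups.append((med.loc[pool].to_numpy(dtype=float), k))

    x = len(trait_elig)
    null = np.empty(n_samples)
    chunk = 2000
    for c0 in range(0, n_samples, chunk):
        c1 = min(c0 + chunk, n_samples)
        draw_vals = np.empty((c1 - c0, x))
        col = 0
        for pool_vals, k in groups:
            m = pool_vals.size
            keys = rng.random((c1 - c0, m))
            pick = np.argpartition(keys, k - 1, axis=1)[:, :k]
            draw_vals[:, col:col + k] = pool_vals[pick]
            col += k
        null[c0:c1] = np.median(draw_vals, axis=1)

    return EnrichmentResult(
        trait_id=trait_id, n_windows=x, observed_median_fcs=observed,
        null_medians=null, empirical_p=_empirical_p(null, observed, plus_one),
        scheme="window", seed=seed, notes=notes)


def matched_gene_permutation(trait_id: str, virus_gene_ids,
                             genes: pd.DataFrame, annotated: pd.DataFrame,
                             n_samples: int = 10_000,
                             seed: int | None = None,
                             flank: int = 10_000,
                             plus_one: bool = False,
                             rng: np.random.Generator | None = None,
                             ) -> EnrichmentResult:
    """Scheme 2 (gene resampling, preserving window adjacency structure):
    draw the same number of genes from the non-focal gene universe, expand
    each draw to the 50-kb windows overlapping their coding +/- flank spans,
    and take the median window FCS.  Windows associated with the focal trait
    are excluded from the null expansion."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    genes = validate_gene_table(genes).reset_index(drop=True)
    wanted = list(dict.fromkeys(virus_gene_ids))
    obs_idx = build_virus_windows(annotated, genes, wanted, flank=flank)
    med = annotated["median_fcs"]
    obs_elig = [i for i in obs_idx if np.isfinite(med.loc[i])]
    if not obs_elig:
        raise ValueError(f"trait {trait_id}: no eligible windows")
    observed = float(np.median(med.loc[obs_elig].to_numpy()))

    universe = genes[~genes["gene_id"].isin(wanted)].reset_index()
    if len(universe) < len(wanted):
        raise ValueError(f"trait {trait_id}: gene universe too small to resample")

    # precompute each universe gene's eligible, non-focal window indices
    trait_set = set(obs_idx.tolist())
    elig = set(annotated.index[np.isfinite(med)].tolist()) - trait_set
    per_gene = []
    for _, g in universe.iterrows():
        s, e = g["start"] - flank, g["end"] + flank
        hit = annotated[(annotated["chrom"] == g["chrom"])
                        & (annotated["start"] < e) & (annotated["end"] > s)]
        per_gene.append(np.array([i for i in hit.index if i in elig], dtype=int))

    k = len(wanted)
    null = np.empty(n_samples)
    med_arr = med.to_dict()
    for d in range(n_samples):
        pick = rng.choice(len(universe), size=k, replace=False)
        wset = np.unique(np.concatenate([per_gene[i] for i in pick])) \
            if any(per_gene[i].size for i in pick) else np.array([], dtype=int)
        null[d] = np.median([med_arr[i] for i in wset]) if wset.size else -np.inf
    return EnrichmentResult(
        trait_id=trait_id, n_windows=len(obs_elig),
        observed_median_fcs=observed, null_medians=null,
        empirical_p=_empirical_p(null, observed, plus_one),
        scheme="gene", seed=seed)


# ---------------------------------------------------------------------------
# Multiple testing & sanity flags
# ---------------------------------------------------------------------------

def adjust_fdr(results: list[EnrichmentResult], fdr: float = 0.10) -> pd.DataFrame:
    """BH-adjust empirical p across traits; returns the results table with q
    and the significance call at the requested FDR."""
    from statsmodels.stats.multitest import multipletests

    p = np.array([r.empirical_p for r in results])
    q = multipletests(p, method="fdr_bh")[1]
    for r, qi in zip(results, q):
        r.bh_q = float(qi)
    return pd.DataFrame({
        "trait": [r.trait_id for r in results],
        "n_windows": [r.n_windows for r in results],
        "observed_median_fcs": [r.observed_median_fcs for r in results],
        "p": p, "q": q, "significant": q <= fdr,
        "scheme": [r.scheme for r in results],
    })


def flag_outlier_traits(trait_window_counts: dict[str, int],
                        min_ratio: float = 10.0) -> list[str]:
    """Flag traits whose testable-window count is >= ``min_ratio``-fold below
    the median across traits (they are flagged, not dropped)."""
    if len(trait_window_counts) < 2:
        return []
    counts = np.array(list(trait_window_counts.values()), dtype=float)
    m = np.median(counts)
    return [t for t, c in trait_window_counts.items() if c <= m / min_ratio]
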