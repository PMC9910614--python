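"""Per-SNP selection statistics: iHS, XP-EHH, per-site F_ST and PBS.

All statistics propagate undefined values as NaN plus an explicit boolean
validity column — never as silent zeros.  The genome-scan driver
:func:`compute_scan` glues the numba EHH kernels, the Weir & Cockerham F_ST,
and the frequency-bin standardization into one per-site table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ehh as _ehh
from .panel import GeneticMapTable, PhasedPanel

__all__ = [
    "ScanParams", "ihs_raw_at_site", "xpehh_raw_at_site",
    "fst_weir_cockerham", "pbs", "standardize_in_freq_bins",
    "compute_scan", "write_scan_table", "read_scan_table",
]


@dataclass
class ScanParams:
    """Tunables of the per-SNP scan.

    maf_haplo : minimum MAF (per analyzed population) for iHS / XP-EHH.
    maf_pbs   : minimum MAF in all three populations for PBS.
    ehh_floor : EHH truncation threshold for iHH integration.
    max_gap   : physical gap (bp) at which an EHH walk is abandoned.
    n_bins / min_bin_count : derived-frequency bins for iHS standardization.
    xpehh_per_bin : standardize XP-EHH within frequency bins instead of
        genome-wide (genome-wide is the default, matching the common tools).
    """

    maf_haplo: float = 0.05
    maf_pbs: float = 0.01
    ehh_floor: float = 0.05
    max_gap: int = 200_000
    n_bins: int = 50
    min_bin_count: int = 20
    xpehh_per_bin: bool = False
    fst_eps: float = 1e-8


# ---------------------------------------------------------------------------
# Single-site haplotype statistics (reference path)
# ---------------------------------------------------------------------------

def ihs_raw_at_site(panel: PhasedPanel, site: int, cm: np.ndarray,
                    params: ScanParams = ScanParams()) -> float:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one site.

    NaN when either allele class has <2 carriers, either decay is truncated
    by an edge/gap before reaching the EHH floor, or an iHH is zero.
    """
    vals = []
    for allele in (0, 1):
        decay = _ehh.ehh_decay(panel, site, allele, cm,
                               params.ehh_floor, params.max_gap)
        if decay is None:
            return np.nan
        ihh, ok = _ehh.integrate_ihh(decay, params.ehh_floor)
        if not ok or ihh <= 0:
            return np.nan
        vals.append(ihh)
    return float(np.log(vals[0] / vals[1]))


def xpehh_raw_at_site(panel_focal: PhasedPanel, panel_ref: PhasedPanel,
                      site: int, cm: np.ndarray,
                      params: ScanParams = ScanParams()) -> float:
    """Unstandardized XP-EHH = ln(iHH_focal / iHH_ref), allele-agnostic cores."""
    vals = []
    for p in (panel_focal, panel_ref):
        decay = _ehh.ehh_decay(p, site, None, cm, params.ehh_floor, params.max_gap)
        if decay is None:
            return np.nan
        ihh, ok = _ehh.integrate_ihh(decay, params.ehh_floor)
        if not ok or ihh <= 0:
            return np.nan
        vals.append(ihh)
    return float(np.log(vals[0] / vals[1]))


# ---------------------------------------------------------------------------
# F_ST and PBS
# ---------------------------------------------------------------------------

def fst_weir_cockerham(n1, p1, n2, p2):
    """Weir & Cockerham (1984) single-SNP theta from haploid allele counts.

    Parameters are haplotype sample sizes and allele-1 frequencies of the two
    populations (scalars or arrays).  Uses the variance-component (a, b)
    form for r=2 samples of haploid data.  NaN where the site is monomorphic
    across both samples (a+b = 0).  The raw estimate may be negative; PBS
    flooring happens in :func:`pbs`.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    r = 2.0
    n_tot = n1 + n2
    nbar = n_tot / r
    nc = (n_tot - (n1 ** 2 + n2 ** 2) / n_tot) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
    a = nbar / nc * (s2 - inner / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * inner
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b != 0.0, a / (a + b), np.nan)
    return theta if theta.ndim else float(theta)


def pbs(fst_f_r1, fst_f_r2, fst_r1_r2, eps: float = 1e-8):
    """Population branch statistic of the focal population.

    PBS = (T_f,r1 + T_f,r2 - T_r1,r2) / 2 with T = -ln(1 - F_ST); F_ST is
    floored at 0 and capped at 1 - eps before the log.  NaN propagates from
    any undefined F_ST.
    """
    def T(f):
        f = np.clip(np.asarray(f, dtype=float), 0.0, 1.0 - eps)
        return -np.log1p(-f)

    out = (T(fst_f_r1) + T(fst_f_r2) - T(fst_r1_r2)) / 2.0
    out = np.where(np.isnan(np.asarray(fst_f_r1, dtype=float))
                   | np.isnan(np.asarray(fst_f_r2, dtype=float))
                   | np.isnan(np.asarray(fst_r1_r2, dtype=float)), np.nan, out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize_in_freq_bins(values: np.ndarray, freqs: np.ndarray,
                             n_bins: int = 50, min_bin_count: int = 20,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Z-standardize ``values`` within equal-width derived-frequency bins.

    Bins with fewer than ``min_bin_count`` valid sites are greedily merged
    with their interior-side neighbor before standardizing.  Returns
    ``(standardized, valid)``; sites in a zero-variance bin (or with NaN
    input) come back NaN / invalid.
    """
    values = np.asarray(values, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    out = np.full_like(values, np.nan)
    ok_in = np.isfinite(values) & np.isfinite(freqs)
    if not ok_in.any():
        return out, np.zeros_like(ok_in)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    raw_bin = np.clip(np.digitize(freqs, edges[1:-1]), 0, n_bins - 1)

    # greedy merge of sparse bins toward the interior
    group = np.arange(n_bins)

    def _root(g):
        while group[g] != g:
            g = group[g]
        return g

    counts = np.bincount(raw_bin[ok_in], minlength=n_bins)
    changed = True
    while changed:
        changed = False
        roots = sorted({_root(g) for g in range(n_bins)})
        eff = {r: sum(counts[g] for g in range(n_bins) if _root(g) == r) for r in roots}
        nonzero = [r for r in roots if eff[r] > 0]
        if len(nonzero) <= 1:
            break
        for i, r in enumerate(nonzero):
            if eff[r] < min_bin_count:
                # merge toward the interior: low bins rightward, high leftward
                target = nonzero[i + 1] if i < len(nonzero) / 2 else nonzero[i - 1]
                group[r] = target
                changed = True
                break

    merged = np.array([_root(b) for b in raw_bin])
    valid = np.zeros_like(ok_in)
    for r in np.unique(merged[ok_in]):
        sel = ok_in & (merged == r)
        mu = values[sel].mean()
        sd = values[sel].std()
        if sd > 0:
            out[sel] = (values[sel] - mu) / sd
            valid[sel] = True
    return out, valid


# ---------------------------------------------------------------------------
# Genome-scan driver
# ---------------------------------------------------------------------------

def compute_scan(focal: PhasedPanel, refs: list[PhasedPanel],
                 gmap: GeneticMapTable, params: ScanParams = ScanParams(),
                 xpehh_ref: int = -1) -> pd.DataFrame:
    """Per-SNP iHS, XP-EHH, pairwise F_ST and PBS for one chromosome.

    ``focal`` and ``refs`` (one or two panels) must share a site list
    (:func:`sweepscan.io.harmonize_panels`) and be polarized.  XP-EHH is
    computed against ``refs[xpehh_ref]`` (default: the last, i.e. most
    diverged, reference); PBS needs exactly two references.

    Returns a DataFrame with one row per shared site: frequencies, raw and
    standardized statistics, and per-statistic validity flags.
    """
    panels = [focal] + list(refs)
    for p in panels[1:]:
        if not np.array_equal(p.positions, focal.positions):
            raise ValueError("panels must share a site list; use harmonize_panels")
    pos = focal.positions
    cm = gmap.interpolate(pos)
    n = pos.size

    freqs = [p.allele_freq() for p in panels]
    ns = [(~p.missing).sum(axis=0).astype(float) for p in panels]
    maf = [np.minimum(f, 1 - f) for f in freqs]

    df = pd.DataFrame({"chrom": focal.chrom, "pos": pos, "cM": cm,
                       "daf_focal": freqs[0]})
    for i, f in enumerate(freqs[1:], start=1):
        df[f"daf_ref{i}"] = f

    # --- iHS ------------------------------------------------------------
    Hf = np.ascontiguousarray(np.where(focal.missing, _ehh.MISSING_CODE,
                                       focal.alleles).astype(np.uint8))
    elig_ihs = maf[0] > params.maf_haplo
    ihh_a, ihh_d, ihs_ok = _ehh.ihs_ihh_all_sites(
        Hf, cm, pos, elig_ihs, params.ehh_floor, params.max_gap)
    with np.errstate(invalid="ignore", divide="ignore"):
        ihs_raw = np.log(ihh_a / ihh_d)
    ihs_std, ihs_std_ok = standardize_in_freq_bins(
        np.where(ihs_ok, ihs_raw, np.nan), freqs[0],
        params.n_bins, params.min_bin_count)
    df["ihh_a"], df["ihh_d"] = ihh_a, ihh_d
    df["ihs_raw"] = np.where(ihs_ok, ihs_raw, np.nan)
    df["ihs_std"] = ihs_std
    df["ihs_valid"] = ihs_ok & ihs_std_ok

    # --- XP-EHH ---------------------------------------------------------
    ref_idx = (len(panels) - 1) if xpehh_ref == -1 else xpehh_ref + 1
    ref_panel = panels[ref_idx]
    elig_xp = (maf[0] > params.maf_haplo) & (maf[ref_idx] > params.maf_haplo)
    Hr = np.ascontiguousarray(np.where(ref_panel.missing, _ehh.MISSING_CODE,
                                       ref_panel.alleles).astype(np.uint8))
    ihh_foc, ok_f = _ehh.pooled_ihh_all_sites(Hf, cm, pos, elig_xp,
                                              params.ehh_floor, params.max_gap)
    ihh_ref, ok_r = _ehh.pooled_ihh_all_sites(Hr, cm, pos, elig_xp,
                                              params.ehh_floor, params.max_gap)
    xp_ok = ok_f & ok_r
    with np.errstate(invalid="ignore", divide="ignore"):
        xp_raw = np.log(ihh_foc / ihh_ref)
    xp_raw = np.where(xp_ok, xp_raw, np.nan)
    if params.xpehh_per_bin:
        xp_std, xp_std_ok = standardize_in_freq_bins(
            xp_raw, freqs[0], params.n_bins, params.min_bin_count)
    else:
        xp_std, xp_std_ok = standardize_in_freq_bins(xp_raw, freqs[0], 1, 1)
    df["xpehh_raw"] = xp_raw
    df["xpehh_std"] = xp_std
    df["xpehh_valid"] = xp_ok & xp_std_ok

    # --- F_ST / PBS ------------------------------------------------------
    if len(refs) == 2:
        f_f1 = fst_weir_cockerham(ns[0], freqs[0], ns[1], freqs[1])
        f_f2 = fst_weir_cockerham(ns[0], freqs[0], ns[2], freqs[2])
        f_12 = fst_weir_cockerham(ns[1], freqs[1], ns[2], freqs[2])
        elig_pbs = (maf[0] > params.maf_pbs) & (maf[1] > params.maf_pbs) \
            & (maf[2] > params.maf_pbs)
        pbs_val = pbs(f_f1, f_f2, f_12, params.fst_eps)
        df["fst_focal_ref1"], df["fst_focal_ref2"], df["fst_ref1_ref2"] = f_f1, f_f2, f_12
        df["pbs"] = np.where(elig_pbs, pbs_val, np.nan)
        df["pbs_valid"] = elig_pbs & np.isfinite(pbs_val)
    return df


def write_scan_table(scan: pd.DataFrame, path: str) -> None:
    """Lossless TSV dump of a scan table."""
    scan.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
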