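"""Extended haplotype homozygosity (EHH) and its integral (iHH).

EHH at a site x, relative to a core SNP and a set of carrier haplotypes, is
the probability that two randomly drawn carriers are identical at every SNP
on the stretch from the core out to x.  iHH is the area under the EHH curve
over genetic distance, integrated outward on both sides down to the point
where EHH crosses a truncation floor (linearly interpolated).

Two code paths compute the same quantity:

* :func:`ehh_decay` / :func:`integrate_ihh` — explicit, per-core NumPy
  implementation returning the full decay profile (used for inspection and
  as the reference in tests);
* the numba kernels :func:`ihs_ihh_all_sites` / :func:`pooled_ihh_all_sites`
  — the genome-scan hot path, which never materializes profiles.

A core is *allele-specific* (carriers of one allele; iHS) or
*allele-agnostic* (all haplotypes of a population start in one group at
EHH=1; the XP-EHH convention).  Haplotypes with a missing call at a visited
site are treated as matching nobody there (identity broken); haplotypes
missing at an allele-specific core are excluded from the carrier set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["EHHDecay", "ehh_decay", "integrate_ihh",
           "ihs_ihh_all_sites", "pooled_ihh_all_sites", "MISSING_CODE"]

#: allele code used internally for missing calls (never equal to 0/1)
MISSING_CODE = 2


@dataclass
class EHHDecay:
    """EHH profile around one core.

    ``offsets`` are signed genetic distances (cM) of the visited sites from
    the core, in left-to-right order and including the core itself (offset 0,
    EHH 1).  A side that stopped for a non-floor reason (chromosome end or a
    physical gap larger than ``max_gap``) has its ``truncated_*`` flag set;
    such sides make the core invalid for iHS/XP-EHH.
    """

    core_site: int
    core_allele: int | None
    offsets: np.ndarray
    ehh_values: np.ndarray
    truncated_left: bool
    truncated_right: bool

    @property
    def valid(self) -> bool:
        return not (self.truncated_left or self.truncated_right)


def _encode(panel) -> np.ndarray:
    """Alleles with missing cells replaced by MISSING_CODE."""
    H = panel.alleles.copy()
    H[panel.missing] = MISSING_CODE
    return np.ascontiguousarray(H)


def _side_profile(H, rows, core, step, cm, pos, floor, max_gap):
    """Walk outward one side; return (site_indices, ehh_values, truncated)."""
    n_sites = H.shape[1]
    k = rows.size
    npairs = k * (k - 1) / 2.0
    labels = np.zeros(k, dtype=np.int64)
    sites, values = [], []
    j = core
    ehh = 1.0
    while ehh >= floor:
        jn = j + step
        if jn < 0 or jn >= n_sites:
            return sites, values, True
        if abs(int(pos[jn]) - int(pos[j])) > max_gap:
            return sites, values, True
        keys = labels * (MISSING_CODE + 2) + H[rows, jn]
        _, labels, counts = np.unique(keys, return_inverse=True, return_counts=True)
        ehh = float((counts * (counts - 1)).sum() / 2.0 / npairs)
        sites.append(jn)
        values.append(ehh)
        j = jn
    return sites, values, False


def ehh_decay(panel, core_site: int, core_allele: int | None,
              cm: np.ndarray, ehh_floor: float = 0.05,
              max_gap: int = 200_000) -> EHHDecay | None:
    """Full EHH decay profile around ``core_site``.

    ``core_allele`` 0/1 selects carriers of that allele (iHS convention);
    ``None`` pools all haplotypes with an allele-agnostic core (XP-EHH
    convention).  ``cm`` is the per-site genetic position.  Returns ``None``
    when fewer than 2 usable carriers exist (undefined statistic).
    """
    H = _encode(panel)
    if core_allele is None:
        rows = np.arange(H.shape[0])  # agnostic core: no call required at the core
    else:
        rows = np.flatnonzero(H[:, core_site] == core_allele)
    if rows.size < 2:
        return None
    pos = panel.positions
    rs, rv, rtrunc = _side_profile(H, rows, core_site, +1, cm, pos, ehh_floor, max_gap)
    ls, lv, ltrunc = _side_profile(H, rows, core_site, -1, cm, pos, ehh_floor, max_gap)
    idx = list(reversed(ls)) + [core_site] + rs
    vals = list(reversed(lv)) + [1.0] + rv
    offsets = cm[np.array(idx, dtype=int)] - cm[core_site]
    return EHHDecay(core_site=core_site, core_allele=core_allele,
                    offsets=offsets, ehh_values=np.array(vals),
                    truncated_left=ltrunc, truncated_right=rtrunc)


def integrate_ihh(decay: EHHDecay, ehh_floor: float = 0.05) -> tuple[float, bool]:
    """Trapezoidal iHH of a decay profile, both sides summed.

    Integration on each side runs to the (linearly interpolated) crossing of
    ``ehh_floor``.  Returns ``(ihh, valid)``; ``valid`` is False when either
    side stopped before reaching the floor (edge/gap truncation).
    """
    core = int(np.argmin(np.abs(decay.offsets)))
    total = 0.0
    for sl in (slice(core, None, 1), slice(core, None, -1)):
        off = np.abs(decay.offsets[sl])
        ehh = decay.ehh_values[sl]
        for t in range(1, len(ehh)):
            d = off[t] - off[t - 1]
            if ehh[t] < ehh_floor:
                if ehh[t - 1] > ehh_floor:
                    frac = (ehh[t - 1] - ehh_floor) / (ehh[t - 1] - ehh[t])
                    total += 0.5 * (ehh[t - 1] + ehh_floor) * frac * d
                break
            total += 0.5 * (ehh[t - 1] + ehh[t]) * d
    return total, decay.valid


# ---------------------------------------------------------------------------
# numba hot path
# ---------------------------------------------------------------------------

@njit(cache=True)
def _walk_ihh(H, rows, core, step, cm, pos, floor, max_gap):  # pragma: no cover
    n_sites = H.shape[1]
    k = rows.size
    npairs = 0.5 * k * (k - 1)
    labels = np.zeros(k, dtype=np.int64)
    keys = np.empty(k, dtype=np.int64)
    # counting-sort scratch over keys = 3*label + allele (allele in {0,1,2})
    counts = np.zeros(3 * k, dtype=np.int64)
    key_map = np.empty(3 * k, dtype=np.int64)
    n_groups = 1
    ihh = 0.0
    ehh_prev = 1.0
    cm_prev = cm[core]
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= n_sites:
            return ihh, False
        gap = pos[jn] - pos[j] if step > 0 else pos[j] - pos[jn]
        if gap > max_gap:
            return ihh, False
        span = 3 * n_groups
        for i in range(k):
            key = labels[i] * 3 + H[rows[i], jn]
            keys[i] = key
            counts[key] += 1
        same = 0.0
        lab = 0
        for key in range(span):
            c = counts[key]
            if c > 0:
                same += 0.5 * c * (c - 1)
                key_map[key] = lab
                lab += 1
                counts[key] = 0
        for i in range(k):
            labels[i] = key_map[keys[i]]
        n_groups = lab
        ehh = same / npairs
        dcm = cm[jn] - cm_prev if step > 0 else cm_prev - cm[jn]
        if ehh < floor:
            if ehh_prev > floor:
                frac = (ehh_prev - floor) / (ehh_prev - ehh)
                ihh += 0.5 * (ehh_prev + floor) * frac * dcm
            return ihh, True
        ihh += 0.5 * (ehh_prev + ehh) * dcm
        ehh_prev = ehh
        cm_prev = cm[jn]
        j = jn


@njit(cache=True)
def ihs_ihh_all_sites(H, cm, pos, eligible, floor, max_gap):  # pragma: no cover
    """Per-site (iHH_ancestral, iHH_derived, valid) over eligible sites.

    H carries codes 0 (ancestral) / 1 (derived) / 2 (missing).  A site is
    valid only when both allele classes have >=2 carriers, both sides of both
    decays reach the EHH floor, and both integrals are positive.
    """
    n_hap, n_sites = H.shape
    ihh_a = np.full(n_sites, np.nan)
    ihh_d = np.full(n_sites, np.nan)
    valid = np.zeros(n_sites, dtype=np.bool_)
    for s in range(n_sites):
        if not eligible[s]:
            continue
        ok = True
        vals = np.empty(2)
        for allele in range(2):
            cnt = 0
            for i in range(n_hap):
                if H[i, s] == allele:
                    cnt += 1
            if cnt < 2:
                ok = False
                break
            rows = np.empty(cnt, dtype=np.int64)
            t = 0
            for i in range(n_hap):
                if H[i, s] == allele:
                    rows[t] = i
                    t += 1
            r_ihh, r_fl = _walk_ihh(H, rows, s, 1, cm, pos, floor, max_gap)
            l_ihh, l_fl = _walk_ihh(H, rows, s, -1, cm, pos, floor, max_gap)
            if not (r_fl and l_fl):
                ok = False
                break
            vals[allele] = r_ihh + l_ihh
        if ok and vals[0] > 0.0 and vals[1] > 0.0:
            ihh_a[s] = vals[0]
            ihh_d[s] = vals[1]
            valid[s] = True
    return ihh_a, ihh_d, valid


@njit(cache=True)
def pooled_ihh_all_sites(H, cm, pos, eligible, floor, max_gap):  # pragma: no cover
    """Allele-agnostic per-site iHH over all haplotypes (XP-EHH kernel)."""
    n_hap, n_sites = H.shape
    rows = np.arange(n_hap)
    ihh = np.full(n_sites, np.nan)
    valid = np.zeros(n_sites, dtype=np.bool_)
    for s in range(n_sites):
        if not eligible[s]:
            continue
        r_ihh, r_fl = _walk_ihh(H, rows, s, 1, cm, pos, floor, max_gap)
        l_ihh, l_fl = _walk_ihh(H, rows, s, -1, cm, pos, floor, max_gap)
        if r_fl and l_fl and r_ihh + l_ihh > 0.0:
            ihh[s] = r_ihh + l_ihh
            valid[s] = True
    return ihh, valid
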