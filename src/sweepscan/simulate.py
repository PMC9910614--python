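"""Forward-time Wright-Fisher simulator and synthetic annotation layers.

The simulator produces exactly the inputs the scan assumes: 2-3 populations
of phased diploid haplotypes descended from a common ancestor (ladder
topology: the last-listed population splits off first), with optional
bottlenecks, symmetric migration, an optional hard sweep in one population,
and known ancestral alleles.  Mutation follows infinite sites on a discrete
bp grid (occupied positions are re-drawn), crossover follows a uniform rate
or a piecewise genetic map, and a rescaled effective size N_e keeps runtimes
at desk scale while preserving theta = 4*N*mu and rho = 4*N*r.

Everything downstream of a seed is deterministic: one
``numpy.random.Generator`` drives reproduction, mutation, migration and
sampling in a fixed order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .panel import GeneticMapTable, PhasedPanel, SiteMask

logger = logging.getLogger("sweepscan")

__all__ = [
    "Bottleneck", "PopulationConfig", "DemographyConfig", "SweepConfig",
    "simulate_panels", "AnnotationBundle", "make_annotations",
    "NeutralFCSNull", "neutral_fcs_null", "power_curve",
    "default_demography",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class Bottleneck:
    """Size reduction active for generations (time - duration, time]."""

    time: int
    size: int
    duration: int


@dataclass
class PopulationConfig:
    name: str
    size: int                       # diploid N after the population exists
    bottleneck: Bottleneck | None = None


@dataclass
class DemographyConfig:
    """Ladder demography for 1-3 populations.

    ``split_times`` (generations before sampling, ascending) has one entry
    per split: with three populations the last one branches off at
    ``split_times[1]`` and the first two separate at ``split_times[0]``.
    Rates are per bp per generation *in rescaled units* (multiply nominal
    rates by 1/rescale_factor when scaling N down by rescale_factor).
    """

    populations: list[PopulationConfig]
    split_times: list[int]
    ancestral_size: int
    sequence_length: int
    mutation_rate: float
    recomb: float | GeneticMapTable = 1e-8
    migration: float = 0.0          # per-gamete prob of an immigrant parent
    internal_size: int | None = None
    burn_in_factor: int = 10
    warm_start: bool = True         # seed the burn-in from a Watterson SFS draw
    rescale_factor: float = 1.0     # bookkeeping only
    founder: tuple[np.ndarray, np.ndarray] | None = None  # (positions, freqs)

    def __post_init__(self) -> None:
        n = len(self.populations)
        if not 1 <= n <= 3:
            raise ValueError("1-3 populations supported")
        if len(self.split_times) != n - 1:
            raise ValueError("need exactly n_pops - 1 split times")
        if any(t <= 0 for t in self.split_times) or \
                list(self.split_times) != sorted(self.split_times):
            raise ValueError("split times must be positive and ascending")
        if self.mutation_rate < 0 or self.migration < 0:
            raise ValueError("rates must be non-negative")

    # -- genetic map helpers ------------------------------------------------
    def genetic_map(self, chrom: str = "chr1") -> GeneticMapTable:
        """The map (rescaled cM) implied by the recombination model."""
        if isinstance(self.recomb, GeneticMapTable):
            return self.recomb
        L = self.sequence_length
        return GeneticMapTable(chrom=chrom, anchor_positions=np.array([0, L]),
                               anchor_cM=np.array([0.0, self.recomb * L * 100.0]))

    def total_morgans(self) -> float:
        gm = self.genetic_map()
        return float(gm.anchor_cM[-1] - gm.anchor_cM[0]) / 100.0

    def sample_breakpoints(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """bp positions of n crossovers, density proportional to the map."""
        gm = self.genetic_map()
        u = rng.random(n) * (gm.anchor_cM[-1] - gm.anchor_cM[0]) + gm.anchor_cM[0]
        return np.interp(u, gm.anchor_cM, gm.anchor_positions.astype(float))


@dataclass
class SweepConfig:
    """A hard sweep: fitness 1 / 1+hs / 1+2s for the derived allele in the
    target population, introduced ``origin_time`` generations before
    sampling (as a new mutation, or at ``start_freq`` as standing variation).
    Replicates are re-run from the injection point until the final
    population frequency lands in [min_final_freq, max_final_freq]; an
    ongoing (partial) sweep is the regime haplotype scans detect best, so
    power studies typically condition on a high-but-unfixed final
    frequency."""

    population: str
    s: float
    position: int
    origin_time: int
    h: float = 0.5
    start_freq: float | None = None
    min_final_freq: float = 0.0
    max_final_freq: float = 1.0
    max_tries: int = 100

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


# ---------------------------------------------------------------------------
# numba splice kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _splice(H_par, parent_idx, start_hap, bp_offsets, bp_cols, out):  # pragma: no cover
    """Copy recombinant offspring haplotypes from a parent matrix.

    Offspring haplotype i descends from diploid parent ``parent_idx[i]``,
    starting on haplotype ``start_hap[i]`` and switching at the (sorted)
    column indices ``bp_cols[bp_offsets[i]:bp_offsets[i+1]]``.
    """
    n_off = parent_idx.size
    L = H_par.shape[1]
    for i in range(n_off):
        p = parent_idx[i]
        a = 2 * p + start_hap[i]
        b = 2 * p + 1 - start_hap[i]
        cur = a
        prev = 0
        for t in range(bp_offsets[i], bp_offsets[i + 1]):
            c = bp_cols[t]
            out[i, prev:c] = H_par[cur, prev:c]
            cur = b if cur == a else a
            prev = c
        out[i, prev:L] = H_par[cur, prev:L]


@njit(cache=True)
def _rebuild(H_src, src_map, out):  # pragma: no cover
    """Gather surviving columns (src_map >= 0) and zero new-mutation columns
    (src_map == -1) in one pass."""
    n_hap = H_src.shape[0]
    S = src_map.size
    for i in range(n_hap):
        for jo in range(S):
            js = src_map[jo]
            out[i, jo] = H_src[i, js] if js >= 0 else np.uint8(0)


# ---------------------------------------------------------------------------
# Simulator core
# ---------------------------------------------------------------------------

class _SimState:
    """Mutable simulator state: shared sorted site registry + per-pop
    haplotype matrices (uint8, 0=ancestral / 1=derived)."""

    def __init__(self, positions, matrices):
        self.positions = positions          # (S,) int64 sorted
        self.H = matrices                   # dict label -> (2N, S) uint8

    def copy(self) -> "_SimState":
        return _SimState(self.positions.copy(),
                         {k: v.copy() for k, v in self.H.items()})


def _reproduce_pop(H_par: np.ndarray, n_dip: int, positions: np.ndarray,
                   demog: DemographyConfig, rng: np.random.Generator,
                   weights: np.ndarray | None) -> np.ndarray:
    n_off_hap = 2 * n_dip
    n_par = H_par.shape[0] // 2
    if weights is None:
        parent_idx = rng.integers(0, n_par, size=n_off_hap)
    else:
        parent_idx = rng.choice(n_par, size=n_off_hap, p=weights)
    start_hap = rng.integers(0, 2, size=n_off_hap).astype(np.int64)
    lam = demog.total_morgans()
    n_cx = rng.poisson(lam, size=n_off_hap)
    offsets = np.zeros(n_off_hap + 1, dtype=np.int64)
    np.cumsum(n_cx, out=offsets[1:])
    bps = demog.sample_breakpoints(int(offsets[-1]), rng)
    cols = np.searchsorted(positions, bps).astype(np.int64)
    # sort breakpoints within each offspring haplotype
    owner = np.repeat(np.arange(n_off_hap), n_cx)
    order = np.lexsort((cols, owner))
    cols = cols[order]
    out = np.empty((n_off_hap, H_par.shape[1]), dtype=np.uint8)
    _splice(H_par, parent_idx.astype(np.int64), start_hap, offsets, cols, out)
    return out


def _sweep_weights(H: np.ndarray, col: int, s: float, h: float) -> np.ndarray:
    g = H[0::2, col].astype(np.int64) + H[1::2, col].astype(np.int64)
    w = 1.0 + np.where(g == 2, 2.0 * s, np.where(g == 1, h * 2.0 * s, 0.0))
    return w / w.sum()


def _in_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    if sorted_arr.size == 0:
        return np.zeros(values.size, dtype=bool)
    idx = np.searchsorted(sorted_arr, values)
    idx = np.minimum(idx, sorted_arr.size - 1)
    return sorted_arr[idx] == values


def _unique_new_positions(n: int, L: int, occupied: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Infinite sites on a discrete grid: re-draw collisions (``occupied``
    must be sorted)."""
    out = np.empty(0, dtype=np.int64)
    need = n
    while need > 0:
        cand = np.unique(rng.integers(0, L, size=need))
        cand = cand[~_in_sorted(cand, occupied)]
        if out.size:
            cand = cand[~_in_sorted(cand, np.sort(out))]
        out = np.concatenate([out, cand])
        need = n - out.size
    return out[:n]


def _sfs_founder(n_hap: int, theta_L: float, L: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Standing variation drawn from the neutral equilibrium SFS
    (E[xi_i] = theta/i) at linkage equilibrium; the burn-in then builds the
    linkage structure forward in time."""
    i = np.arange(1, n_hap)
    a_n = (1.0 / i).sum()
    S0 = rng.poisson(theta_L * a_n)
    S0 = min(S0, L // 2)
    counts = rng.choice(i, size=S0, p=(1.0 / i) / a_n)
    positions = np.sort(_unique_new_positions(S0, L, np.empty(0, np.int64), rng))
    H0 = np.zeros((n_hap, S0), dtype=np.uint8)
    perm = rng.permuted(np.tile(np.arange(n_hap), (S0, 1)), axis=1)
    sel = np.arange(n_hap)[None, :] < counts[:, None]
    H0[perm[sel], np.repeat(np.arange(S0), counts)] = 1
    return positions, H0


def simulate_panels(demog: DemographyConfig, sweep: SweepConfig | None = None,
                    n_haplotypes: int = 100, seed: int | None = None,
                    rng: np.random.Generator | None = None, chrom: str = "chr1",
                    ) -> tuple[dict[str, PhasedPanel], pd.DataFrame]:
    """Run the forward simulation and sample phased panels.

    Returns ``(panels, truth)``: one polarized :class:`PhasedPanel` per
    population (sites segregating in the union of samples, shared site list)
    and a truth table (one row per sweep; empty under neutrality).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = demog.sequence_length
    pops = demog.populations
    names = [p.name for p in pops]
    n_pops = len(pops)
    t_root = (demog.split_times[-1] if demog.split_times else 0)
    t_start = demog.burn_in_factor * demog.ancestral_size + t_root

    # birth time and parent of each population label
    internal = demog.internal_size or demog.ancestral_size
    birth: dict[str, tuple[int, str]] = {}
    root_label = names[0] if n_pops == 1 else "__root__"
    root_size = pops[0].size if n_pops == 1 else demog.ancestral_size
    sizes: dict[str, int] = {root_label: root_size}
    if n_pops == 1:
        pass  # the root itself is the sampled population
    elif n_pops == 2:
        for nm, p in zip(names, pops):
            birth[nm] = (demog.split_times[0], "__root__")
            sizes[nm] = p.size
    else:
        birth["__anc01__"] = (demog.split_times[1], "__root__")
        sizes["__anc01__"] = internal
        birth[names[2]] = (demog.split_times[1], "__root__")
        sizes[names[2]] = pops[2].size
        for nm, p in zip(names[:2], pops[:2]):
            birth[nm] = (demog.split_times[0], "__anc01__")
            sizes[nm] = p.size
    bn = {p.name: p.bottleneck for p in pops}

    def size_at(label: str, g: int) -> int:
        b = bn.get(label)
        if b is not None and b.time - b.duration < g <= b.time:
            return b.size
        return sizes[label]

    if sweep is not None:
        if sweep.population not in names:
            raise ValueError(f"unknown sweep population {sweep.population}")
        if sweep.origin_time >= birth[sweep.population][0]:
            raise ValueError("sweep must originate after its population exists")
        if not 0 <= sweep.position < L:
            raise ValueError("sweep position outside the sequence")

    # --- initial state at t_start (root population only) -----------------
    n_root_hap = 2 * root_size
    if demog.founder is not None:
        fpos, ffreq = demog.founder
        order = np.argsort(fpos)
        fpos = np.asarray(fpos, dtype=np.int64)[order]
        ffreq = np.asarray(ffreq, dtype=float)[order]
        H0 = (rng.random((n_root_hap, fpos.size)) < ffreq).astype(np.uint8)
        state = _SimState(fpos, {root_label: H0})
    elif demog.warm_start and demog.mutation_rate > 0:
        theta_L = 2.0 * n_root_hap * demog.mutation_rate * L
        fpos, H0 = _sfs_founder(n_root_hap, theta_L, L, rng)
        state = _SimState(fpos, {root_label: H0})
    else:
        state = _SimState(np.empty(0, dtype=np.int64),
                          {root_label: np.zeros((n_root_hap, 0), dtype=np.uint8)})

    sweep_active = False
    sweep_checkpoint = None
    just_injected = False
    tries = 0
    mu_L = demog.mutation_rate * L

    g = t_start
    while g > 0:
        g -= 1
        # 1. population set at generation g: a split replaces the parent by
        # its children at the children's birth generation
        # NB: iteration order must be deterministic across processes (it
        # drives RNG consumption), hence the sorted() calls
        plan = []  # (child, parent)
        current = sorted(state.H.keys())
        newly_born = [c for c, (bt, par) in birth.items() if bt == g and par in current]
        for label in current:
            if any(par == label for c, (bt, par) in birth.items() if bt == g):
                continue  # parent replaced by its children
            plan.append((label, label))
        for c in newly_born:
            plan.append((c, birth[c][1]))

        # 2. reproduction (with migration and selection where applicable)
        sweep_col = -1
        if sweep_active:
            sweep_col = int(np.searchsorted(state.positions, sweep.position))
        new_H: dict[str, np.ndarray] = {}
        for child, parent in plan:
            n_dip = size_at(child, g)
            weights = None
            if sweep_active and child == sweep.population and parent in state.H:
                weights = _sweep_weights(state.H[parent], sweep_col, sweep.s, sweep.h)
            if demog.migration > 0 and len(state.H) > 1 and parent in state.H:
                # split offspring gametes between local and immigrant parents
                n_off = 2 * n_dip
                src = np.where(rng.random(n_off) < demog.migration, 1, 0)
                others = [l for l in state.H if l != parent]
                parts = []
                loc_idx = np.flatnonzero(src == 0)
                mig_idx = np.flatnonzero(src == 1)
                out = np.empty((n_off, state.positions.size), dtype=np.uint8)
                if loc_idx.size:
                    out[loc_idx] = _reproduce_pop(
                        state.H[parent], loc_idx.size // 2 + loc_idx.size % 2,
                        state.positions, demog, rng, weights)[:loc_idx.size]
                if mig_idx.size:
                    src_pop = others[int(rng.integers(0, len(others)))]
                    out[mig_idx] = _reproduce_pop(
                        state.H[src_pop], mig_idx.size // 2 + mig_idx.size % 2,
                        state.positions, demog, rng, None)[:mig_idx.size]
                new_H[child] = out
            else:
                new_H[child] = _reproduce_pop(state.H[parent], n_dip,
                                              state.positions, demog, rng, weights)
        state.H = new_H

        # 3. sweep injection
        if sweep is not None and g == sweep.origin_time and not sweep_active:
            col = int(np.searchsorted(state.positions, sweep.position))
            if col == state.positions.size or state.positions[col] != sweep.position:
                state.positions = np.insert(state.positions, col, sweep.position)
                for lbl in state.H:
                    state.H[lbl] = np.insert(state.H[lbl], col, 0, axis=1)
            else:
                for lbl in state.H:
                    state.H[lbl][:, col] = 0
            Ht = state.H[sweep.population]
            n_hap = Ht.shape[0]
            k = 1 if sweep.start_freq is None else max(1, round(sweep.start_freq * n_hap))
            carriers = rng.choice(n_hap, size=k, replace=False)
            Ht[carriers, col] = 1
            sweep_active = True
            just_injected = True

        # 4+5. mutation and pruning of globally fixed/lost sites, as one
        # rebuild per generation
        total_hap = sum(h.shape[0] for h in state.H.values())
        n_mut = rng.poisson(mu_L * total_hap) if mu_L > 0 else 0
        keep = None
        if state.positions.size:
            totals = np.zeros(state.positions.size, dtype=np.int64)
            for h in state.H.values():
                totals += h.sum(axis=0, dtype=np.int64)
            keep = (totals > 0) & (totals < total_hap)
            if sweep_active:
                keep[np.searchsorted(state.positions, sweep.position)] = True
            if keep.all():
                keep = None
        if n_mut > 0 or keep is not None:
            old_idx = np.arange(state.positions.size) if keep is None \
                else np.flatnonzero(keep)
            old_pos = state.positions[old_idx]
            if n_mut > 0:
                new_pos = np.sort(_unique_new_positions(n_mut, L,
                                                        state.positions, rng))
                hap_owner = rng.integers(0, total_hap, size=n_mut)
                ins = np.searchsorted(old_pos, new_pos)
                merged = np.insert(old_pos, ins, new_pos)
                new_cols = ins + np.arange(n_mut)
                src_map = np.full(merged.size, -1, dtype=np.int64)
                old_mask = np.ones(merged.size, dtype=bool)
                old_mask[new_cols] = False
                src_map[old_mask] = old_idx
            else:
                merged = old_pos
                src_map = old_idx
            state.positions = merged
            offset = 0
            for lbl in list(state.H.keys()):
                Hs = state.H[lbl]
                n_hap = Hs.shape[0]
                out = np.empty((n_hap, merged.size), dtype=np.uint8)
                _rebuild(Hs, src_map, out)
                if n_mut > 0:
                    sel = (hap_owner >= offset) & (hap_owner < offset + n_hap)
                    out[hap_owner[sel] - offset, new_cols[sel]] = 1
                state.H[lbl] = out
                offset += n_hap

        # checkpoint the completed injection generation for conditioning retries
        if just_injected:
            sweep_checkpoint = (g, state.copy())
            just_injected = False

        # 6. sweep conditioning at sampling time
        if g == 0 and sweep is not None and \
                (sweep.min_final_freq > 0 or sweep.max_final_freq < 1):
            col = int(np.searchsorted(state.positions, sweep.position))
            hit = (col < state.positions.size
                   and state.positions[col] == sweep.position)
            freq = state.H[sweep.population][:, col].mean() if hit else 0.0
            if not sweep.min_final_freq <= freq <= sweep.max_final_freq:
                tries += 1
                if tries >= sweep.max_tries:
                    raise RuntimeError(
                        f"sweep failed to reach {sweep.min_final_freq} in "
                        f"{sweep.max_tries} tries")
                g, state = sweep_checkpoint
                state = state.copy()
                continue

    # --- sampling ---------------------------------------------------------
    panels: dict[str, PhasedPanel] = {}
    sampled_rows = {}
    for nm in names:
        Hl = state.H[nm]
        n_dip = Hl.shape[0] // 2
        take = rng.choice(n_dip, size=n_haplotypes // 2, replace=False)
        rows = np.sort(np.concatenate([2 * take, 2 * take + 1]))
        sampled_rows[nm] = Hl[rows]
    seg = sum(h.sum(axis=0, dtype=np.int64) for h in sampled_rows.values())
    tot = sum(h.shape[0] for h in sampled_rows.values())
    keep = (seg > 0) & (seg < tot)
    positions = state.positions[keep]
    anc = rng.integers(0, 4, size=positions.size)
    der = (anc + rng.integers(1, 4, size=positions.size)) % 4
    for nm in names:
        sub = np.ascontiguousarray(sampled_rows[nm][:, keep])
        panels[nm] = PhasedPanel(
            chrom=chrom, positions=positions, alleles=sub,
            haplotype_ids=[f"{nm}_{i}|{k}" for i in range(n_haplotypes // 2)
                           for k in (0, 1)],
            population=nm, ref=_BASES[anc], alt=_BASES[der], polarized=True)

    truth_rows = []
    if sweep is not None:
        col = int(np.searchsorted(positions, sweep.position))
        hit = col < positions.size and positions[col] == sweep.position
        final = panels[sweep.population].alleles[:, col].mean() if hit else \
            (1.0 if _fixed_in(state, sweep) else 0.0)
        truth_rows.append({"position": sweep.position, "s": sweep.s,
                           "h": sweep.h, "population": sweep.population,
                           "final_freq": float(final), "tries": tries + 1})
    truth = pd.DataFrame(truth_rows,
                         columns=["position", "s", "h", "population",
                                  "final_freq", "tries"])
    return panels, truth


def _fixed_in(state: _SimState, sweep: SweepConfig) -> bool:
    col = int(np.searchsorted(state.positions, sweep.position))
    if col < state.positions.size and state.positions[col] == sweep.position:
        return bool(state.H[sweep.population][:, col].all())
    return False


def default_demography(sequence_length: int = 5_000_000,
                       n_pops: int = 3) -> DemographyConfig:
    """Desk-scale study conditions: a focal population with a founding
    bottleneck, a closely related reference, and a diverged reference.

    Sizes and times are rescaled (factor ~0.01 of human-like values); the
    per-generation mutation and recombination rates are scaled up by the
    inverse factor so that theta and rho per bp stay realistic
    (theta ~ 3e-4/bp, ~1 cM/Mb nominal).
    """
    pops = [
        PopulationConfig("focal", 100, bottleneck=Bottleneck(time=30, size=50,
                                                             duration=10)),
        PopulationConfig("ref1", 100),
        PopulationConfig("ref2", 100),
    ][:n_pops]
    split_times = [30, 50][:n_pops - 1]
    return DemographyConfig(
        populations=pops,
        split_times=split_times,
        ancestral_size=80,
        internal_size=80,
        sequence_length=sequence_length,
        mutation_rate=1.4e-6,    # rescaled: theta/bp = 4*N_anc*mu ~ 4.5e-4
        recomb=1.34e-6,          # rescaled: rho/bp = 4*N*r ~ 5e-4, human-like
        burn_in_factor=4,        # warm start seeds the SFS; 4N builds the LD
        rescale_factor=0.01,
    )


# ---------------------------------------------------------------------------
# Annotation layers
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    conserved: SiteMask
    genes: pd.DataFrame
    recomb_map: GeneticMapTable
    gwas: dict[str, pd.DataFrame]         # trait -> (chrom, pos, p)
    virus_genes: dict[str, list[str]]     # virus -> gene ids


def make_annotations(sequence_length: int, seed: int | None = None,
                     chrom: str = "chr1",
                     conserved_density: float = 0.05,
                     conserved_mean_len: int = 500,
                     n_genes: int = 80,
                     gene_len_range: tuple[int, int] = (5_000, 40_000),
                     recomb_cM_per_Mb: float = 1.0,
                     recomb_segment: int = 100_000,
                     recomb_log_sd: float = 0.8,
                     n_null_traits: int = 5,
                     hits_per_trait: int = 20,
                     n_virus: int = 2,
                     genes_per_virus: int = 8,
                     positive_windows: pd.DataFrame | None = None,
                     rng: np.random.Generator | None = None,
                     ) -> AnnotationBundle:
    """Synthetic annotation layers for the polygenic test.

    Conserved elements follow a Poisson interval process with exponential
    lengths; genes are non-overlapping stranded intervals; the recombination
    map is piecewise constant with log-normal hot/cold segments; GWAS hits
    of null traits are uniform over the sequence, while an optional
    ``positive_windows`` table (chrom/start/end) receives the hits of one
    positive-control trait named ``"positive"``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = sequence_length

    # conserved elements
    intervals = []
    if conserved_density > 0:
        n_el = rng.poisson(conserved_density * L / conserved_mean_len)
        starts = np.sort(rng.integers(0, L, size=n_el))
        lens = np.maximum(1, rng.exponential(conserved_mean_len, size=n_el)).astype(int)
        intervals = [(chrom, int(s), int(min(s + l, L)))
                     for s, l in zip(starts, lens)]
    conserved = SiteMask(pd.DataFrame(intervals or [],
                                      columns=["chrom", "start", "end"])
                         if intervals else
                         pd.DataFrame(columns=["chrom", "start", "end"]),
                         label="conserved_elements")

    # genes: non-overlapping via rejection on sorted starts
    starts = np.sort(rng.choice(L, size=min(3 * n_genes, L // 2), replace=False))
    genes_rows = []
    prev_end = -1
    for s in starts:
        if len(genes_rows) >= n_genes:
            break
        glen = int(rng.integers(gene_len_range[0], gene_len_range[1]))
        if s <= prev_end or s + glen > L:
            continue
        genes_rows.append((f"G{len(genes_rows):04d}", chrom, int(s), int(s + glen),
                           "+" if rng.random() < 0.5 else "-"))
        prev_end = s + glen
    genes = pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "start",
                                              "end", "strand"])

    # piecewise recombination map with hot/cold segments
    edges = np.arange(0, L + recomb_segment, recomb_segment)
    edges[-1] = L
    rates = recomb_cM_per_Mb * np.exp(
        rng.normal(0.0, recomb_log_sd, size=edges.size - 1)
        - recomb_log_sd ** 2 / 2)
    cM = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges) / 1e6)])
    recomb_map = GeneticMapTable(chrom=chrom, anchor_positions=edges, anchor_cM=cM)

    # GWAS hit tables
    gwas = {}
    for t in range(n_null_traits):
        pos = rng.integers(0, L, size=hits_per_trait)
        gwas[f"null_trait_{t}"] = pd.DataFrame(
            {"chrom": chrom, "pos": np.sort(pos),
             "p": 10.0 ** rng.uniform(-12, -8.5, size=hits_per_trait)})
    if positive_windows is not None and len(positive_windows):
        pos = []
        for _, w in positive_windows.iterrows():
            pos.append(int(rng.integers(w["start"], w["end"])))
        gwas["positive"] = pd.DataFrame(
            {"chrom": chrom, "pos": sorted(pos),
             "p": 10.0 ** rng.uniform(-12, -8.5, size=len(pos))})

    virus = {}
    if len(genes) and n_virus > 0:
        for v in range(n_virus):
            k = min(genes_per_virus, len(genes))
            virus[f"virus_{v}"] = sorted(
                rng.choice(genes["gene_id"].to_numpy(), size=k, replace=False))
    return AnnotationBundle(conserved=conserved, genes=genes,
                            recomb_map=recomb_map, gwas=gwas,
                            virus_genes=virus)


# ---------------------------------------------------------------------------
# Neutral FCS null and power
# ---------------------------------------------------------------------------

@dataclass
class NeutralFCSNull:
    """Pooled per-site FCS values from neutral replicates.

    ``percentile`` places a query median-FCS in the pooled distribution;
    ``percentile_spread`` gives the mean +/- SD of the per-replicate
    percentiles (how consistently the replicates rank the query).
    """

    pooled: np.ndarray
    per_replicate: list[np.ndarray]
    low_precision: bool = False
    tables: list[pd.DataFrame] | None = None  # per-replicate FCS tables

    def window_median_pool(self, window_size: int = 50_000,
                           min_window_snps: int = 10) -> np.ndarray:
        """Null distribution of 50-kb window median FCS across replicates
        (requires the null to have been built with ``keep_tables``).  Query
        *medians* should be ranked against this pool — a window median is a
        much tighter statistic than a single site's FCS."""
        if self.tables is None:
            raise ValueError("null was built without keep_tables=True")
        meds = []
        for tab in self.tables:
            pos = tab["pos"].to_numpy()
            vals = tab["fcs"].to_numpy()
            win = pos // window_size
            for w in np.unique(win):
                sel = vals[win == w]
                if sel.size >= min_window_snps:
                    meds.append(np.median(sel))
        return np.asarray(meds)

    def percentile(self, value: float) -> float:
        return 100.0 * float(np.mean(self.pooled < value))

    def percentile_spread(self, value: float) -> tuple[float, float]:
        per = np.array([100.0 * float(np.mean(r < value))
                        for r in self.per_replicate])
        return float(per.mean()), float(per.std())


def neutral_fcs_null(demog: DemographyConfig, n_replicates: int = 100,
                     n_haplotypes: int = 100, seed: int | None = None,
                     scan_params=None, fcs_params=None,
                     max_retries: int = 3,
                     keep_tables: bool = False) -> NeutralFCSNull:
    """Simulate neutral replicates, run the full scan + FCS pipeline on
    each, and pool the per-site FCS values into a null distribution."""
    from .stats import ScanParams, compute_scan
    from .windows import FCSParams, ranks_to_fcs

    scan_params = scan_params or ScanParams()
    fcs_params = fcs_params or FCSParams()
    rng = np.random.default_rng(seed)
    per_rep = []
    tables = []
    r = 0
    while len(per_rep) < n_replicates:
        r += 1
        if r > n_replicates + max_retries * max(1, n_replicates // 10):
            raise RuntimeError("too many failed neutral replicates")
        panels, _ = simulate_panels(demog, sweep=None,
                                    n_haplotypes=n_haplotypes, rng=rng)
        names = [p.name for p in demog.populations]
        try:
            scan = compute_scan(panels[names[0]],
                                [panels[n] for n in names[1:]],
                                demog.genetic_map(), scan_params)
            fcs = ranks_to_fcs(scan, fcs_params)
        except ValueError:
            logger.warning("neutral replicate without valid FCS sites; retried")
            continue
        vals = fcs["fcs"].to_numpy()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("neutral replicate without valid FCS sites; retried")
            continue
        per_rep.append(vals)
        if keep_tables:
            tables.append(fcs[["chrom", "pos", "fcs"]])
    return NeutralFCSNull(pooled=np.concatenate(per_rep),
                          per_replicate=per_rep,
                          low_precision=n_replicates < 10,
                          tables=tables if keep_tables else None)


def power_curve(s_values, demog: DemographyConfig, n_replicates: int = 50,
                n_haplotypes: int = 100, seed: int | None = None,
                sweep_template: SweepConfig | None = None,
                scan_params=None, fcs_params=None, call_params=None,
                window_size: int = 50_000) -> pd.DataFrame:
    """Fraction of replicates in which the implanted sweep's window falls in
    a called candidate region, per selection coefficient and approach.

    ``s = 0`` rows are neutral (detection rate estimates the false-positive
    window rate).  Wilson 95% intervals are reported per cell.
    """
    from scipy.stats import norm

    from .stats import ScanParams, compute_scan
    from .windows import (FCSParams, WindowCallParams, call_outlier_windows,
                          collapse_regions, ranks_to_fcs, tile_windows)

    scan_params = scan_params or ScanParams()
    fcs_params = fcs_params or FCSParams()
    call_params = call_params or WindowCallParams()
    rng = np.random.default_rng(seed)
    names = [p.name for p in demog.populations]
    L = demog.sequence_length
    if sweep_template is None:
        sweep_template = SweepConfig(population=names[0], s=0.0,
                                     position=L // 2,
                                     origin_time=demog.split_times[0] - 1
                                     if demog.split_times else 50,
                                     min_final_freq=0.7)
    rows = []
    for s in s_values:
        detected = {"A": 0, "B": 0, "union": 0}
        n_ok = 0
        for _ in range(n_replicates):
            sw = None
            if s > 0:
                sw = SweepConfig(population=sweep_template.population, s=float(s),
                                 position=sweep_template.position,
                                 origin_time=sweep_template.origin_time,
                                 h=sweep_template.h,
                                 start_freq=sweep_template.start_freq,
                                 min_final_freq=sweep_template.min_final_freq,
                                 max_tries=sweep_template.max_tries)
            try:
                panels, truth = simulate_panels(demog, sweep=sw,
                                                n_haplotypes=n_haplotypes, rng=rng)
                scan = compute_scan(panels[names[0]],
                                    [panels[n] for n in names[1:]],
                                    demog.genetic_map(), scan_params)
                fcs = ranks_to_fcs(scan, fcs_params)
            except (ValueError, RuntimeError) as exc:
                logger.warning("power replicate skipped: %s", exc)
                continue
            n_ok += 1
            windows = tile_windows({panels[names[0]].chrom: L}, window_size)
            target = sweep_template.position
            for approach in ("A", "B", "union"):
                called = call_outlier_windows(windows, fcs, approach, call_params)
                regions = collapse_regions(called)
                inside = ((regions["start"] <= target)
                          & (regions["end"] > target)).any() if len(regions) else False
                detected[approach] += int(inside)
        z = norm.ppf(0.975)
        for approach in ("A", "B", "union"):
            k, n = detected[approach], max(n_ok, 1)
            p = k / n
            denom = 1 + z ** 2 / n
            center = (p + z ** 2 / (2 * n)) / denom
            half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
            rows.append({"s": s, "approach": approach, "n_replicates": n_ok,
                         "n_detected": k, "rate": p,
                         "ci_low": max(0.0, center - half),
                         "ci_high": min(1.0, center + half)})
    return pd.DataFrame(rows)
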