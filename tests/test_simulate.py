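"""Forward Wright-Fisher simulator: determinism, neutral expectations,
sweeps, annotation layers, and an independent coalescent cross-check."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import io as gio
from sweepscan.simulate import (Bottleneck, DemographyConfig,
                                PopulationConfig, SweepConfig,
                                default_demography, make_annotations,
                                neutral_fcs_null, simulate_panels)


def one_pop(n=40, L=200_000, mu=2e-6, r=1e-6, **kw):
    return DemographyConfig(
        populations=[PopulationConfig("pop", n)], split_times=[],
        ancestral_size=n, sequence_length=L, mutation_rate=mu, recomb=r, **kw)


def two_pop(split, n=40, L=200_000, mu=2e-6, r=1e-6, **kw):
    return DemographyConfig(
        populations=[PopulationConfig("a", n), PopulationConfig("b", n)],
        split_times=[split], ancestral_size=n, sequence_length=L,
        mutation_rate=mu, recomb=r, **kw)


class TestDeterminismAndInvariants:
    def test_fixed_seed_identical_panels(self):
        d = one_pop()
        p1, t1 = simulate_panels(d, seed=42, n_haplotypes=20)
        p2, t2 = simulate_panels(d, seed=42, n_haplotypes=20)
        np.testing.assert_array_equal(p1["pop"].alleles, p2["pop"].alleles)
        np.testing.assert_array_equal(p1["pop"].positions, p2["pop"].positions)
        pd.testing.assert_frame_equal(t1, t2)

    def test_panels_satisfy_invariants(self):
        d = default_demography(300_000)
        panels, _ = simulate_panels(d, seed=1, n_haplotypes=30)
        shared = None
        for p in panels.values():
            assert np.all(np.diff(p.positions) > 0)
            assert set(np.unique(p.alleles)) <= {0, 1}
            assert p.n_haplotypes % 2 == 0
            shared = p.positions if shared is None else shared
            np.testing.assert_array_equal(p.positions, shared)
        # union of samples is segregating at every emitted site
        total = sum(p.alleles.sum(axis=0) for p in panels.values())
        n_hap = sum(p.n_haplotypes for p in panels.values())
        assert total.min() > 0 and total.max() < n_hap

    def test_vcf_round_trip(self, tmp_path):
        d = default_demography(200_000)
        panels, _ = simulate_panels(d, seed=3, n_haplotypes=20)
        path = tmp_path / "sim.vcf"
        plist = list(panels.values())
        gio.write_phased_vcf(plist, str(path))
        for p in plist:
            samples = [h.rsplit("|", 1)[0] for h in p.haplotype_ids[::2]]
            back = gio.read_phased_vcf(str(path), samples, p.population)
            np.testing.assert_array_equal(back.positions, p.positions)
            np.testing.assert_array_equal(back.alleles, p.alleles)


class TestNeutralExpectations:
    def test_allele_frequency_martingale(self):
        """With no mutation, Wright-Fisher drift is a martingale: starting
        founder sites at frequency 0.5, the mean final frequency pooled over
        replicates stays at 0.5 (fixation and loss are symmetric at 0.5, so
        conditioning on the emitted, still-segregating sites is unbiased)."""
        founder_pos = np.arange(12) * 1000 + 500
        d = one_pop(n=20, L=20_000, mu=0.0, r=0.0, burn_in_factor=2,
                    founder=(founder_pos, np.full(12, 0.5)))
        rng = np.random.default_rng(7)
        pooled = []
        for _ in range(120):
            panels, _ = simulate_panels(d, rng=rng, n_haplotypes=40)
            pooled.extend(panels["pop"].allele_freq())
        pooled = np.asarray(pooled)
        se = pooled.std() / np.sqrt(120)  # replicates, not (linked) sites
        assert abs(pooled.mean() - 0.5) < max(3 * se, 0.05)

    def test_sfs_matches_neutral_expectation(self):
        """Site-frequency spectrum of a constant-size neutral population is
        proportional to 1/i within Monte-Carlo error."""
        d = one_pop(n=60, L=400_000, mu=2e-6, r=1e-6)
        rng = np.random.default_rng(5)
        counts = np.zeros(19)
        for _ in range(4):
            panels, _ = simulate_panels(d, rng=rng, n_haplotypes=20)
            c = panels["pop"].alleles.sum(axis=0)
            c = c[(c > 0) & (c < 20)]
            counts += np.bincount(c, minlength=20)[1:20]
        i = np.arange(1, 20)
        expected = (1.0 / i) / (1.0 / i).sum() * counts.sum()
        # chi-square-ish relative deviation on the pooled spectrum
        rel = (counts - expected) / np.sqrt(expected)
        assert np.abs(rel[:10]).mean() < 3.0
        # singletons dominate doubletons roughly 2:1
        assert 1.4 < counts[0] / counts[1] < 2.8

    def test_fst_increases_with_divergence_time(self):
        from sweepscan.stats import fst_weir_cockerham
        rng = np.random.default_rng(9)
        means = []
        for split in (5, 20, 60):
            vals = []
            for _ in range(3):
                panels, _ = simulate_panels(two_pop(split), rng=rng,
                                            n_haplotypes=30)
                fa, fb = panels["a"].allele_freq(), panels["b"].allele_freq()
                f = fst_weir_cockerham(30, fa, 30, fb)
                vals.append(np.nanmean(np.clip(f, 0, 1)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_rescaling_invariance(self):
        """Halving N while doubling mu, r and halving times preserves the
        per-site F_ST distribution (KS not rejected at alpha=0.01).  The
        invariance is a diffusion-limit property, so the arms use sizes
        (N=60 vs 30) where O(1/N) corrections are small, and the KS runs on
        modest subsamples because linked sites are correlated."""
        from scipy.stats import ks_2samp
        from sweepscan.stats import fst_weir_cockerham
        rng = np.random.default_rng(21)

        def fsts(n, mu, r, split, reps):
            out = []
            for _ in range(reps):
                panels, _ = simulate_panels(
                    two_pop(split, n=n, L=150_000, mu=mu, r=r), rng=rng,
                    n_haplotypes=24)
                f = fst_weir_cockerham(24, panels["a"].allele_freq(),
                                       24, panels["b"].allele_freq())
                out.append(f[np.isfinite(f)])
            return np.concatenate(out)

        a = fsts(60, 2e-6, 1e-6, 30, 4)
        b = fsts(30, 4e-6, 2e-6, 15, 4)
        sub_a = rng.choice(a, size=300, replace=False)
        sub_b = rng.choice(b, size=300, replace=False)
        assert ks_2samp(sub_a, sub_b).pvalue > 0.01


class TestSweeps:
    def test_conditioned_final_frequency(self):
        d = default_demography(300_000)
        sw = SweepConfig("focal", 0.5, 150_000, 20, min_final_freq=0.6,
                         max_final_freq=0.95, max_tries=300)
        panels, truth = simulate_panels(d, sweep=sw, seed=13, n_haplotypes=40)
        assert len(truth) == 1
        assert truth["final_freq"].iloc[0] >= 0.5  # sample freq near pop freq
        assert truth["position"].iloc[0] == 150_000

    def test_neutral_truth_empty(self):
        panels, truth = simulate_panels(one_pop(), seed=2, n_haplotypes=10)
        assert truth.empty

    def test_sweep_elevates_ihs_at_core(self):
        """Across replicates, raw iHS at/near a strong sweep core is negative
        (long derived haplotypes) more often than not."""
        from sweepscan.stats import compute_scan
        d = default_demography(600_000)
        gm = d.genetic_map()
        sw = SweepConfig("focal", 0.4, 300_000, 20, min_final_freq=0.6,
                         max_final_freq=0.9, max_tries=300)
        rng = np.random.default_rng(31)
        signs = []
        for _ in range(6):
            panels, _ = simulate_panels(d, sweep=sw, rng=rng)
            scan = compute_scan(panels["focal"], [panels["ref1"],
                                                  panels["ref2"]], gm)
            # sites whose derived allele rode the sweep: high focal DAF but
            # still rare in the diverged reference
            near = scan[(scan.pos > 270_000) & (scan.pos < 330_000)
                        & scan.ihs_valid & (scan.daf_focal > 0.6)
                        & (scan.daf_ref2 < 0.2)]
            if len(near):
                signs.append(np.median(near["ihs_raw"]))
        assert len(signs) >= 4
        assert np.mean(np.array(signs) < 0) > 0.5

    def test_invalid_sweep_configs(self):
        d = default_demography(300_000)
        with pytest.raises(ValueError):
            simulate_panels(d, sweep=SweepConfig("nope", 0.1, 1000, 10), seed=1)
        with pytest.raises(ValueError):
            simulate_panels(d, sweep=SweepConfig("focal", 0.1, 10**9, 10), seed=1)
        with pytest.raises(ValueError):
            # origin before the focal population exists
            simulate_panels(d, sweep=SweepConfig("focal", 0.1, 1000, 40), seed=1)


class TestAnnotations:
    def test_zero_density_empty_mask(self):
        ann = make_annotations(500_000, seed=1, conserved_density=0.0)
        assert len(ann.conserved.intervals) == 0

    def test_reproducible_under_seed(self):
        a = make_annotations(500_000, seed=7)
        b = make_annotations(500_000, seed=7)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.conserved.intervals, b.conserved.intervals)
        for t in a.gwas:
            pd.testing.assert_frame_equal(a.gwas[t], b.gwas[t])

    def test_genes_non_overlapping_and_map_monotone(self):
        ann = make_annotations(2_000_000, seed=3, n_genes=40)
        g = ann.genes.sort_values("start")
        assert (g["start"].values[1:] >= g["end"].values[:-1]).all()
        assert np.all(np.diff(ann.recomb_map.anchor_cM) >= 0)

    def test_positive_trait_hits_inside_windows(self):
        wins = pd.DataFrame({"chrom": ["chr1"], "start": [100_000],
                             "end": [150_000]})
        ann = make_annotations(1_000_000, seed=5, positive_windows=wins)
        hits = ann.gwas["positive"]
        assert ((hits["pos"] >= 100_000) & (hits["pos"] < 150_000)).all()


class TestNeutralNull:
    def test_single_replicate_flags_low_precision(self):
        d = default_demography(300_000)
        null = neutral_fcs_null(d, n_replicates=1, n_haplotypes=40, seed=3)
        assert null.low_precision
        assert null.percentile(-1.0) == 0.0
        assert null.percentile(1e9) == 100.0


class TestCoalescentCrossCheck:
    def test_diversity_against_msprime(self):
        """Mean pairwise diversity of the forward simulator agrees with an
        independent coalescent simulation at matched theta (within 25%)."""
        import msprime

        n, L, mu = 50, 300_000, 2e-6
        d = one_pop(n=n, L=L, mu=mu, r=1e-6)
        rng = np.random.default_rng(17)
        pis = []
        for _ in range(3):
            panels, _ = simulate_panels(d, rng=rng, n_haplotypes=30)
            a = panels["pop"].alleles
            f = a.mean(axis=0)
            pis.append((2 * f * (1 - f) * 30 / 29).sum() / L)
        ours = np.mean(pis)
        ts_pis = []
        for seed in (1, 2, 3):
            ts = msprime.sim_ancestry(samples=15, population_size=n,
                                      sequence_length=L,
                                      recombination_rate=1e-6,
                                      random_seed=seed)
            ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed)
            ts_pis.append(ts.diversity())
        theirs = np.mean(ts_pis)
        assert ours == pytest.approx(theirs, rel=0.25)
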