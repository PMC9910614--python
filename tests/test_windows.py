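"""FCS combination, window tiling/calling, regions, gene enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sweepscan.windows import (FCSParams, WindowCallParams, annotate_genes,
                               annotate_windows, call_outlier_windows,
                               collapse_regions, enrichment_table,
                               ranks_to_fcs, region_median_fcs, tile_windows,
                               trait_enrichment_hypergeom)


def scan_frame(ihs, xp, pbs_vals):
    n = len(ihs)
    return pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(n) * 1000,
        "ihs_std": ihs, "ihs_valid": np.isfinite(ihs),
        "xpehh_std": xp, "xpehh_valid": np.isfinite(xp),
        "pbs": pbs_vals, "pbs_valid": np.isfinite(pbs_vals),
    })


class TestRanksToFcs:
    def test_top_ranked_everywhere(self, rng):
        n = 99
        ihs = rng.normal(size=n)
        xp = rng.normal(size=n)
        pb = rng.random(n)
        ihs[0], xp[0], pb[0] = 99.0, 99.0, 99.0  # most extreme on all three
        fcs = ranks_to_fcs(scan_frame(ihs, xp, pb))
        assert fcs.loc[fcs["pos"] == 0, "fcs"].iloc[0] == \
            pytest.approx(6 * np.log(100), abs=1e-10)

    def test_median_site(self):
        # 99 sites with symmetric ranks; construct p = 0.5 on all three for
        # the site at the exact median rank
        n = 99
        vals = np.arange(n, dtype=float)
        fcs = ranks_to_fcs(scan_frame(vals - n / 2, vals, vals))
        med = fcs.loc[49]
        # |ihs| direction makes rank 50 ambiguous for ihs; check xp/pbs ranks
        assert med["rank_xpehh"] == 50
        assert med["p_xpehh"] == pytest.approx(0.5)
        assert -2 * 3 * np.log(0.5) == pytest.approx(4.1588, abs=1e-3)

    def test_ties_get_average_rank_and_order_invariance(self, rng):
        n = 40
        ihs = rng.normal(size=n)
        xp = rng.normal(size=n)
        pb = rng.random(n)
        pb[3] = pb[7] = 0.9999  # tie on the extreme end
        frame = scan_frame(ihs, xp, pb)
        base = ranks_to_fcs(frame)
        assert base.loc[3, "rank_pbs"] == base.loc[7, "rank_pbs"] == 1.5
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        out = ranks_to_fcs(shuffled)
        merged = out.merge(base, on="pos", suffixes=("_a", "_b"))
        assert len(merged) == n
        np.testing.assert_allclose(merged["fcs_a"], merged["fcs_b"], atol=1e-10)

    def test_min_stats_drops_partial_sites(self, rng):
        ihs = rng.normal(size=20)
        xp = rng.normal(size=20)
        pb = rng.random(20)
        pb[5] = np.nan
        fcs = ranks_to_fcs(scan_frame(ihs, xp, pb), FCSParams(min_stats=3))
        assert 5000 not in set(fcs["pos"])
        assert len(fcs) == 19

    def test_all_invalid_is_hard_error(self):
        empty = scan_frame(np.full(5, np.nan), np.full(5, np.nan),
                           np.full(5, np.nan))
        with pytest.raises(ValueError):
            ranks_to_fcs(empty)


class TestTileWindows:
    def test_partial_tail(self):
        w = tile_windows({"chr1": 120_000})
        assert len(w) == 3
        assert tuple(w.iloc[-1][["start", "end", "partial"]]) == (100_000, 120_000, True)

    def test_exact_boundary(self):
        w = tile_windows({"chr1": 100_000})
        assert len(w) == 2 and not w["partial"].any()

    def test_halfopen_site_assignment(self):
        w = tile_windows({"chr1": 150_000})
        fcs = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000], "fcs": [1.0]})
        ann = annotate_windows(w, fcs)
        assert ann.loc[1, "n_snps"] == 1 and ann.loc[0, "n_snps"] == 0


class TestCallOutlierWindows:
    def make_fcs(self, rng, n_windows=200, per_window=20):
        pos = np.sort(rng.choice(n_windows * 50_000,
                                 size=n_windows * per_window, replace=False))
        return pd.DataFrame({"chrom": "chr1", "pos": pos,
                             "fcs": rng.chisquare(6, size=pos.size)})

    def test_degenerate_constant_fcs_calls_nothing(self, rng):
        fcs = self.make_fcs(rng)
        fcs["fcs"] = 5.0
        w = tile_windows({"chr1": 200 * 50_000})
        called = call_outlier_windows(w, fcs, "union")
        assert called.empty

    def test_loaded_window_called_by_both(self, rng):
        fcs = self.make_fcs(rng, n_windows=500)
        top = fcs.nlargest(50, "fcs").index
        # move the 50 highest-FCS sites into one window
        fcs.loc[top, "pos"] = np.arange(50) * 900 + 123 * 50_000 + 100
        fcs = fcs.sort_values("pos").reset_index(drop=True)
        w = tile_windows({"chr1": 500 * 50_000})
        called = call_outlier_windows(w, fcs, "union")
        hit = called[(called["start"] == 123 * 50_000)]
        assert len(hit) == 1
        assert bool(hit["called_A"].iloc[0]) and bool(hit["called_B"].iloc[0])

    def test_union_superset(self, rng):
        fcs = self.make_fcs(rng)
        w = tile_windows({"chr1": 200 * 50_000})
        a = call_outlier_windows(w, fcs, "A")
        b = call_outlier_windows(w, fcs, "B")
        u = call_outlier_windows(w, fcs, "union")
        su = set(u["start"])
        assert set(a["start"]) <= su and set(b["start"]) <= su


class TestCollapseRegions:
    def test_bookended_merge(self):
        w = pd.DataFrame({"chrom": "chr1",
                          "start": [0, 50_000, 200_000],
                          "end": [50_000, 100_000, 250_000]})
        r = collapse_regions(w, merge_adjacent=True)
        assert len(r) == 2
        assert tuple(r.iloc[0][["start", "end"]]) == (0, 100_000)

    def test_no_adjacent_merge_flag(self):
        w = pd.DataFrame({"chrom": "chr1",
                          "start": [0, 50_000, 200_000],
                          "end": [50_000, 100_000, 250_000]})
        assert len(collapse_regions(w, merge_adjacent=False)) == 3

    def test_idempotent(self, rng):
        starts = np.sort(rng.choice(100, size=20, replace=False)) * 50_000
        w = pd.DataFrame({"chrom": "chr1", "start": starts,
                          "end": starts + 50_000})
        once = collapse_regions(w)
        twice = collapse_regions(once)
        pd.testing.assert_frame_equal(
            once[["chrom", "start", "end"]], twice[["chrom", "start", "end"]])


class TestAnnotateGenes:
    GENES = pd.DataFrame({
        "gene_id": ["G1", "G2", "G3"],
        "chrom": "chr1",
        "start": [10_000, 300_000, 301_000],
        "end": [20_000, 310_000, 302_000],
        "strand": ["+", "-", "+"],
    })

    def region(self, start, end):
        return pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})

    def test_overlap(self):
        out = annotate_genes(self.region(0, 50_000), self.GENES)
        assert out["overlapping_genes"].iloc[0] == ["G1"]

    def test_nearby_boundary_inclusive(self):
        genes = pd.DataFrame({"gene_id": ["GX"], "chrom": "chr1",
                              "start": [50_000 + 250_000], "end": [50_000 + 260_000],
                              "strand": ["+"]})
        out = annotate_genes(self.region(0, 50_000), genes)
        assert out["nearby_genes"].iloc[0] == ["GX"]

    def test_past_boundary_excluded(self):
        genes = pd.DataFrame({"gene_id": ["GX"], "chrom": "chr1",
                              "start": [50_000 + 250_001], "end": [50_000 + 260_000],
                              "strand": ["+"]})
        out = annotate_genes(self.region(0, 50_000), genes)
        assert out["nearby_genes"].iloc[0] == []


class TestHypergeom:
    def test_textbook_case(self):
        p = trait_enrichment_hypergeom(20, 5, 10, 5)
        assert p == pytest.approx(252 / 15504, rel=1e-12)

    def test_zero_overlap_is_one(self):
        assert trait_enrichment_hypergeom(20, 5, 10, 0) == pytest.approx(1.0)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            trait_enrichment_hypergeom(10, 5, 4, 5)

    def test_enumeration_oracle(self, rng):
        """Exhaustive enumeration of candidate-gene draws for small
        universes."""
        for _ in range(40):
            universe = int(rng.integers(4, 13))
            trait = int(rng.integers(1, universe + 1))
            cand = int(rng.integers(1, universe + 1))
            overlap = int(rng.integers(0, min(trait, cand) + 1))
            trait_set = set(range(trait))
            total = hits = 0
            for draw in combinations(range(universe), cand):
                total += 1
                hits += len(trait_set & set(draw)) >= overlap
            assert trait_enrichment_hypergeom(universe, cand, trait, overlap) \
                == pytest.approx(hits / total, rel=1e-10)


class TestEnrichmentTable:
    def test_bh_and_min_genes(self):
        counts = pd.DataFrame({
            "trait": ["t1", "t2", "t3"],
            "universe": [100, 100, 100],
            "candidate": [10, 10, 10],
            "trait_genes": [20, 30, 3],
            "overlap": [8, 2, 1],
        })
        out = enrichment_table(counts)
        assert np.isnan(out.loc[2, "p"])  # below min_trait_genes
        assert out.loc[0, "p"] < out.loc[1, "p"]
        assert (out.loc[~out["q"].isna(), "q"] >= out.loc[~out["q"].isna(), "p"] - 1e-12).all()

    def test_fdr_monotone(self, rng):
        counts = pd.DataFrame({
            "trait": [f"t{i}" for i in range(12)],
            "universe": 200, "candidate": 15,
            "trait_genes": rng.integers(7, 40, size=12),
            "overlap": rng.integers(0, 6, size=12),
        })
        strict = enrichment_table(counts, fdr=0.10)["significant"].sum()
        loose = enrichment_table(counts, fdr=0.20)["significant"].sum()
        assert strict <= loose


class TestRegionMedian:
    def test_median_over_member_sites(self):
        fcs = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30, 90],
                            "fcs": [1.0, 3.0, 100.0, 7.0]})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50]})
        out = region_median_fcs(regions, fcs)
        assert out["median_fcs"].iloc[0] == 3.0
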