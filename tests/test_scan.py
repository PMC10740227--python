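"""Scan statistics against naive independent implementations, and the
consensus/merging machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from domsweep import GeneModelSet, Gene, assign_genes, consensus_outliers, fst_window, make_windows, merge_regions, pi_window, rod
from domsweep.scan import SweepScan

from conftest import build_panel, random_panel


# --------------------------------------------------------------------------
# independent oracles

def pi_pairwise_oracle(panel, window, population):
    """Mean pairwise allele difference summed over sites / window length."""
    chrom, start, end = window
    idx = panel.sites_in(chrom, start, end)
    cols = panel.pop_indices(population)
    total = 0.0
    for i in idx:
        alleles = []
        for j in cols:
            d = panel.genotypes[i, j]
            if d != -1:
                alleles += [1] * int(d) + [0] * (2 - int(d))
        n = len(alleles)
        if n < 2:
            continue
        diff = sum(
            1 for a in range(n) for b in range(a + 1, n) if alleles[a] != alleles[b]
        )
        total += diff / (n * (n - 1) / 2)
    return total / (end - start)


def wc_fst_oracle(panel, window):
    """Literal per-site transcription of the Weir-Cockerham (1984)
    two-population estimator, summed ratio-of-sums."""
    chrom, start, end = window
    idx = panel.sites_in(chrom, start, end)
    num = den = 0.0
    r = 2
    for i in idx:
        stats = []
        for pop in ("wild", "dom"):
            g = [panel.genotypes[i, j] for j in panel.pop_indices(pop) if panel.genotypes[i, j] != -1]
            n = len(g)
            if n == 0:
                stats = None
                break
            p = sum(g) / (2 * n)
            het = sum(1 for x in g if x == 1) / n
            stats.append((n, p, het))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        if pbar in (0.0, 1.0) and hbar == 0.0:
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


class TestWindows:
    def test_sliding_window_arithmetic(self):
        w = make_windows({"chr1": 100_000}, 40_000, 10_000)
        assert len(w) == 7
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (0, 40_000)
        assert (w.iloc[-1]["start"], w.iloc[-1]["end"]) == (60_000, 100_000)

    def test_exact_fit_gives_one_window(self):
        assert len(make_windows({"chr1": 40_000}, 40_000, 10_000)) == 1

    def test_step_equals_size_tiles(self):
        w = make_windows({"chr1": 120_000}, 40_000, 40_000)
        assert list(w["start"]) == [0, 40_000, 80_000]

    def test_short_chromosome_warns_and_skips(self):
        with pytest.warns(UserWarning, match="shorter"):
            w = make_windows({"tiny": 30_000}, 40_000, 10_000)
        assert len(w) == 0


class TestPi:
    def test_monomorphic_window_is_zero(self):
        panel = build_panel([[2, 2, 2, 2]] * 5)
        assert pi_window(panel, ("chr1", 0, 100), "wild") == 0.0

    def test_two_diploid_half_frequency_site(self):
        # dosages {0, 2}: p=0.5, n=4 alleles -> 2*0.25*(4/3) = 2/3 per bp
        panel = build_panel([[0, 2, 0, 0]], pos=[1])
        assert pi_window(panel, ("chr1", 0, 1), "wild") == pytest.approx(2 / 3)
        # oracle: 4 differing pairs of 6
        assert pi_pairwise_oracle(panel, ("chr1", 0, 1), "wild") == pytest.approx(2 / 3)

    def test_matches_pairwise_oracle_on_random_panels(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            panel = random_panel(rng, n_sites=50, n_wild=6, n_dom=4, missing_rate=0.1)
            win = ("chr1", 0, 1000)
            for pop in ("wild", "dom"):
                assert pi_window(panel, win, pop) == pytest.approx(
                    pi_pairwise_oracle(panel, win, pop), abs=1e-12
                )


class TestFst:
    def test_fixed_difference_is_one(self):
        panel = build_panel([[0, 0, 2, 2]], pos=[5])
        assert fst_window(panel, ("chr1", 0, 10)) == pytest.approx(1.0)

    def test_identical_populations_non_positive(self):
        panel = build_panel([[0, 1, 0, 1], [1, 2, 1, 2], [0, 2, 0, 2]])
        val = fst_window(panel, ("chr1", 0, 100))
        assert val <= 0  # reported raw, not clamped

    def test_no_usable_site_is_nan(self):
        panel = build_panel([[1, 1, 1, 1]], pos=[500])
        assert math.isnan(fst_window(panel, ("chr1", 0, 100)))

    def test_matches_wc84_oracle_on_random_panels(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            panel = random_panel(
                rng,
                n_sites=int(rng.integers(5, 200)),
                n_wild=int(rng.integers(2, 10)),
                n_dom=int(rng.integers(2, 10)),
                missing_rate=0.1,
            )
            win = ("chr1", 0, 5000)
            assert fst_window(panel, win) == pytest.approx(
                wc_fst_oracle(panel, win), abs=1e-12
            )


class TestRod:
    @pytest.mark.parametrize(
        "pi_w,pi_d,expected",
        [(0.01, 0.01, 0.0), (0.01, 0.0, 1.0), (0.01, 0.005, 0.5)],
    )
    def test_formula(self, pi_w, pi_d, expected):
        assert rod(pi_w, pi_d) == pytest.approx(expected)

    def test_zero_wild_diversity_undefined(self):
        assert math.isnan(rod(0.0, 0.01))


class TestConsensus:
    def _stats(self, fst, rod_, xpclr, n_snps=30):
        n = len(fst)
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 1000,
                "n_snps": n_snps,
                "fst": fst,
                "rod": rod_,
                "xpclr": xpclr,
            }
        )

    def test_single_statistic_not_enough(self):
        rng = np.random.default_rng(3)
        fst = rng.random(100)
        fst[0] = 10.0  # extreme in FST only
        stats = self._stats(fst, rng.random(100), rng.random(100))
        out, _ = consensus_outliers(stats)
        assert 0 not in out.index

    def test_two_statistics_make_outlier(self):
        rng = np.random.default_rng(3)
        fst, rod_, xp = rng.random(100), rng.random(100), rng.random(100)
        fst[0], rod_[0] = 10.0, 10.0
        out, thr = consensus_outliers(self._stats(fst, rod_, xp))
        assert 0 in out.index
        assert thr["fst"] < 10

    def test_low_snp_windows_excluded(self):
        rng = np.random.default_rng(4)
        fst, rod_, xp = rng.random(100), rng.random(100), rng.random(100)
        fst[0], rod_[0], xp[0] = 10, 10, 10
        stats = self._stats(fst, rod_, xp)
        stats.loc[0, "n_snps"] = 20  # "more than 20" is strict
        out, _ = consensus_outliers(stats)
        assert 0 not in out.index

    def test_planted_outliers_match_independent_recomputation(self):
        rng = np.random.default_rng(5)
        n = 1000
        fst, rod_, xp = rng.random(n), rng.random(n), rng.random(n)
        planted = rng.choice(n, 10, replace=False)
        for arr in (fst, rod_, xp):
            arr[planted] = 2.0 + rng.random(10)
        stats = self._stats(fst, rod_, xp)
        out, _ = consensus_outliers(stats)
        # oracle: per-statistic quantile + set intersection counting
        hits = np.zeros(n, dtype=int)
        for arr in (fst, rod_, xp):
            hits += arr > np.quantile(arr, 0.95)
        expected = set(np.flatnonzero(hits >= 2))
        assert set(out.index) == expected
        assert set(planted) <= expected


class TestMergeAndAssign:
    def _windows(self, spans):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(spans),
                "start": [s for s, _ in spans],
                "end": [e for _, e in spans],
                "n_snps": 30,
                "fst": 0.5,
                "rod": 0.5,
                "xpclr": 1.0,
            }
        )

    def test_overlap_merges(self):
        regions = merge_regions(self._windows([(0, 40_000), (10_000, 50_000)]))
        assert len(regions) == 1
        assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (0, 50_000)

    def test_bookended_merges_and_gap_splits(self):
        regions = merge_regions(self._windows([(0, 40_000), (40_000, 80_000), (90_000, 100_000)]))
        assert list(regions["start"]) == [0, 90_000]

    def test_matches_coverage_array_union(self):
        rng = np.random.default_rng(9)
        spans = []
        for _ in range(40):
            s = int(rng.integers(0, 500)) * 100
            spans.append((s, s + int(rng.integers(1, 5)) * 100))
        regions = merge_regions(self._windows(spans))
        cover = np.zeros(100_000, dtype=bool)
        for s, e in spans:
            cover[s:e] = True
        edges = np.diff(cover.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if cover[0]:
            starts = [0] + starts
        if cover[-1]:
            ends = ends + [len(cover)]
        assert list(regions["start"]) == starts
        assert list(regions["end"]) == ends

    def test_gene_overlap_is_half_open(self):
        genes = GeneModelSet(
            [
                Gene("inside", "chr1", 1001, 2000, "+", ((1001, 2000),)),
                Gene("outside", "chr1", 5001, 6000, "+", ((5001, 6000),)),
            ]
        )
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5000]})
        out = assign_genes(regions, genes)
        assert out.iloc[0]["genes"] == ["inside"]
        # gene starting exactly at the region end (0-based 5000) excluded
        assert out.iloc[0]["n_genes"] == 1


class TestSweepScanModel:
    def test_fit_summary_and_regions(self, sweep_scenario):
        cfg, genes, panel, truth = sweep_scenario
        res = SweepScan(
            panel, genes=genes, size=4000, step=800, chrom_lengths={"chr1": cfg.chrom_length}
        ).fit()
        assert {"fst", "rod", "xpclr"} <= set(res.thresholds)
        assert res.n_regions > 0
        assert "sweep regions" in res.summary()
        # every region overlaps a planted interval (precision check, 1 seed)
        for reg in res.regions.itertuples(index=False):
            assert any(
                reg.start < iv[2] and iv[1] < reg.end for iv in truth.sweep_intervals
            )

    def test_xpclr_optional(self, null_scenario):
        cfg, genes, panel, _ = null_scenario
        res = SweepScan(
            panel, size=10_000, step=10_000, chrom_lengths={"chr1": cfg.chrom_length},
            compute_xpclr=False,
        ).fit()
        assert res.window_stats["xpclr"].isna().all()
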