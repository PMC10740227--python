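"""Variant location classification, structure summaries and metaprofiles."""

import numpy as np
import pytest

from domsweep import (
    Gene,
    GeneModelSet,
    allele_frequency_summary,
    classify_location,
    fixed_snp_fraction,
    tss_tts_metaprofile,
)
from domsweep.annotation import CATEGORIES, classify_sites

from conftest import build_panel


@pytest.fixture()
def two_genes():
    return GeneModelSet(
        [
            Gene("gA", "chr1", 5000, 8999, "+", ((5000, 5999), (8000, 8999))),
            Gene("gB", "chr1", 20000, 23999, "-", ((20000, 20999), (23000, 23999))),
        ]
    )


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (4500, "upstream"),     # within 2 kb left of + TSS
            (5500, "exon"),         # inside exon 1
            (6500, "intron"),
            (9500, "downstream"),
            (15000, "intergenic"),  # > 2 kb from both genes
            (24500, "upstream"),    # right of - strand TSS at 23999
            (19500, "downstream"),  # left of - strand TTS at 20000
        ],
    )
    def test_strand_aware_categories(self, two_genes, pos, expected):
        assert classify_location(pos, "chr1", two_genes, flank=2000) == expected

    def test_unknown_chromosome_raises(self, two_genes):
        with pytest.raises(KeyError):
            classify_location(100, "chrX", two_genes)

    def test_gene_body_beats_flank(self):
        # pos inside gB's exon is also within 2 kb of gA's TSS
        genes = GeneModelSet(
            [
                Gene("gA", "chr1", 5000, 8999, "+", ((5000, 8999),)),
                Gene("gB", "chr1", 3000, 4500, "+", ((3000, 4500),)),
            ]
        )
        assert classify_location(4000, "chr1", genes) == "exon"

    def test_flank_overlap_goes_to_nearest_tss(self):
        genes = GeneModelSet(
            [
                Gene("gA", "chr1", 5000, 5999, "+", ((5000, 5999),)),
                Gene("gB", "chr1", 8000, 8999, "+", ((8000, 8999),)),
            ]
        )
        # 6600 is downstream of gA (TSS 5000, 1600 away) and upstream of
        # gB (TSS 8000, 1400 away): nearest TSS wins
        assert classify_location(6600, "chr1", genes) == "upstream"
        # 6400 is nearer gA's TSS -> downstream
        assert classify_location(6400, "chr1", genes) == "downstream"
        # exact tie at 6500 -> lexicographically first gene id (gA)
        assert classify_location(6500, "chr1", genes) == "downstream"

    def test_partition_covers_all_sites(self, two_genes):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(30_000, 200, replace=False)) + 1
        panel = build_panel([[0, 1, 1, 2]] * 200, pos=pos)
        cats = classify_sites(panel, two_genes)
        assert set(cats) <= set(CATEGORIES)
        assert len(cats) == panel.n_sites


class TestAlleleFrequencySummary:
    def test_saturated_dom_frequency(self, two_genes):
        panel = build_panel([[0, 1, 2, 2]] * 3, pos=[4500, 5500, 15000])
        table = allele_frequency_summary(panel, two_genes)
        occupied = table[(table["population"] == "dom") & (table["n_snps"] > 0)]
        assert (occupied["mean_alt_freq"] == 1.0).all()

    def test_counts_match_hand_enumeration(self, two_genes):
        # 5 sites: upstream, exon, intron, downstream, intergenic of gA
        pos = [4500, 5500, 6500, 9500, 15000]
        geno = [
            [0, 2, 1, 1],
            [1, 1, 0, 2],
            [2, 2, 2, 2],
            [0, 0, 1, 1],
            [1, 0, 0, 1],
        ]
        panel = build_panel(geno, pos=pos)
        table = allele_frequency_summary(panel, two_genes).set_index(["category", "population"])
        assert table.loc[("upstream", "wild"), "n_snps"] == 1
        assert table.loc[("upstream", "wild"), "mean_alt_freq"] == pytest.approx(0.5)
        assert table.loc[("exon", "dom"), "mean_alt_freq"] == pytest.approx(0.5)
        assert table.loc[("intron", "wild"), "mean_alt_freq"] == 1.0
        assert table.loc[("intergenic", "dom"), "mean_alt_freq"] == pytest.approx(0.25)

    def test_empty_category_flagged(self, two_genes):
        panel = build_panel([[0, 1, 1, 2]], pos=[15000])  # intergenic only
        table = allele_frequency_summary(panel, two_genes).set_index(["category", "population"])
        assert table.loc[("exon", "wild"), "n_snps"] == 0
        assert np.isnan(table.loc[("exon", "wild"), "mean_alt_freq"])


class TestFixedSnpFraction:
    def test_fixed_definition_per_population(self):
        # site 0: dom all hom-alt (fixed), wild mixed (not fixed)
        panel = build_panel([[0, 1, 2, 2], [0, 0, 0, 0]], pos=[10, 20])
        out = fixed_snp_fraction(panel, [("chr1", 0, 100)])
        assert out.frac_fixed_dom == pytest.approx(1.0)
        assert out.frac_fixed_wild == pytest.approx(0.5)

    def test_fraction_arithmetic(self):
        geno = [[0, 1, 2, 2]] * 3 + [[0, 1, 1, 2]] * 7  # 3 of 10 fixed in dom
        panel = build_panel(geno, pos=np.arange(1, 11) * 10)
        out = fixed_snp_fraction(panel, [("chr1", 0, 200)])
        assert out.frac_fixed_dom == pytest.approx(0.3)
        assert out.n_sites == 10

    def test_no_sites_flagged_undefined(self):
        panel = build_panel([[0, 1, 1, 2]], pos=[10])
        out = fixed_snp_fraction(panel, [("chr1", 5000, 6000)])
        assert out.n_sites == 0 and np.isnan(out.frac_fixed_dom)

    def test_matches_exhaustive_site_loop(self, sweep_scenario):
        _, genes, panel, truth = sweep_scenario
        out = fixed_snp_fraction(panel, truth.sweep_intervals)
        expect = {"wild": 0, "dom": 0}
        n = 0
        seen = set()
        for c, s, e in truth.sweep_intervals:
            for i in range(panel.n_sites):
                if panel.chrom[i] == c and s < panel.pos[i] <= e and i not in seen:
                    seen.add(i)
                    n += 1
                    for pop in ("wild", "dom"):
                        g = [
                            panel.genotypes[i, j]
                            for j in panel.pop_indices(pop)
                            if panel.genotypes[i, j] != -1
                        ]
                        if sum(g) in (0, 2 * len(g)):
                            expect[pop] += 1
        assert out.n_sites == n
        assert out.frac_fixed_wild == pytest.approx(expect["wild"] / n)
        assert out.frac_fixed_dom == pytest.approx(expect["dom"] / n)


class TestMetaProfile:
    def test_snp_near_tss_lands_in_first_upstream_bin(self):
        genes = GeneModelSet([Gene("g", "chr1", 5000, 8999, "+", ((5000, 8999),))])
        panel = build_panel([[0, 1, 1, 2]], pos=[4990])  # TSS-10
        prof = tss_tts_metaprofile(panel, genes, bin_width=30, flank=2010)["TSS"]
        bin_starts = prof.bin_starts
        hit = np.flatnonzero(prof.counts["wild"])
        assert len(hit) == 1
        assert bin_starts[hit[0]] == -30  # offset -10 in [-30, 0)

    def test_minus_strand_mirrors_offset(self):
        genes = GeneModelSet([Gene("g", "chr1", 5000, 8999, "-", ((5000, 8999),))])
        # TSS = 8999; SNP at 9009 is 10 bp genomically right = offset -10
        panel = build_panel([[0, 1, 1, 2]], pos=[9009])
        prof = tss_tts_metaprofile(panel, genes, bin_width=30, flank=2010)["TSS"]
        hit = np.flatnonzero(prof.counts["wild"])
        assert prof.bin_starts[hit[0]] == -30

    def test_bin_width_must_divide(self):
        genes = GeneModelSet([Gene("g", "chr1", 5000, 8999, "+", ((5000, 8999),))])
        panel = build_panel([[0, 1, 1, 2]], pos=[4990])
        with pytest.raises(ValueError, match="divide"):
            tss_tts_metaprofile(panel, genes, bin_width=30, flank=2000)

    def test_matches_bruteforce_per_gene_recount(self, sweep_scenario):
        _, genes, panel, _ = sweep_scenario
        profiles = tss_tts_metaprofile(panel, genes, bin_width=30, flank=2010)
        seg = {}
        for pop in ("wild", "dom"):
            f = panel.alt_freq(pop)
            seg[pop] = (f > 0) & (f < 1)
        for anchor in ("TSS", "TTS"):
            expected = {p: np.zeros(134, dtype=int) for p in ("wild", "dom")}
            for g in list(genes)[:50]:
                a = g.tss if anchor == "TSS" else g.tts
                for i in range(panel.n_sites):
                    off = panel.pos[i] - a if g.strand == "+" else a - panel.pos[i]
                    if -2010 <= off < 2010:
                        b = (off + 2010) // 30
                        for pop in ("wild", "dom"):
                            if seg[pop][i]:
                                expected[pop][b] += 1
            sub = tss_tts_metaprofile(
                panel, GeneModelSet(list(genes)[:50]), bin_width=30, flank=2010
            )[anchor]
            for pop in ("wild", "dom"):
                np.testing.assert_array_equal(sub.counts[pop], expected[pop])

    def test_strand_reflection_invariance(self):
        """Reversing every strand and reflecting coordinates leaves the
        oriented profile unchanged."""
        L = 30_000
        genes = GeneModelSet([Gene("g", "chr1", 5000, 8999, "+", ((5000, 8999),))])
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(3000, 11000), 40, replace=False))
        geno = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        panel = build_panel(geno, pos=pos)
        prof = tss_tts_metaprofile(panel, genes, 30, 2010)["TSS"]

        refl_genes = GeneModelSet(
            [Gene("g", "chr1", L - 8999 + 1, L - 5000 + 1, "-", ((L - 8999 + 1, L - 5000 + 1),))]
        )
        refl_pos = (L - pos + 1)[::-1]
        refl_panel = build_panel(geno[::-1], pos=refl_pos)
        refl_prof = tss_tts_metaprofile(refl_panel, refl_genes, 30, 2010)["TSS"]
        for pop in ("wild", "dom"):
            np.testing.assert_array_equal(prof.counts[pop], refl_prof.counts[pop])
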