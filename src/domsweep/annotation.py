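"""Gene-model-aware variant accounting.

Location classification (upstream / downstream / exon / intron /
intergenic with a 2-kb flank, annotator-style precedence), per-structure
allele-frequency summaries, fixed-SNP fractions, and strand-oriented
TSS/TTS variant-density metaprofiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import GeneModelSet
from .panel import GenotypePanel

__all__ = [
    "CATEGORIES",
    "classify_location",
    "classify_sites",
    "allele_frequency_summary",
    "fixed_snp_fraction",
    "tss_tts_metaprofile",
    "MetaProfile",
]

CATEGORIES = ("upstream", "downstream", "exon", "intron", "intergenic")


def _site_category(pos: int, genes_on_chrom, flank: int) -> str:
    """Category of a single 1-based position.

    Precedence: gene-body categories (exon over intron) beat flank
    categories; among multiple candidate genes the one with the nearest TSS
    wins, ties broken by lexicographically smallest gene id.
    """
    body_hits = []
    flank_hits = []
    p0 = pos - 1  # 0-based
    for g in genes_on_chrom:
        b0, b1 = g.body_interval()
        if b0 <= p0 < b1:
            role = "intron"
            for s, e in g.exons:
                if s <= pos <= e:
                    role = "exon"
                    break
            body_hits.append((abs(pos - g.tss), g.gene_id, role))
            continue
        u0, u1 = g.upstream_interval(flank)
        if u0 <= p0 < u1:
            flank_hits.append((abs(pos - g.tss), g.gene_id, "upstream"))
            continue
        d0, d1 = g.downstream_interval(flank)
        if d0 <= p0 < d1:
            flank_hits.append((abs(pos - g.tss), g.gene_id, "downstream"))
    for hits in (body_hits, flank_hits):
        if hits:
            hits.sort()
            return hits[0][2]
    return "intergenic"


def classify_location(pos: int, chrom: str, genes: GeneModelSet, flank: int = 2000) -> str:
    """Classify one genomic position against the gene models."""
    if chrom not in genes.chroms():
        raise KeyError(f"unknown chromosome {chrom!r}")
    return _site_category(pos, genes.on_chrom(chrom), flank)


def classify_sites(panel: GenotypePanel, genes: GeneModelSet, flank: int = 2000) -> np.ndarray:
    """Category for every panel site (vectorised over chromosomes)."""
    out = np.empty(panel.n_sites, dtype=object)
    for chrom in pd.unique(panel.chrom):
        mask = panel.chrom == chrom
        gl = genes.on_chrom(str(chrom))
        out[mask] = [_site_category(int(p), gl, flank) for p in panel.pos[mask]]
    return out


def allele_frequency_summary(
    panel: GenotypePanel, genes: GeneModelSet, flank: int = 2000
) -> pd.DataFrame:
    """Per (category, population): SNP count and mean alt-allele frequency.

    Frequencies are computed over non-missing alleles; a site enters a
    population's summary whenever at least one genotype is called there.
    Categories with no sites are reported with n_snps = 0 and NaN mean.
    """
    cats = classify_sites(panel, genes, flank)
    rows = []
    for pop in ("wild", "dom"):
        freq = panel.alt_freq(pop)
        for cat in CATEGORIES:
            in_cat = (cats == cat) & ~np.isnan(freq)
            n = int(in_cat.sum())
            rows.append(
                {
                    "category": cat,
                    "population": pop,
                    "n_snps": n,
                    "mean_alt_freq": float(freq[in_cat].mean()) if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FixedFractions:
    frac_fixed_wild: float
    frac_fixed_dom: float
    n_sites: int


def fixed_snp_fraction(panel: GenotypePanel, regions) -> FixedFractions:
    """Fraction of region sites fixed (alt frequency exactly 0 or 1 over
    non-missing alleles) in each population.

    ``regions`` is an iterable of (chrom, start, end) 0-based half-open
    intervals.  With no sites in the regions, fractions are NaN.
    """
    idx = np.unique(np.concatenate([panel.sites_in(c, s, e) for c, s, e in regions])) if regions else np.array([], int)
    if len(idx) == 0:
        return FixedFractions(float("nan"), float("nan"), 0)
    fracs = {}
    for pop in ("wild", "dom"):
        alt, n = panel.allele_counts(pop)
        alt, n = alt[idx], n[idx]
        fixed = (n > 0) & ((alt == 0) | (alt == n))
        fracs[pop] = float(fixed.mean())
    return FixedFractions(fracs["wild"], fracs["dom"], int(len(idx)))


@dataclass
class MetaProfile:
    """Strand-oriented variant-density profile around a gene anchor.

    Offsets are gene-oriented: negative offsets lie 5' (gene-upstream) of
    the anchor for every gene regardless of genomic strand.  ``counts``
    maps population -> per-bin SNP counts; a SNP counts for a population
    when it is segregating there (0 < alt frequency < 1).
    """

    anchor: str  # "TSS" or "TTS"
    bin_width: int
    flank: int
    counts: dict

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_width

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank, self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop, arr in self.counts.items():
            for b, cnt in zip(self.bin_starts, arr):
                rows.append(
                    {
                        "anchor": self.anchor,
                        "offset_bin_start": int(b),
                        "offset_bin_end": int(b + self.bin_width),
                        "population": pop,
                        "count": int(cnt),
                    }
                )
        return pd.DataFrame(rows)


def tss_tts_metaprofile(
    panel: GenotypePanel,
    genes: GeneModelSet,
    bin_width: int = 30,
    flank: int = 2010,
) -> dict[str, MetaProfile]:
    """Summed SNP counts per offset bin around every gene's TSS and TTS.

    For each gene, SNPs within +/- ``flank`` of the anchor are placed into
    strand-oriented offset bins (offset = pos - anchor on +, anchor - pos
    on -); counts are summed over genes per population.  ``bin_width``
    must divide 2*flank.
    """
    if (2 * flank) % bin_width != 0:
        raise ValueError("bin_width must divide 2*flank")
    n_bins = 2 * flank // bin_width
    seg = {}
    for pop in ("wild", "dom"):
        f = panel.alt_freq(pop)
        seg[pop] = (f > 0) & (f < 1)
    profiles = {}
    for anchor in ("TSS", "TTS"):
        counts = {pop: np.zeros(n_bins, dtype=np.int64) for pop in seg}
        for g in genes:
            a = g.tss if anchor == "TSS" else g.tts
            # query one bp wide on each side; the oriented-offset mask below
            # applies the exact [-flank, flank) bounds for either strand
            idx = panel.sites_in(g.chrom, max(0, a - 1 - flank), a + flank)
            if len(idx) == 0:
                continue
            off = panel.pos[idx] - a if g.strand == "+" else a - panel.pos[idx]
            inside = (off >= -flank) & (off < flank)
            bins = ((off[inside] + flank) // bin_width).astype(int)
            for pop, segmask in seg.items():
                np.add.at(counts[pop], bins[segmask[idx[inside]]], 1)
        profiles[anchor] = MetaProfile(anchor, bin_width, flank, counts)
    return profiles
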