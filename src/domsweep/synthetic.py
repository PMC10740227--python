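"""Synthetic two-population domestication panels with known ground truth.

Generates every input the pipeline consumes: gene models on a single
synthetic chromosome, a wild/domestic genotype panel with weak
Balding-Nichols background differentiation and sweeps planted on
designated gene promoters, differential-expression tables enriched for the
planted-selected gene set, and fatty-acid composition tables.  Every
generator is a pure function of its configuration seed.

The analytic panel generator draws genotypes in Hardy-Weinberg proportions
from per-population frequencies and carries no linkage disequilibrium;
LD-bearing panels come from the forward simulator (:mod:`domsweep.wf`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genes import Gene, GeneModelSet
from .lipids import FattyAcidProfile
from .panel import GenotypePanel

__all__ = [
    "ScenarioConfig",
    "TruthSet",
    "generate_gene_models",
    "simulate_panel",
    "generate_de_table",
    "generate_fatty_acid_table",
    "pick_sweep_targets",
    "write_scenario",
]

_BASES = np.array(list("ACGT"), dtype=object)

MIN_GENE_LEN = 500
MIN_SPACER = 300


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic domestication scenario.

    Defaults mirror the resequencing design the pipeline targets: a 1-Mb
    chromosome carrying 300 compact genes, 40 wild + 45 domestic diploid
    samples, ~10 SNPs/kb (the density of the filtered two-population
    resequencing callset), weak genome-wide background differentiation
    (FST ~ 0.05, exposed as a knob since the real panel's value is a
    property of the data, not a constant), and promoter sweeps that pull
    the domestic allele frequency toward fixation with a linear decay over
    ``sweep_halfwidth`` bp.
    """

    chrom_length: int = 1_000_000
    n_genes: int = 300
    n_wild: int = 40
    n_dom: int = 45
    mutation_density: float = 10.0  # expected SNPs per kb (~the filtered resequencing panel)
    sweep_targets: tuple = ()
    sweep_strength: float = 0.8
    sweep_halfwidth: int = 2_500
    de_enrichment: float = 1.0
    de_rate: float = 0.35
    tissues: tuple = ("muscle", "liver", "fat")
    background_fst: float = 0.05
    promoter_flank: int = 2_000
    chrom: str = "chr1"
    seed: int = 0
    gene_seed: int | None = None  # separate stream so panels can vary on fixed genes

    def __post_init__(self):
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.n_wild < 2 or self.n_dom < 2:
            raise ValueError("need at least 2 diploid samples per population")
        if not 0 <= self.sweep_strength <= 1:
            raise ValueError("sweep_strength must lie in [0, 1]")
        if any(t < 0 or t >= self.n_genes for t in self.sweep_targets):
            raise ValueError("sweep_targets must index into [0, n_genes)")
        if self.de_enrichment < 1:
            raise ValueError("de_enrichment must be >= 1")
        if not 0 < self.background_fst < 1:
            raise ValueError("background_fst must lie in (0, 1)")


@dataclass
class TruthSet:
    """Ground truth planted by the generator."""

    sweep_intervals: list  # (chrom, start, end), 0-based half-open
    selected_gene_ids: list
    de_gene_ids: dict = field(default_factory=dict)  # tissue -> list

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        d["sweep_intervals"] = [tuple(x) for x in d["sweep_intervals"]]
        return cls(**d)


def generate_gene_models(config: ScenarioConfig) -> GeneModelSet:
    """Place ``n_genes`` non-overlapping genes with alternating strands.

    The chromosome is divided into equal slots; each gene body (2-8 exons)
    sits inside its slot with a private ``promoter_flank``-bp upstream
    clearance on its promoter side (the body hugs the slot end the TSS
    faces away from), so upstream intervals of neighbouring genes never
    overlap each other or another gene body.
    """
    margin = 1_000
    min_footprint = MIN_GENE_LEN + MIN_SPACER + config.promoter_flank
    needed = config.n_genes * min_footprint + 2 * margin
    if config.chrom_length < needed:
        raise ValueError(
            f"chromosome of {config.chrom_length} bp cannot hold {config.n_genes} genes "
            f"with {config.promoter_flank}-bp promoters; needs at least {needed} bp"
        )
    rng = np.random.default_rng(
        [config.gene_seed if config.gene_seed is not None else config.seed, 101]
    )
    slot = (config.chrom_length - 2 * margin) // config.n_genes
    genes = []
    for i in range(config.n_genes):
        slot_start = margin + i * slot
        max_len = min(2_500, slot - MIN_SPACER - config.promoter_flank)
        body_len = int(rng.integers(MIN_GENE_LEN, max(max_len, MIN_GENE_LEN + 1)))
        free = slot - body_len - MIN_SPACER - config.promoter_flank
        offset = int(rng.integers(0, max(free, 1)))
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            # promoter occupies the left of the slot
            start = slot_start + config.promoter_flank + offset + 1  # 1-based
        else:
            # promoter occupies the right of the slot
            start = slot_start + MIN_SPACER // 2 + offset + 1
        end = start + body_len - 1
        genes.append(
            Gene(
                gene_id=f"g{i:04d}",
                chrom=config.chrom,
                start=start,
                end=end,
                strand=strand,
                exons=_random_exons(rng, start, end),
            )
        )
    return GeneModelSet(genes)


def _random_exons(rng, start, end, max_exons=8):
    length = end - start + 1
    n_ex = int(rng.integers(2, min(max_exons, max(2, length // 120)) + 1))
    n_cuts = 2 * n_ex - 2
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for j in range(0, len(bounds) - 1, 2):
        exons.append((start + int(bounds[j]), start + int(bounds[j + 1]) - 1))
    return tuple(exons)


def _promoter_center(gene: Gene, flank: int) -> int:
    s, e = gene.upstream_interval(flank)
    return (s + e) // 2


def sweep_interval(gene: Gene, config: ScenarioConfig) -> tuple[str, int, int]:
    """Planted interval (0-based half-open) centred on the gene's promoter."""
    c = _promoter_center(gene, config.promoter_flank)
    return (
        gene.chrom,
        max(0, c - config.sweep_halfwidth),
        min(config.chrom_length, c + config.sweep_halfwidth),
    )


def pick_sweep_targets(config: ScenarioConfig, n_targets: int, min_gap_genes: int = 5) -> tuple:
    """Choose well-spaced target gene indices (deterministic for a seed)."""
    rng = np.random.default_rng([config.seed, 202])
    candidates = np.arange(2, config.n_genes - 2)
    chosen: list[int] = []
    rng.shuffle(candidates)
    for c in candidates:
        if all(abs(c - x) >= min_gap_genes for x in chosen):
            chosen.append(int(c))
        if len(chosen) == n_targets:
            break
    if len(chosen) < n_targets:
        raise ValueError("cannot place that many well-spaced sweep targets")
    return tuple(sorted(chosen))


def simulate_panel(config: ScenarioConfig, genes: GeneModelSet) -> tuple[GenotypePanel, TruthSet]:
    """Draw the two-population genotype panel and record planted truth.

    Background: ancestral frequency ~ U(0.05, 0.95); each population's
    frequency is an independent Beta draw with drift parameter
    ``background_fst`` (Balding-Nichols).  Within each planted interval
    the domestic frequency is pulled toward fixation of the
    ancestral-minor allele (the derived, favoured variant) by
    ``sweep_strength`` decaying linearly with distance from the promoter
    centre.  Genotypes are Hardy-Weinberg draws; monomorphic
    sites are never emitted.
    """
    rng = np.random.default_rng([config.seed, 303])
    n_sites = int(round(config.chrom_length * config.mutation_density / 1000.0))
    pos = np.sort(rng.choice(config.chrom_length, size=n_sites, replace=False)) + 1

    p_anc = rng.uniform(0.05, 0.95, n_sites)
    F = config.background_fst
    shape = (1.0 - F) / F
    p_wild = rng.beta(p_anc * shape, (1 - p_anc) * shape)
    p_dom = rng.beta(p_anc * shape, (1 - p_anc) * shape)

    gene_list = list(genes)
    intervals, selected_ids = [], []
    for t in config.sweep_targets:
        g = gene_list[t]
        iv = sweep_interval(g, config)
        intervals.append(iv)
        selected_ids.append(g.gene_id)
        center = (iv[1] + iv[2]) // 2
        dist = np.abs((pos - 1) - center)
        w = config.sweep_strength * np.clip(1.0 - dist / config.sweep_halfwidth, 0.0, None)
        # the favoured (hitchhiking) allele is the ancestral-minor one, as
        # for a derived beneficial variant rising from low frequency
        target = (p_anc <= 0.5).astype(float)
        p_dom = np.where(w > 0, (1 - w) * p_dom + w * target, p_dom)

    _check_truth_consistency(intervals, selected_ids, genes, config.promoter_flank)

    g_wild = rng.binomial(2, p_wild[:, None], size=(n_sites, config.n_wild))
    g_dom = rng.binomial(2, p_dom[:, None], size=(n_sites, config.n_dom))
    geno = np.concatenate([g_wild, g_dom], axis=1).astype(np.int8)
    total = geno.sum(axis=1)
    seg = (total > 0) & (total < 2 * (config.n_wild + config.n_dom))

    ref = _BASES[rng.integers(0, 4, n_sites)]
    shift = rng.integers(1, 4, n_sites)
    alt = _BASES[(np.searchsorted(_BASES, ref.astype(str)) + shift) % 4]

    samples = [f"wild_{i:02d}" for i in range(config.n_wild)] + [
        f"dom_{i:02d}" for i in range(config.n_dom)
    ]
    labels = np.array(["wild"] * config.n_wild + ["dom"] * config.n_dom, dtype=object)
    panel = GenotypePanel(
        chrom=np.full(seg.sum(), config.chrom, dtype=object),
        pos=pos[seg],
        ref=ref[seg],
        alt=alt[seg],
        genotypes=geno[seg],
        samples=samples,
        pop_labels=labels,
    )
    return panel, TruthSet(sweep_intervals=intervals, selected_gene_ids=selected_ids)


def _check_truth_consistency(intervals, selected_ids, genes, flank):
    """Every planted interval must overlap the promoter of exactly one
    selected gene (choose better-spaced targets otherwise)."""
    proms = {g.gene_id: g.upstream_interval(flank) for g in genes}
    sel = set(selected_ids)
    for iv in intervals:
        hits = [
            gid
            for gid in sel
            if proms[gid][0] < iv[2] and iv[1] < proms[gid][1]
        ]
        if len(hits) != 1:
            raise ValueError(
                f"sweep interval {iv} overlaps {len(hits)} selected-gene promoters; "
                "targets are too close together"
            )


def generate_de_table(
    genes: GeneModelSet, truth: TruthSet, config: ScenarioConfig, alpha: float = 0.05
) -> pd.DataFrame:
    """Per gene x tissue (log2FC, padj) rows with DE odds multiplied by
    ``de_enrichment`` for planted-selected genes."""
    rng = np.random.default_rng([config.seed, 404])
    selected = set(truth.selected_gene_ids)
    r = config.de_rate
    base_odds = r / (1 - r)
    p_sel = (config.de_enrichment * base_odds) / (1 + config.de_enrichment * base_odds)
    rows = []
    de_ids: dict[str, list] = {t: [] for t in config.tissues}
    for g in genes:
        for tissue in config.tissues:
            p_de = p_sel if g.gene_id in selected else r
            is_de = rng.random() < p_de
            if is_de:
                padj = rng.uniform(0, alpha)
                lfc = rng.choice([-1.0, 1.0]) * (0.2 + abs(rng.normal(1.5, 0.75)))
                de_ids[tissue].append(g.gene_id)
            else:
                padj = rng.uniform(alpha, 1.0)
                lfc = rng.normal(0.0, 0.3)
            rows.append(
                {
                    "gene": g.gene_id,
                    "tissue": tissue,
                    "stage": "pooled",
                    "log2fc": float(lfc),
                    "padj": float(padj),
                }
            )
    truth.de_gene_ids = de_ids
    return pd.DataFrame(rows)


_SPECIES = {
    # class -> ((fatty acid id, double bonds), ...)
    "SFA": (("C16:0", 0), ("C18:0", 0)),
    "MUFA": (("C16:1", 1), ("C18:1", 1)),
    "PUFA": (("C18:2", 2), ("C18:3", 3)),
}


def generate_fatty_acid_table(
    n_samples: int, class_means: tuple[float, float, float], seed: int = 0, noise_sd: float = 2.0
) -> list[FattyAcidProfile]:
    """Per-sample weight-% fatty-acid profiles around (SFA, MUFA, PUFA)
    class means that must sum to 100."""
    if abs(sum(class_means) - 100.0) > 1e-6:
        raise ValueError("class means must sum to 100")
    rng = np.random.default_rng([seed, 505])
    means = np.asarray(class_means, float)
    profiles = []
    for i in range(n_samples):
        # multiplicative noise keeps absent classes exactly absent
        totals = means * np.exp(rng.normal(0, noise_sd / 50.0, 3))
        totals = totals / totals.sum() * 100.0
        entries = []
        for cls, total in zip(("SFA", "MUFA", "PUFA"), totals):
            species = _SPECIES[cls]
            split = rng.dirichlet(np.ones(len(species)) * 5.0) * total
            for (fa, db), wt in zip(species, split):
                entries.append((fa, float(wt), db))
        profiles.append(FattyAcidProfile(sample_id=f"s{i:02d}", entries=entries))
    return profiles


def write_scenario(config: ScenarioConfig, outdir: str) -> dict:
    """Generate and write a complete scenario directory (VCF, GFF3,
    promoter BED, truth JSON, DE TSV, fatty-acid TSV).  Returns paths."""
    import os

    from .lipids import profiles_to_frame
    from .panel import write_vcf
    from .genes import write_gff3

    os.makedirs(outdir, exist_ok=True)
    genes = generate_gene_models(config)
    panel, truth = simulate_panel(config, genes)
    de = generate_de_table(genes, truth, config)
    fa = generate_fatty_acid_table(12, (38.0, 42.0, 20.0), seed=config.seed)
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "promoters": os.path.join(outdir, "promoters.bed"),
        "truth": os.path.join(outdir, "truth.json"),
        "de": os.path.join(outdir, "de.tsv"),
        "fatty_acids": os.path.join(outdir, "fatty_acids.tsv"),
        "pops": os.path.join(outdir, "pops.tsv"),
    }
    write_vcf(panel, paths["vcf"])
    write_gff3(genes, paths["gff"])
    genes.promoter_bed(config.promoter_flank).to_csv(
        paths["promoters"], sep="\t", header=False, index=False
    )
    truth.to_json(paths["truth"])
    de.to_csv(paths["de"], sep="\t", index=False)
    profiles_to_frame(fa).to_csv(paths["fatty_acids"], sep="\t", index=False)
    pd.DataFrame({"sample": panel.samples, "population": panel.pop_labels}).to_csv(
        paths["pops"], sep="\t", index=False, header=False
    )
    return paths
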