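"""Two-population SNP genotype panels.

The :class:`GenotypePanel` is the central in-memory container of the
package: a matrix of alt-allele dosages (0/1/2, ``-1`` for missing) over
biallelic SNPs for samples labelled ``wild`` (ancestral) or ``dom``
(derived/domesticated).  All scan statistics, annotation summaries and
metaprofiles consume it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "read_vcf", "write_vcf", "apply_site_filters"]

MISSING = -1

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=domsweep
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


@dataclass
class GenotypePanel:
    """Biallelic SNP dosage matrix for a wild/domestic two-population panel.

    Parameters
    ----------
    chrom : array of str, per site
    pos : array of int, 1-based positions, strictly increasing per chrom
    ref, alt : arrays of single-base allele strings
    genotypes : (n_sites, n_samples) int8 array of alt dosages; -1 = missing
    samples : sample identifiers
    pop_labels : per-sample population, each ``"wild"`` or ``"dom"``
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    pop_labels: np.ndarray
    _pop_idx: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (sites x samples) matrix")
        n_sites, n_samples = self.genotypes.shape
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == n_sites):
            raise ValueError("site arrays and genotype matrix disagree on n_sites")
        if len(self.samples) != n_samples or len(self.pop_labels) != n_samples:
            raise ValueError("sample arrays and genotype matrix disagree on n_samples")
        bad = set(self.pop_labels) - {"wild", "dom"}
        if bad:
            raise ValueError(f"unknown population labels: {sorted(bad)}")
        for p in ("wild", "dom"):
            if not np.any(self.pop_labels == p):
                raise ValueError(f"population {p!r} has no samples")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        self._pop_idx = {
            "wild": np.flatnonzero(self.pop_labels == "wild"),
            "dom": np.flatnonzero(self.pop_labels == "dom"),
        }

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def pop_indices(self, population: str) -> np.ndarray:
        try:
            return self._pop_idx[population]
        except KeyError:
            raise KeyError(f"population must be 'wild' or 'dom', got {population!r}")

    def alt_freq(self, population: str | None = None) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing alleles.

        NaN where a population has no called genotype at the site.
        """
        g = self.genotypes if population is None else self.genotypes[:, self.pop_indices(population)]
        called = g != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def allele_counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, total called allele count) per site."""
        g = self.genotypes[:, self.pop_indices(population)]
        called = g != MISSING
        return np.where(called, g, 0).sum(axis=1), 2 * called.sum(axis=1)

    def take_sites(self, index: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            pop_labels=self.pop_labels,
        )

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites with 1-based pos in the 0-based half-open [start, end)."""
        on = self.chrom == chrom
        idx = np.flatnonzero(on)
        p = self.pos[idx]
        lo = np.searchsorted(p, start + 1, side="left")
        hi = np.searchsorted(p, end, side="right")
        return idx[lo:hi]


def apply_site_filters(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    maf_max: float = 0.99,
    max_missing: float = 0.1,
) -> GenotypePanel:
    """Retain sites whose combined-panel MAF lies in the closed interval
    [maf_min, maf_max] and whose missing-genotype fraction is <= max_missing.

    Mirrors the vcftools-style ``--maf/--max-maf/--max-missing`` filter used
    to produce analysis-ready domestication panels.  The interval is closed
    on both ends: a site whose MAF equals a bound is kept.
    """
    if not (0 <= maf_min < maf_max <= 1):
        raise ValueError("need 0 <= maf_min < maf_max <= 1")
    freq = panel.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    missing_frac = (panel.genotypes == MISSING).mean(axis=1)
    keep = (
        ~np.isnan(freq)
        & (maf >= maf_min)
        & (maf <= maf_max)
        & (missing_frac <= max_missing)
    )
    if not keep.any():
        warnings.warn("site filters removed every site", stacklevel=2)
    return panel.take_sites(np.flatnonzero(keep))


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as an uncompressed VCF v4.2 with GT-only records."""
    gt_str = np.array(["0/0", "0/1", "1/1", "./."], dtype=object)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in pd.unique(panel.chrom):
            length = int(panel.pos[panel.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        codes = np.where(panel.genotypes == MISSING, 3, panel.genotypes)
        for i in range(panel.n_sites):
            row = "\t".join(gt_str[codes[i]])
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t.\t{panel.ref[i]}\t"
                f"{panel.alt[i]}\t.\tPASS\t.\tGT\t{row}\n"
            )


def read_vcf(path: str, pops: dict[str, str] | pd.DataFrame) -> GenotypePanel:
    """Read a biallelic-SNP VCF into a :class:`GenotypePanel`.

    Parameters
    ----------
    path : VCF path (plain or bgzipped).
    pops : mapping sample -> population ("wild"/"dom"), or a two-column
        DataFrame (sample, population) as produced by ``--pops pops.tsv``.
    """
    from cyvcf2 import VCF

    if isinstance(pops, pd.DataFrame):
        pops = dict(zip(pops.iloc[:, 0].astype(str), pops.iloc[:, 1].astype(str)))
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    missing_labels = [s for s in samples if s not in pops]
    if missing_labels:
        raise ValueError(f"samples without a population label: {missing_labels[:5]}")
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # biallelic SNPs only
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    vcf.close()
    genotypes = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypePanel(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=genotypes,
        samples=samples,
        pop_labels=np.array([pops[s] for s in samples], dtype=object),
    )
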