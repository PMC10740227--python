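"""Genome-wide selective-sweep scan: windowed pi, Weir-Cockerham FST, ROD,
XP-CLR, top-quantile consensus calling, and merging into sweep regions.

The scan contrasts an ancestral ("wild") against a derived ("dom")
population in sliding windows (40 kb / 10 kb by default).  A window is
called a putative sweep when it falls in the top tail for at least two of
the three statistics; consecutive outlier windows are merged into sweep
regions and annotated with overlapping genes.

FST uses the Weir & Cockerham (1984) variance-component estimator with
ratio-of-sums aggregation over the window: theta_W = sum(a) / sum(a+b+c),
where per site

    a = (nbar/nc) * [s2 - (pbar*qbar - s2/2 - hbar/4) / (nbar-1)]
    b = (nbar/(nbar-1)) * [pbar*qbar - s2/2 - (2*nbar-1)/(4*nbar) * hbar]
    c = hbar/2

with nbar the mean per-population diploid sample size, nc its
size-imbalance correction, pbar the weighted mean allele frequency, s2 the
weighted between-population variance of frequencies and hbar the weighted
observed heterozygosity.  Sites monomorphic across the combined panel
contribute nothing.  Negative window values are reported raw (not clamped)
so that ranking is well defined.

Nucleotide diversity per window is the unbiased per-site heterozygosity
summed over sites and divided by the full window length:

    pi = sum_sites 2*p*(1-p) * n/(n-1) / L

with n the number of called alleles.  ROD = 1 - pi_dom / pi_wild.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "make_windows",
    "pi_window",
    "fst_window",
    "rod",
    "consensus_outliers",
    "merge_regions",
    "assign_genes",
    "SweepScan",
    "SweepScanResult",
]


# ---------------------------------------------------------------------------
# windows

def make_windows(chrom_lengths: dict[str, int], size: int = 40_000, step: int = 10_000) -> pd.DataFrame:
    """Sliding windows (0-based half-open) at offsets 0, step, 2*step, ...

    The final partial window at a chromosome end is dropped, not truncated,
    so per-bp quantities stay comparable across windows.  Chromosomes
    shorter than ``size`` yield no windows (with a warning).
    """
    if not (0 < step <= size):
        raise ValueError("need 0 < step <= size")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < size:
            warnings.warn(f"chromosome {chrom} shorter than window size; skipped", stacklevel=2)
            continue
        starts = np.arange(0, length - size + 1, step, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(s + size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# per-site kernels

def _per_site_pi_terms(panel: GenotypePanel, population: str) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*p*(1-p)*n/(n-1); 0 where n < 2."""
    alt, n = panel.allele_counts(population)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        term = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
    term[n < 2] = 0.0
    return term


def _per_site_wc_components(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) two-population variance components per site.

    Returns (a, a+b+c).  Sites with fewer than one called diploid in either
    population, or with nbar <= 1, are zeroed out (they contribute nothing
    to the ratio of sums).
    """
    comps = []
    for pop in ("wild", "dom"):
        g = panel.genotypes[:, panel.pop_indices(pop)]
        called = g != -1
        n = called.sum(axis=1).astype(float)  # diploid count
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), 0.0)
            h = np.where(n > 0, (g == 1).sum(axis=1) / np.maximum(n, 1), 0.0)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    nsum = n1 + n2
    nbar = nsum / 2.0
    valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = nsum - (n1**2 + n2**2) / np.maximum(nsum, 1)
        pbar = (n1 * p1 + n2 * p2) / np.maximum(nsum, 1)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / np.maximum(nbar, 1)
        hbar = (n1 * h1 + n2 * h2) / np.maximum(nsum, 1)
        pq = pbar * (1.0 - pbar)
        inner = pq - s2 / 2.0 - hbar / 4.0
        # guards only protect rows zeroed by `valid` below
        a = (nbar / np.maximum(nc, 0.5)) * (s2 - inner / np.maximum(nbar - 1, 0.5))
        b = (nbar / np.maximum(nbar - 1, 0.5)) * (
            pq - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, 0.0)
    d = np.where(valid, a + b + c, 0.0)
    # combined-panel monomorphic sites contribute nothing
    mono = (pbar <= 0) | (pbar >= 1)
    a[mono & (hbar == 0)] = 0.0
    d[mono & (hbar == 0)] = 0.0
    return a, d


# ---------------------------------------------------------------------------
# single-window operations (thin wrappers over the kernels)

def pi_window(panel: GenotypePanel, window: tuple[str, int, int], population: str) -> float:
    """Per-bp nucleotide diversity of one 0-based half-open window."""
    chrom, start, end = window
    idx = panel.sites_in(chrom, start, end)
    sub = panel.take_sites(idx) if len(idx) else None
    if sub is None:
        return 0.0
    return float(_per_site_pi_terms(sub, population).sum() / (end - start))


def fst_window(panel: GenotypePanel, window: tuple[str, int, int]) -> float:
    """Weir-Cockerham ratio-of-sums FST of one window; NaN when undefined."""
    chrom, start, end = window
    idx = panel.sites_in(chrom, start, end)
    if len(idx) == 0:
        return float("nan")
    a, d = _per_site_wc_components(panel.take_sites(idx))
    denom = d.sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def rod(pi_wild, pi_dom):
    """Reduction of diversity, 1 - pi_dom/pi_wild; NaN where pi_wild == 0."""
    pi_wild = np.asarray(pi_wild, dtype=float)
    pi_dom = np.asarray(pi_dom, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(pi_wild > 0, 1.0 - pi_dom / np.where(pi_wild > 0, pi_wild, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# consensus calling and region merging

def consensus_outliers(
    stats: pd.DataFrame,
    quantile: float = 0.95,
    min_snps: int = 20,
    min_methods: int = 2,
    statistics: tuple[str, ...] = ("fst", "rod", "xpclr"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Call consensus outlier windows: strictly above the per-statistic
    empirical ``quantile`` for at least ``min_methods`` statistics, among
    windows with n_snps strictly greater than ``min_snps``.

    Returns (outlier window rows, realized thresholds).
    """
    stats = stats.reset_index(drop=True)
    eligible = stats["n_snps"] > min_snps
    thresholds: dict[str, float] = {}
    exceed = np.zeros(len(stats), dtype=int)
    n_usable_stats = 0
    for col in statistics:
        if col not in stats.columns:
            continue
        vals = stats.loc[eligible, col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            thresholds[col] = float("nan")
            continue
        n_usable_stats += 1
        if len(vals) < 1.0 / (1.0 - quantile):
            warnings.warn(f"few defined windows for {col}; quantile unstable", stacklevel=2)
        thr = float(np.quantile(vals, quantile))
        thresholds[col] = thr
        col_vals = stats[col].to_numpy(dtype=float)
        exceed += (eligible.to_numpy() & ~np.isnan(col_vals) & (col_vals > thr)).astype(int)
    if n_usable_stats < min_methods:
        raise ValueError("fewer defined statistics than min_methods; cannot call consensus")
    out = stats.loc[exceed >= min_methods].copy()
    out["n_methods"] = exceed[exceed >= min_methods]
    return out, thresholds


def merge_regions(outliers: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended outlier windows (same chrom) into
    maximal disjoint regions; per-statistic maxima are carried along."""
    if len(outliers) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "max_fst", "max_rod", "max_xpclr"])
    df = outliers.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    cur = None
    for rec in df.itertuples(index=False):
        if cur is not None and rec.chrom == cur["chrom"] and rec.start <= cur["end"]:
            cur["end"] = max(cur["end"], rec.end)
            cur["n_windows"] += 1
            for col in ("fst", "rod", "xpclr"):
                v = getattr(rec, col, float("nan"))
                prev = cur[f"max_{col}"]
                if np.isnan(prev):
                    cur[f"max_{col}"] = v
                elif not np.isnan(v):
                    cur[f"max_{col}"] = max(prev, v)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": rec.chrom,
                "start": int(rec.start),
                "end": int(rec.end),
                "n_windows": 1,
                "max_fst": getattr(rec, "fst", float("nan")),
                "max_rod": getattr(rec, "rod", float("nan")),
                "max_xpclr": getattr(rec, "xpclr", float("nan")),
            }
    rows.append(cur)
    return pd.DataFrame(rows)


def assign_genes(regions: pd.DataFrame, genes) -> pd.DataFrame:
    """Attach the list of genes whose TSS-TTS span overlaps each region by
    at least 1 bp (half-open region coordinates)."""
    gene_lists = []
    for rec in regions.itertuples(index=False):
        hits = []
        for g in genes.on_chrom(rec.chrom):
            b0, b1 = g.body_interval()
            if b0 < rec.end and rec.start < b1:
                hits.append(g.gene_id)
        gene_lists.append(hits)
    out = regions.copy()
    out["genes"] = gene_lists
    out["n_genes"] = [len(h) for h in gene_lists]
    return out


# ---------------------------------------------------------------------------
# model-style front end

@dataclass
class SweepScan:
    """Windowed three-statistic sweep scan, statsmodels-style.

    Build from a :class:`GenotypePanel` (plus optional gene models and a
    genetic map), then :meth:`fit` to obtain a :class:`SweepScanResult`
    with the window-statistic table, realized thresholds, consensus
    outliers, and merged sweep regions.
    """

    panel: GenotypePanel
    genes: object = None
    size: int = 40_000
    step: int = 10_000
    chrom_lengths: dict = None
    quantile: float = 0.95
    min_snps: int = 20
    min_methods: int = 2
    compute_xpclr: bool = True
    xpclr_config: object = None
    genetic_map: object = None

    def _chrom_lengths(self) -> dict[str, int]:
        if self.chrom_lengths is not None:
            return dict(self.chrom_lengths)
        out = {}
        for c in pd.unique(self.panel.chrom):
            out[str(c)] = int(self.panel.pos[self.panel.chrom == c].max())
        return out

    def fit(self) -> "SweepScanResult":
        from .xpclr import XpclrModelConfig, estimate_omega, xpclr_scores

        panel = self.panel
        windows = make_windows(self._chrom_lengths(), self.size, self.step)
        pi_w_terms = _per_site_pi_terms(panel, "wild")
        pi_d_terms = _per_site_pi_terms(panel, "dom")
        wc_a, wc_d = _per_site_wc_components(panel)

        n_snps = np.zeros(len(windows), dtype=int)
        pi_w = np.zeros(len(windows))
        pi_d = np.zeros(len(windows))
        fst = np.full(len(windows), np.nan)
        site_idx: list[np.ndarray] = []
        for i, rec in enumerate(windows.itertuples(index=False)):
            idx = panel.sites_in(rec.chrom, rec.start, rec.end)
            site_idx.append(idx)
            n_snps[i] = len(idx)
            L = rec.end - rec.start
            pi_w[i] = pi_w_terms[idx].sum() / L
            pi_d[i] = pi_d_terms[idx].sum() / L
            denom = wc_d[idx].sum()
            if denom != 0:
                fst[i] = wc_a[idx].sum() / denom

        stats = windows.copy()
        stats["n_snps"] = n_snps
        stats["pi_wild"] = pi_w
        stats["pi_dom"] = pi_d
        stats["fst"] = fst
        stats["rod"] = rod(pi_w, pi_d)

        if self.compute_xpclr:
            cfg = self.xpclr_config or XpclrModelConfig()
            if cfg.omega is None:
                cfg = cfg.with_omega(estimate_omega(panel))
            stats["xpclr"] = xpclr_scores(panel, windows, site_idx, cfg, self.genetic_map)
            statistics = ("fst", "rod", "xpclr")
        else:
            stats["xpclr"] = np.nan
            statistics = ("fst", "rod")

        outliers, thresholds = consensus_outliers(
            stats, self.quantile, self.min_snps, self.min_methods, statistics
        )
        regions = merge_regions(outliers)
        if self.genes is not None and len(regions):
            regions = assign_genes(regions, self.genes)
        return SweepScanResult(self, stats, thresholds, outliers, regions)


class SweepScanResult:
    """Results of a :class:`SweepScan` fit."""

    def __init__(self, model, window_stats, thresholds, outliers, regions):
        self.model = model
        self.window_stats = window_stats
        self.thresholds = thresholds
        self.outliers = outliers
        self.regions = regions

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_genes(self) -> list[str]:
        if "genes" not in self.regions.columns:
            return []
        seen = dict.fromkeys(g for lst in self.regions["genes"] for g in lst)
        return list(seen)

    def summary(self) -> str:
        s = self.window_stats
        lines = [
            "Selective-sweep scan (FST / ROD / XP-CLR consensus)",
            "=" * 55,
            f"windows:            {len(s)} ({self.model.size/1000:g} kb, step {self.model.step/1000:g} kb)",
            f"eligible (> {self.model.min_snps} SNPs): {(s['n_snps'] > self.model.min_snps).sum()}",
            "realized thresholds (top {:.0f}%):".format(100 * (1 - self.model.quantile)),
        ]
        for k, v in self.thresholds.items():
            lines.append(f"  {k:<6} > {v:.4g}")
        lines.append(f"consensus outlier windows (>= {self.model.min_methods} statistics): {len(self.outliers)}")
        lines.append(f"merged sweep regions: {self.n_regions}")
        if "genes" in getattr(self.regions, "columns", []):
            lines.append(f"genes in sweep regions: {len(self.region_genes)}")
        return "\n".join(lines)

    def to_bed(self, path: str) -> None:
        cols = self.regions[["chrom", "start", "end"]].copy()
        cols["name"] = [f"sweep_{i+1}" for i in range(len(cols))]
        cols.to_csv(path, sep="\t", header=False, index=False)
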