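"""Cross-population composite likelihood ratio (XP-CLR) scan statistic.

The statistic contrasts, SNP by SNP, the probability of the observed
derived-population ("query", here ``dom``) allele counts given the
ancestral-population ("reference", here ``wild``) allele frequency under
two models:

* **neutral drift** — the query frequency x given the reference frequency
  p is modelled as a Gaussian of mean p and variance ``omega * p * (1-p)``
  truncated to (0, 1), with the truncated tail probability placed as point
  masses on the absorbing boundaries 0 and 1 (Brownian drift with
  absorption).  ``omega`` is the genome-wide drift dispersion, estimated by
  moment matching unless supplied.

* **sweep** — a beneficial allele at the window centre rose to fixation.
  Under the star-like hitchhiking approximation a neutral lineage at
  recombination distance r (Morgans) escapes the sweep with probability
  q = 1 - exp(-r * T(s)), where T(s) = ln(2*N*s)/s is the sweep duration
  in generations.  The post-sweep frequency is then a two-point mixture:
  with probability p the swept haplotype carried the alt allele and the
  frequency is pulled to 1-q+q*p, otherwise to q*p; drift noise with the
  same omega is added around either mean.

The window score is 2 * (max_s CL(s) - CL(0)) with the composite
log-likelihood CL summing per-SNP log likelihoods weighted down for LD:
each SNP's weight is 1/(number of window SNPs whose reference-population
dosage r^2 with it exceeds the cutoff, itself included).  Because 0 is in
the selection grid the score is non-negative by construction.

All internals (grid, omega estimator, hitchhiking kernel, LD weighting)
are package design choices, exposed in :class:`XpclrModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .panel import GenotypePanel

__all__ = ["XpclrModelConfig", "estimate_omega", "xpclr_window", "xpclr_scores", "snp_log_likelihood"]

DEFAULT_S_GRID = (0.0, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1)


@dataclass(frozen=True)
class XpclrModelConfig:
    """Tunables of the XP-CLR composite-likelihood model."""

    s_grid: tuple = DEFAULT_S_GRID
    omega: float | None = None  # None -> estimate genome-wide
    max_snps_per_window: int = 600
    ld_r2_cutoff: float = 0.95
    sweep_popsize: float = 10_000.0  # N entering the sweep-duration ln(2Ns)/s
    cm_per_mb: float = 1.0  # uniform map fallback
    n_quad: int = 48  # Gauss-Legendre nodes on (0,1)

    def __post_init__(self):
        if 0.0 not in self.s_grid:
            raise ValueError("s_grid must contain 0")
        if not (0 < self.ld_r2_cutoff <= 1):
            raise ValueError("ld_r2_cutoff must be in (0, 1]")
        if self.omega is not None and self.omega <= 0:
            raise ValueError("omega must be positive")

    def with_omega(self, omega: float) -> "XpclrModelConfig":
        return replace(self, omega=float(omega))


def estimate_omega(panel: GenotypePanel) -> float:
    """Genome-wide drift dispersion by moment matching.

    E[(p_dom - p_wild)^2] = omega * p_wild * (1 - p_wild) + sampling noise;
    the binomial sampling variances of both sample frequencies are
    subtracted before taking the ratio of sums.
    """
    a1, m1 = panel.allele_counts("wild")
    a2, m2 = panel.allele_counts("dom")
    ok = (m1 > 1) & (m2 > 1)
    p1 = a1[ok] / m1[ok]
    p2 = a2[ok] / m2[ok]
    seg = (p1 > 0) & (p1 < 1)
    p1, p2 = p1[seg], p2[seg]
    mm1, mm2 = m1[ok][seg], m2[ok][seg]
    if len(p1) == 0:
        return 0.05
    num = np.sum((p2 - p1) ** 2 - p1 * (1 - p1) / mm1 - p2 * (1 - p2) / mm2)
    den = np.sum(p1 * (1 - p1))
    return float(np.clip(num / den, 1e-3, 5.0))


def _sweep_duration(s: float, N: float) -> float:
    """Approximate sweep duration T(s) = ln(2Ns)/s; None when effectively
    neutral (s <= 0 or 2Ns <= 1)."""
    if s <= 0 or 2.0 * N * s <= 1.0:
        return None
    return float(np.log(2.0 * N * s) / s)


def _binom_matrix(k, m, nodes):
    """Binomial pmf of each SNP's counts over the quadrature nodes."""
    lchoose = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    with np.errstate(divide="ignore"):
        logx = np.log(nodes)[None, :]
        log1x = np.log1p(-nodes)[None, :]
    return np.exp(lchoose[:, None] + k[:, None] * logx + (m - k)[:, None] * log1x)


def _component_loglik(k, m, mu, sigma, nodes, wts, binom):
    """log P(k of m | truncated-Gaussian(mu, sigma) frequency density)."""
    mu = np.asarray(mu, dtype=float)
    z0 = ndtr((0.0 - mu) / sigma)  # mass absorbed at 0
    z1 = 1.0 - ndtr((1.0 - mu) / sigma)  # mass absorbed at 1
    gauss = np.exp(-0.5 * ((nodes[None, :] - mu[:, None]) / sigma[:, None]) ** 2) / (
        sigma[:, None] * np.sqrt(2 * np.pi)
    )
    interior = (binom * gauss * wts[None, :]).sum(axis=1)
    lik = interior + z0 * (k == 0) + z1 * (k == m)
    return np.log(np.maximum(lik, 1e-300))


def snp_log_likelihood(k, m, p_ref, sigma, q_escape, nodes, wts, binom=None):
    """Per-SNP sweep-model log likelihood (q_escape = 1 gives neutrality).

    The post-sweep frequency density is the p_ref-weighted mixture of the
    hitchhiked (mean 1-q+q*p) and non-hitchhiked (mean q*p) components.
    """
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    p = np.asarray(p_ref, dtype=float)
    q = np.asarray(q_escape, dtype=float)
    if binom is None:
        binom = _binom_matrix(k, m, nodes)
    mu_hitch = 1.0 - q + q * p
    mu_escape = q * p
    l1 = _component_loglik(k, m, mu_hitch, sigma, nodes, wts, binom)
    l0 = _component_loglik(k, m, mu_escape, sigma, nodes, wts, binom)
    hi = np.maximum(l1, l0)
    return hi + np.log(p * np.exp(l1 - hi) + (1.0 - p) * np.exp(l0 - hi))


def _ld_weights(panel: GenotypePanel, idx: np.ndarray, cutoff: float) -> np.ndarray:
    """1 / (cluster size of SNPs with reference-population r^2 > cutoff)."""
    g = panel.genotypes[np.ix_(idx, panel.pop_indices("wild"))].astype(float)
    g[g == -1] = np.nan
    mean = np.nanmean(g, axis=1, keepdims=True)
    gc = np.where(np.isnan(g), 0.0, g - mean)
    norm = np.sqrt((gc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    gn = gc / norm[:, None]
    r2 = (gn @ gn.T) ** 2
    counts = (r2 > cutoff).sum(axis=1)
    return 1.0 / np.maximum(counts, 1)


def _genetic_positions(chrom, pos, genetic_map, cm_per_mb):
    """Positions in Morgans, interpolated from a (chrom, pos, cM) map or a
    uniform rate fallback."""
    pos = np.asarray(pos, dtype=float)
    if genetic_map is None:
        return pos * cm_per_mb * 1e-8
    gm = genetic_map[genetic_map["chrom"] == chrom]
    if len(gm) < 2:
        return pos * cm_per_mb * 1e-8
    return np.interp(pos, gm["pos"].to_numpy(float), gm["cM"].to_numpy(float)) / 100.0


from functools import lru_cache


@lru_cache(maxsize=8)
def _quadrature(n_quad: int):
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    return 0.5 * (nodes + 1.0), 0.5 * wts


def _window_score(k, m, p_ref, morgans_from_center, weights, cfg: XpclrModelConfig) -> float:
    sigma = np.sqrt(cfg.omega * p_ref * (1.0 - p_ref))
    nodes, wts = _quadrature(cfg.n_quad)
    binom = _binom_matrix(np.asarray(k, float), np.asarray(m, float), nodes)
    ll_neutral = snp_log_likelihood(k, m, p_ref, sigma, np.ones_like(p_ref), nodes, wts, binom)
    cl0 = float(np.dot(weights, ll_neutral))
    best = cl0
    for s in cfg.s_grid:
        T = _sweep_duration(s, cfg.sweep_popsize)
        if T is None:
            cl = cl0
        else:
            q = 1.0 - np.exp(-morgans_from_center * T)
            cl = float(
                np.dot(weights, snp_log_likelihood(k, m, p_ref, sigma, q, nodes, wts, binom))
            )
        best = max(best, cl)
    return 2.0 * (best - cl0)


def xpclr_window(
    panel: GenotypePanel,
    window: tuple[str, int, int],
    config: XpclrModelConfig | None = None,
    genetic_map: pd.DataFrame | None = None,
) -> float:
    """XP-CLR score of a single 0-based half-open window; NaN when the
    window has no usable SNP (usable = segregating in the reference)."""
    cfg = config or XpclrModelConfig()
    if cfg.omega is None:
        cfg = cfg.with_omega(estimate_omega(panel))
    chrom, start, end = window
    idx = panel.sites_in(chrom, start, end)
    return _score_one(panel, chrom, start, end, idx, cfg, genetic_map)


def _score_one(panel, chrom, start, end, idx, cfg, genetic_map) -> float:
    if len(idx) == 0:
        return float("nan")
    a1, m1 = panel.allele_counts("wild")
    a2, m2 = panel.allele_counts("dom")
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(m1 > 0, a1 / np.maximum(m1, 1), np.nan)
    usable = idx[(m1[idx] > 0) & (m2[idx] > 0) & (p1[idx] > 0) & (p1[idx] < 1)]
    if len(usable) == 0:
        return float("nan")
    if len(usable) > cfg.max_snps_per_window:
        thin = np.linspace(0, len(usable) - 1, cfg.max_snps_per_window).round().astype(int)
        usable = usable[np.unique(thin)]
    center_bp = 0.5 * (start + end)
    gpos = _genetic_positions(chrom, panel.pos[usable], genetic_map, cfg.cm_per_mb)
    gcenter = _genetic_positions(chrom, np.array([center_bp]), genetic_map, cfg.cm_per_mb)[0]
    d = np.abs(gpos - gcenter)
    w = _ld_weights(panel, usable, cfg.ld_r2_cutoff)
    return _window_score(a2[usable].astype(float), m2[usable].astype(float), p1[usable], d, w, cfg)


def xpclr_scores(
    panel: GenotypePanel,
    windows: pd.DataFrame,
    site_idx: list[np.ndarray],
    cfg: XpclrModelConfig,
    genetic_map: pd.DataFrame | None = None,
) -> np.ndarray:
    """Scores for a pre-indexed window table (used by the scan front end)."""
    out = np.full(len(windows), np.nan)
    for i, rec in enumerate(windows.itertuples(index=False)):
        out[i] = _score_one(panel, rec.chrom, rec.start, rec.end, site_idx[i], cfg, genetic_map)
    return out
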