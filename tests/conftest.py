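"""Shared fixtures: hand-built toy panels and synthetic scenarios."""

import numpy as np
import pytest

from domsweep import GenotypePanel, ScenarioConfig, generate_gene_models, pick_sweep_targets, simulate_panel


def build_panel(genotypes, pos=None, chrom="chr1", n_wild=None):
    """Panel from a (sites x samples) dosage list; first half wild."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if n_wild is None:
        n_wild = n_samples // 2
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    labels = ["wild"] * n_wild + ["dom"] * (n_samples - n_wild)
    return GenotypePanel(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        genotypes=g,
        samples=[f"s{i}" for i in range(n_samples)],
        pop_labels=np.array(labels, dtype=object),
    )


def random_panel(rng, n_sites=50, n_wild=5, n_dom=5, missing_rate=0.0):
    """Random segregating panel for oracle comparisons."""
    p_w = rng.uniform(0.05, 0.95, n_sites)
    p_d = rng.uniform(0.05, 0.95, n_sites)
    gw = rng.binomial(2, p_w[:, None], (n_sites, n_wild))
    gd = rng.binomial(2, p_d[:, None], (n_sites, n_dom))
    g = np.concatenate([gw, gd], axis=1).astype(np.int8)
    if missing_rate:
        mask = rng.random(g.shape) < missing_rate
        g[mask] = -1
    return build_panel(g, n_wild=n_wild)


@pytest.fixture(scope="session")
def sweep_scenario():
    """One planted-sweep scenario shared across tests (seed 1, 15 targets)."""
    base = ScenarioConfig(seed=1)
    cfg = ScenarioConfig(seed=1, sweep_targets=pick_sweep_targets(base, 15))
    genes = generate_gene_models(cfg)
    panel, truth = simulate_panel(cfg, genes)
    return cfg, genes, panel, truth


@pytest.fixture(scope="session")
def null_scenario():
    """Sweep-free scenario (seed 11)."""
    cfg = ScenarioConfig(seed=11)
    genes = generate_gene_models(cfg)
    panel, truth = simulate_panel(cfg, genes)
    return cfg, genes, panel, truth
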