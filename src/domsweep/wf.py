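"""Individual-based Wright-Fisher forward simulation of domestication.

The model: a diploid ancestral (wild) population of size ``N_wild``
evolves to mutation-selection-drift balance over a burn-in, then splits
into a wild population (size ``N_wild``) and a bottlenecked domestic
population (size ``N_dom``) that drift and adapt independently for
``t_dom`` generations.  New mutations arise on a ``L``-bp segment at rate
``mu`` per site per generation and fall into a three-class distribution
of fitness effects (a beneficial fraction at ``s_beneficial``, a
deleterious fraction at ``s_deleterious``, the rest neutral).  Fitness is
multiplicative across sites with per-genotype values {1, 1+h*s, 1+s}
(h = 0.5 by default); gametes recombine with Poisson(rec*L) crossovers;
parents are sampled in proportion to fitness.  Mutations that fix stay in
the record ("retained") -- under multiplicative fitness a fixed mutation
rescales every individual equally, so it is dropped from the active
matrix but logged.

Desk-scale runs use the standard diffusion rescaling by a factor
``lam``: N -> N/lam, t -> t/lam, mu -> mu*lam, rec -> rec*lam,
s -> s*lam, which preserves theta = 4*N*mu, N*s, N*r and t/N.

Also provided: Sved's linkage-disequilibrium estimator of effective
population size, Ne = (1/r^2 - 1)/(4c) from E[r^2] = 1/(1 + 4*N*c), which
produced the study's wild/domestic size estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "SimConfig",
    "rescale",
    "run_scenario",
    "SimResult",
    "ReplicateResult",
    "fst_readout",
    "estimate_ne_from_ld",
    "drift_het_decay",
    "fixation_experiment",
    "split_drift_panel",
    "WrightFisherModel",
]


@dataclass(frozen=True)
class SimConfig:
    """Domestication-scenario parameters (full scale by default).

    Defaults follow the study design: a 608-kb noncoding segment,
    mu = 1.91e-9 per site per generation, uniform rec = 1e-8 per bp,
    5% beneficial mutations at s = +0.05, 4% deleterious at s = -0.001,
    wild/domestic sizes 8433 and 4502 (LD-based estimates), a split
    ~2500 generations ago (1 generation per year), 25 replicates.
    """

    L: int = 608_000
    mu: float = 1.91e-9
    rec: float = 1e-8
    frac_beneficial: float = 0.05
    s_beneficial: float = 0.05
    frac_deleterious: float = 0.04
    s_deleterious: float = -0.001
    h: float = 0.5
    N_wild: int = 8433
    N_dom: int = 4502
    t_dom: int = 2500
    burn_in: int | None = None  # None -> 10 * N_wild
    replicates: int = 25
    lam: float = 1.0  # rescaling factor already applied
    seed: int = 0
    free_recombination: bool = False  # unlinked sites (drift-validation runs)

    def __post_init__(self):
        if self.frac_beneficial < 0 or self.frac_deleterious < 0:
            raise ValueError("DFE fractions must be non-negative")
        if self.frac_beneficial + self.frac_deleterious > 1:
            raise ValueError("DFE fractions must sum to at most 1")
        if self.N_wild <= 0 or self.N_dom <= 0 or self.t_dom < 0:
            raise ValueError("population sizes must be positive, t_dom >= 0")
        if not 0 <= self.h <= 1:
            raise ValueError("dominance h must lie in [0, 1]")
        for s in (self.s_beneficial, self.s_deleterious):
            if 1.0 + s <= 0 or 1.0 + self.h * s <= 0:
                raise ValueError(f"pathological selection coefficient s={s}: fitness <= 0")

    @property
    def burn_in_gens(self) -> int:
        return self.burn_in if self.burn_in is not None else 10 * self.N_wild

    def neutral(self) -> "SimConfig":
        """The matched neutral (bottleneck-only) condition."""
        return replace(self, frac_beneficial=0.0, frac_deleterious=0.0)


def rescale(config: SimConfig, lam: float) -> SimConfig:
    """Diffusion rescaling: N/lam, t/lam, mu*lam, rec*lam, s*lam."""
    if lam < 1:
        raise ValueError("rescaling factor must be >= 1")
    n_wild = int(round(config.N_wild / lam))
    n_dom = int(round(config.N_dom / lam))
    if min(n_wild, n_dom) < 10:
        raise ValueError("rescaled population below 10 diploids; diffusion approximation broken")
    return replace(
        config,
        L=config.L,
        mu=config.mu * lam,
        rec=config.rec * lam,
        s_beneficial=config.s_beneficial * lam,
        s_deleterious=config.s_deleterious * lam,
        N_wild=n_wild,
        N_dom=n_dom,
        t_dom=int(round(config.t_dom / lam)),
        burn_in=None if config.burn_in is None else int(round(config.burn_in / lam)),
        lam=config.lam * lam,
    )


# ---------------------------------------------------------------------------
# core engine

class _Deme:
    """One population's haplotypes over the shared active-site registry."""

    __slots__ = ("H",)

    def __init__(self, H: np.ndarray):
        self.H = H  # (2N, S) uint8

    @property
    def n_diploid(self) -> int:
        return self.H.shape[0] // 2


def _draw_s(rng, cfg: SimConfig) -> float:
    u = rng.random()
    if u < cfg.frac_beneficial:
        return cfg.s_beneficial
    if u < cfg.frac_beneficial + cfg.frac_deleterious:
        return cfg.s_deleterious
    return 0.0


def _offspring(H, pos, s_arr, cfg: SimConfig, n_off: int, rng) -> np.ndarray:
    """One Wright-Fisher generation: fitness-weighted parent sampling,
    recombination, no mutation (added by the caller)."""
    two_n_par = H.shape[0]
    n_par = two_n_par // 2
    sel = np.flatnonzero(s_arr != 0.0)
    if len(sel) and n_par > 0:
        D = (H[0::2, sel].astype(np.int16) + H[1::2, sel]).astype(np.int8)
        log_het = np.log1p(cfg.h * s_arr[sel])
        log_hom = np.log1p(s_arr[sel])
        logw = (D == 1).astype(float) @ log_het + (D == 2).astype(float) @ log_hom
        logw -= logw.max()
        w = np.exp(logw)
        tot = w.sum()
        if not np.isfinite(tot) or tot <= 0:
            raise FloatingPointError("mean fitness is not positive; pathological s")
        parents = rng.choice(n_par, size=2 * n_off, p=w / tot)
    else:
        parents = rng.integers(0, n_par, size=2 * n_off)
    start = rng.integers(0, 2, size=2 * n_off)
    if cfg.free_recombination and H.shape[1]:
        which = rng.integers(0, 2, size=(2 * n_off, H.shape[1]), dtype=np.uint8)
        return np.where(which == 0, H[2 * parents], H[2 * parents + 1])
    ks = rng.poisson(cfg.rec * cfg.L, size=2 * n_off)
    out = H[2 * parents + start]
    xo = np.flatnonzero(ks > 0)
    if len(xo) and H.shape[1]:
        out = out.copy()
        for j in xo:
            cuts = np.sort(rng.integers(1, cfg.L, size=ks[j]))
            parity = (np.searchsorted(cuts, pos) % 2).astype(np.uint8)
            choose = start[j] ^ parity  # 0 -> first haplotype, 1 -> second
            p0 = 2 * parents[j]
            out[j] = np.where(choose == 0, H[p0], H[p0 + 1])
    else:
        out = out.copy()
    return out


class _Engine:
    """Shared site registry plus one or two demes."""

    def __init__(self, cfg: SimConfig, rng):
        self.cfg = cfg
        self.rng = rng
        self.pos = np.empty(0, dtype=np.int64)
        self.s = np.empty(0, dtype=float)
        self.origin = np.empty(0, dtype=np.int32)
        self.pos_to_col: dict[int, int] = {}
        self.demes: list[_Deme] = []
        self.gen = 0
        # resolved sites: fixed in at least one deme, invariant in all
        self.resolved: list[tuple] = []  # (pos, s, origin_gen, gen, freqs...)

    def init_monomorphic(self, N: int):
        self.demes = [_Deme(np.zeros((2 * N, 0), dtype=np.uint8))]

    def _mutate(self, deme_idx: int):
        cfg, rng = self.cfg, self.rng
        H = self.demes[deme_idx].H
        two_n = H.shape[0]
        n_mut = rng.poisson(two_n * cfg.L * cfg.mu)
        if n_mut == 0:
            return
        positions = rng.integers(1, cfg.L + 1, size=n_mut)
        rows = rng.integers(0, two_n, size=n_mut)
        new = []
        for p, r in zip(positions, rows):
            col = self.pos_to_col.get(int(p))
            if col is not None:
                self.demes[deme_idx].H[r, col] ^= 1  # recurrent mutation flips
            else:
                new.append((int(p), int(r), _draw_s(rng, cfg)))
        if new:
            n_new = len(new)
            for d_i, d in enumerate(self.demes):
                add = np.zeros((d.H.shape[0], n_new), dtype=np.uint8)
                if d_i == deme_idx:
                    for j, (_, r, _) in enumerate(new):
                        add[r, j] = 1
                d.H = np.concatenate([d.H, add], axis=1)
            base = len(self.pos)
            self.pos = np.concatenate([self.pos, [p for p, _, _ in new]])
            self.s = np.concatenate([self.s, [sv for _, _, sv in new]])
            self.origin = np.concatenate(
                [self.origin, np.full(n_new, self.gen, dtype=np.int32)]
            )
            for j, (p, _, _) in enumerate(new):
                self.pos_to_col[p] = base + j

    def _prune(self):
        if len(self.pos) == 0:
            return
        freqs = [d.H.mean(axis=0) for d in self.demes]
        invariant = np.ones(len(self.pos), dtype=bool)
        any_fixed = np.zeros(len(self.pos), dtype=bool)
        for f in freqs:
            invariant &= (f == 0.0) | (f == 1.0)
            any_fixed |= f == 1.0
        drop = invariant
        if drop.any():
            for i in np.flatnonzero(drop & any_fixed):
                self.resolved.append(
                    (
                        int(self.pos[i]),
                        float(self.s[i]),
                        int(self.origin[i]),
                        self.gen,
                        tuple(float(f[i]) for f in freqs),
                    )
                )
            keep = ~drop
            self.pos = self.pos[keep]
            self.s = self.s[keep]
            self.origin = self.origin[keep]
            for d in self.demes:
                d.H = d.H[:, keep]
            self.pos_to_col = {int(p): j for j, p in enumerate(self.pos)}

    def step(self, sizes: list[int] | None = None):
        """Advance every deme one generation (optionally resizing)."""
        self.gen += 1
        new_H = []
        for i, d in enumerate(self.demes):
            n_off = sizes[i] if sizes else d.n_diploid
            new_H.append(_offspring(d.H, self.pos, self.s, self.cfg, n_off, self.rng))
        for i, H in enumerate(new_H):
            self.demes[i].H = H
        for i in range(len(self.demes)):
            self._mutate(i)
        self._prune()

    def split(self, sizes: list[int]):
        """Found daughter demes from the (single) ancestral deme; counts as
        the first post-split generation."""
        anc = self.demes[0]
        self.gen += 1
        kids = [
            _Deme(_offspring(anc.H, self.pos, self.s, self.cfg, n, self.rng)) for n in sizes
        ]
        self.demes = kids
        for i in range(len(self.demes)):
            self._mutate(i)
        self._prune()

    def mean_het(self, deme_idx: int = 0) -> float:
        """Mean 2*p*(1-p) over active sites (0 when none)."""
        H = self.demes[deme_idx].H
        if H.shape[1] == 0:
            return 0.0
        f = H.mean(axis=0)
        return float((2 * f * (1 - f)).sum())


# ---------------------------------------------------------------------------
# scenario runner and results

@dataclass
class ReplicateResult:
    """Final state of one replicate."""

    site_table: pd.DataFrame  # pos, s, origin_gen, freq_wild, freq_dom, fixed flags
    het_traj: pd.DataFrame  # gen, phase, het (wild deme)
    H_wild: np.ndarray = field(repr=False, default=None)
    H_dom: np.ndarray = field(repr=False, default=None)
    active_pos: np.ndarray = field(repr=False, default=None)
    active_s: np.ndarray = field(repr=False, default=None)

    def sample_panel(self, n_wild: int = 40, n_dom: int = 45, seed: int = 0) -> GenotypePanel:
        """Draw diploid samples from the final generation as a panel.

        Includes active segregating sites plus post-split fixed
        differences; combined-monomorphic sites are dropped.
        """
        rng = np.random.default_rng(seed)
        # diploids are built from gametes drawn with replacement, the
        # binomial sampling the WC estimator assumes (n << N in the field)
        hw = rng.integers(0, self.H_wild.shape[0], size=2 * n_wild)
        hd = rng.integers(0, self.H_dom.shape[0], size=2 * n_dom)
        gw = (self.H_wild[hw[0::2]] + self.H_wild[hw[1::2]]).T.astype(np.int8)
        gd = (self.H_dom[hd[0::2]] + self.H_dom[hd[1::2]]).T.astype(np.int8)
        pos = list(self.active_pos)
        rows = [np.concatenate([gw[i], gd[i]]) for i in range(len(pos))]
        # post-split differential fixations: deterministic genotypes
        st = self.site_table
        fixed_diff = st[
            (st["origin"] == "split")
            & (st["freq_wild"].isin([0.0, 1.0]))
            & (st["freq_dom"].isin([0.0, 1.0]))
            & (st["freq_wild"] != st["freq_dom"])
        ]
        for rec in fixed_diff.itertuples(index=False):
            pos.append(int(rec.pos))
            rows.append(
                np.concatenate(
                    [
                        np.full(n_wild, int(2 * rec.freq_wild), dtype=np.int8),
                        np.full(n_dom, int(2 * rec.freq_dom), dtype=np.int8),
                    ]
                )
            )
        pos = np.asarray(pos, dtype=np.int64)
        geno = np.vstack(rows) if rows else np.empty((0, n_wild + n_dom), dtype=np.int8)
        order = np.argsort(pos, kind="stable")
        pos, geno = pos[order], geno[order]
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        pos, geno = pos[uniq], geno[uniq]
        tot = geno.sum(axis=1)
        seg = (tot > 0) & (tot < 2 * geno.shape[1])
        pos, geno = pos[seg], geno[seg]
        n = geno.shape[0]
        samples = [f"wild_{i:02d}" for i in range(n_wild)] + [f"dom_{i:02d}" for i in range(n_dom)]
        return GenotypePanel(
            chrom=np.full(n, "sim", dtype=object),
            pos=pos,
            ref=np.full(n, "A", dtype=object),
            alt=np.full(n, "T", dtype=object),
            genotypes=geno,
            samples=samples,
            pop_labels=np.array(["wild"] * n_wild + ["dom"] * n_dom, dtype=object),
        )


@dataclass
class SimResult:
    config: SimConfig
    replicates: list

    def __iter__(self):
        return iter(self.replicates)

    def __len__(self):
        return len(self.replicates)


def _run_replicate(cfg: SimConfig, rep_index: int, record_every: int = 25) -> ReplicateResult:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, rep_index]))
    eng = _Engine(cfg, rng)
    eng.init_monomorphic(cfg.N_wild)
    traj = []
    for g in range(cfg.burn_in_gens):
        eng.step()
        if g % record_every == 0:
            traj.append((eng.gen, "burnin", eng.mean_het(0)))
    split_gen = eng.gen
    if cfg.t_dom > 0:
        eng.split([cfg.N_wild, cfg.N_dom])
        for g in range(cfg.t_dom - 1):
            eng.step()
            if g % record_every == 0:
                traj.append((eng.gen, "split", eng.mean_het(0)))
    rows = []
    freqs = [d.H.mean(axis=0) for d in eng.demes]
    f_w = freqs[0]
    f_d = freqs[1] if len(freqs) > 1 else freqs[0]
    for i in range(len(eng.pos)):
        rows.append(
            {
                "pos": int(eng.pos[i]),
                "s": float(eng.s[i]),
                "origin_gen": int(eng.origin[i]),
                "origin": "burnin" if eng.origin[i] <= split_gen else "split",
                "freq_wild": float(f_w[i]),
                "freq_dom": float(f_d[i]),
            }
        )
    for p, sv, og, gen, fr in eng.resolved:
        fw = fr[0]
        fd = fr[1] if len(fr) > 1 else fr[0]
        rows.append(
            {
                "pos": p,
                "s": sv,
                "origin_gen": og,
                "origin": "burnin" if og <= split_gen else "split",
                "freq_wild": fw,
                "freq_dom": fd,
            }
        )
    site_table = pd.DataFrame(
        rows, columns=["pos", "s", "origin_gen", "origin", "freq_wild", "freq_dom"]
    )
    if len(site_table):
        site_table["fixed_wild"] = site_table["freq_wild"].isin([0.0, 1.0])
        site_table["fixed_dom"] = site_table["freq_dom"].isin([0.0, 1.0])
    else:
        site_table["fixed_wild"] = pd.Series(dtype=bool)
        site_table["fixed_dom"] = pd.Series(dtype=bool)
    het = pd.DataFrame(traj, columns=["gen", "phase", "het"])
    H_w = eng.demes[0].H
    H_d = eng.demes[1].H if len(eng.demes) > 1 else eng.demes[0].H
    return ReplicateResult(site_table, het, H_w, H_d, eng.pos.copy(), eng.s.copy())


def run_scenario(config: SimConfig) -> SimResult:
    """Run all replicates of the scenario (deterministic per seed)."""
    reps = [_run_replicate(config, r) for r in range(config.replicates)]
    return SimResult(config, reps)


class WrightFisherModel:
    """Model-style front end around :func:`run_scenario`."""

    def __init__(self, config: SimConfig | None = None, **kwargs):
        self.config = config or SimConfig(**kwargs)

    def rescaled(self, lam: float) -> "WrightFisherModel":
        return WrightFisherModel(rescale(self.config, lam))

    def simulate(self) -> SimResult:
        return run_scenario(self.config)


# ---------------------------------------------------------------------------
# readouts

def fst_readout(
    result: SimResult,
    partition: str = "windows",
    window_size: int = 40_000,
    n_wild: int = 40,
    n_dom: int = 45,
    seed: int = 0,
) -> pd.DataFrame:
    """Weir-Cockerham FST summaries of the final generations.

    partition="windows": per (replicate, window) FST with a flag marking
    windows containing a beneficial mutation fixed in the domestic deme.
    partition="selected_sites"/"neutral_sites": per replicate, FST over
    the chosen site class (ratio of sums).
    """
    from .scan import _per_site_wc_components

    cfg = result.config
    rows = []
    for r, rep in enumerate(result.replicates):
        panel = rep.sample_panel(n_wild, n_dom, seed=seed + 1000 * r)
        if panel.n_sites == 0:
            continue
        a, d = _per_site_wc_components(panel)
        s_by_pos = dict(zip(rep.site_table["pos"], rep.site_table["s"]))
        site_s = np.array([s_by_pos.get(int(p), 0.0) for p in panel.pos])
        if partition == "windows":
            st = rep.site_table
            # differential beneficial fixations: swept to fixation in the
            # domestic deme while still absent/segregating in the wild one
            ben_fix = st[(st["s"] > 0) & (st["freq_dom"] == 1.0) & (st["freq_wild"] < 1.0)][
                "pos"
            ].to_numpy()
            for w0 in range(0, cfg.L - window_size + 1, window_size):
                idx = panel.sites_in("sim", w0, w0 + window_size)
                denom = d[idx].sum()
                fst = a[idx].sum() / denom if denom != 0 else np.nan
                rows.append(
                    {
                        "replicate": r,
                        "start": w0,
                        "end": w0 + window_size,
                        "n_snps": len(idx),
                        "fst": fst,
                        "has_beneficial_fixed": bool(
                            np.any((ben_fix > w0) & (ben_fix <= w0 + window_size))
                        ),
                    }
                )
        else:
            mask = site_s != 0 if partition == "selected_sites" else site_s == 0
            denom = d[mask].sum()
            rows.append(
                {
                    "replicate": r,
                    "partition": partition,
                    "n_snps": int(mask.sum()),
                    "fst": a[mask].sum() / denom if denom != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sved LD -> Ne

def estimate_ne_from_ld(
    r2,
    c,
    n_samples: int | None = None,
    n_bins: int | None = None,
) -> dict:
    """Sved's inversion Ne = (1/r^2 - 1)/(4c), per pair and aggregated.

    With ``n_samples`` (diploids) given, the sample-size inflation of r^2
    is removed first: r2_adj = r2 - 1/(2*n_samples).  Pairs with
    non-positive adjusted r^2 (infinite Ne) are skipped.  The aggregate is
    the harmonic mean of per-pair estimates, optionally also reported per
    recombination-fraction bin.
    """
    r2 = np.asarray(r2, dtype=float)
    c = np.asarray(c, dtype=float)
    if len(r2) == 0:
        raise ValueError("need at least one (r2, c) pair")
    if np.any((c <= 0) | (c > 0.5)):
        raise ValueError("recombination fractions must lie in (0, 0.5]")
    adjusted = n_samples is not None
    r2a = r2 - (1.0 / (2.0 * n_samples) if adjusted else 0.0)
    ok = r2a > 0
    if not ok.any():
        raise ValueError("all pairs have non-positive (adjusted) r^2")
    ne_pair = (1.0 / r2a[ok] - 1.0) / (4.0 * c[ok])
    ne_pair = np.maximum(ne_pair, 0.0)
    out = {"per_pair": ne_pair, "adjusted": adjusted}
    if n_bins and n_bins > 1:
        edges = np.quantile(c[ok], np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(edges, c[ok], side="right") - 1, 0, n_bins - 1)
        per_bin = []
        for b in range(n_bins):
            vals = ne_pair[which == b]
            vals = vals[vals > 0]
            per_bin.append(len(vals) / np.sum(1.0 / vals) if len(vals) else np.nan)
        out["per_bin"] = np.asarray(per_bin)
        vals = out["per_bin"][~np.isnan(out["per_bin"])]
        out["ne"] = float(len(vals) / np.sum(1.0 / vals))
    else:
        pos = ne_pair[ne_pair > 0]
        out["ne"] = float(len(pos) / np.sum(1.0 / pos)) if len(pos) else 0.0
    return out


# ---------------------------------------------------------------------------
# physics experiments (used by validation suites)

def _neutral_cfg(N: int, L: int = 1000, free_recombination: bool = True) -> SimConfig:
    return SimConfig(
        L=L, mu=0.0, rec=0.0, frac_beneficial=0.0, frac_deleterious=0.0,
        N_wild=N, N_dom=N, t_dom=0, burn_in=0, replicates=1,
        free_recombination=free_recombination,
    )


def _engine_from_frequencies(N: int, freqs: np.ndarray, rng, cfg: SimConfig) -> _Engine:
    eng = _Engine(cfg, rng)
    H = (rng.random((2 * N, len(freqs))) < freqs[None, :]).astype(np.uint8)
    eng.pos = np.arange(1, len(freqs) + 1, dtype=np.int64)
    eng.s = np.zeros(len(freqs))
    eng.origin = np.zeros(len(freqs), dtype=np.int32)
    eng.pos_to_col = {int(p): j for j, p in enumerate(eng.pos)}
    eng.demes = [_Deme(H)]
    return eng


def drift_het_decay(N: int, t: int, n_sites: int = 100, p0: float = 0.5, seed: int = 0) -> float:
    """One replicate's heterozygosity decay ratio h_t / h_0.

    Standing variation at frequency ``p0`` drifts for ``t`` generations
    with mutation off and sites unlinked; the expected ratio is
    (1 - 1/(2N))^t.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    cfg = _neutral_cfg(N, L=n_sites + 1)
    eng = _engine_from_frequencies(N, np.full(n_sites, p0), rng, cfg)
    f0 = eng.demes[0].H.mean(axis=0)
    h0 = float((2 * f0 * (1 - f0)).sum())
    if h0 == 0:
        return np.nan
    for _ in range(t):
        eng.gen += 1
        eng.demes[0].H = _offspring(eng.demes[0].H, eng.pos, eng.s, cfg, N, rng)
    f = eng.demes[0].H.mean(axis=0)
    return float((2 * f * (1 - f)).sum()) / h0


def fixation_experiment(
    N: int, s: float = 0.0, h: float = 0.5, n_trials: int = 1000, seed: int = 0,
    max_gens: int | None = None,
) -> float:
    """Fraction of single new mutations (initial count 1) reaching fixation."""
    cfg = replace(_neutral_cfg(N), frac_beneficial=0.0, h=h)
    max_gens = max_gens or 200 * N
    fixed = 0
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial]))
        H = np.zeros((2 * N, 1), dtype=np.uint8)
        H[rng.integers(0, 2 * N), 0] = 1
        s_arr = np.array([s])
        pos = np.array([1], dtype=np.int64)
        for _ in range(max_gens):
            H = _offspring(H, pos, s_arr, cfg, N, rng)
            tot = int(H[:, 0].sum())
            if tot == 0:
                break
            if tot == 2 * N:
                fixed += 1
                break
        else:
            warnings.warn("fixation trial hit max_gens; counted as not fixed", stacklevel=2)
    return fixed / n_trials


def split_drift_panel(
    N1: int, N2: int, t: int, n_sites: int = 200, n_sample1: int = 40, n_sample2: int = 45,
    seed: int = 0,
) -> GenotypePanel:
    """Two demes founded from common ancestral frequencies drifting
    independently for ``t`` generations (founding draw included), then
    sampled as a wild/dom panel.  Sites are unlinked and neutral."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    p0 = rng.uniform(0.05, 0.95, n_sites)
    cfg = _neutral_cfg(max(N1, N2), L=n_sites + 1)
    hs = []
    for N in (N1, N2):
        H = (rng.random((2 * N, n_sites)) < p0[None, :]).astype(np.uint8)
        pos = np.arange(1, n_sites + 1, dtype=np.int64)
        s_arr = np.zeros(n_sites)
        for _ in range(t - 1):
            H = _offspring(H, pos, s_arr, cfg, N, rng)
        hs.append(H)
    panels = []
    for H, n_samp, label in ((hs[0], n_sample1, "wild"), (hs[1], n_sample2, "dom")):
        hap = rng.integers(0, H.shape[0], size=2 * n_samp)  # gametes, with replacement
        panels.append((H[hap[0::2]] + H[hap[1::2]]).T.astype(np.int8))
    geno = np.concatenate(panels, axis=1)
    tot = geno.sum(axis=1)
    seg = (tot > 0) & (tot < 2 * geno.shape[1])
    samples = [f"wild_{i:02d}" for i in range(n_sample1)] + [f"dom_{i:02d}" for i in range(n_sample2)]
    return GenotypePanel(
        chrom=np.full(int(seg.sum()), "sim", dtype=object),
        pos=np.arange(1, n_sites + 1, dtype=np.int64)[seg],
        ref=np.full(int(seg.sum()), "A", dtype=object),
        alt=np.full(int(seg.sum()), "T", dtype=object),
        genotypes=geno[seg],
        samples=samples,
        pop_labels=np.array(["wild"] * n_sample1 + ["dom"] * n_sample2, dtype=object),
    )
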