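# Methods

`domsweep` maps artificial selection in a domesticated population against
its wild ancestor.  This note documents the statistical models, the
simulation machinery, the defaults and the design choices, in the order a
user meets them.

## Scan statistics

**Windows.**  The genome is cut into sliding windows (defaults 40 kb with
a 10-kb step, matching the scale of sweep footprints in livestock
resequencing panels; both are parameters).  A trailing partial window at a
chromosome end is dropped rather than truncated so per-bp diversity stays
comparable across windows.  Windows with 20 or fewer SNPs (strict
inequality; `min_snps`) are excluded from ranking.

**Nucleotide diversity.**  Per window,
`pi = sum_sites 2*p*(1-p) * n/(n-1) / L` with `n` the number of called
alleles at the site and `L` the full window length.  The per-site term is
the unbiased expected heterozygosity and equals the mean pairwise allele
difference, which the test suite verifies by exhaustive pair counting.
Using the full window length as denominator (no accessibility mask) is the
behaviour of the common windowed-diversity tools; masks are out of scope.

**FST.**  Weir & Cockerham's (1984) two-population variance-component
estimator, aggregated ratio-of-sums over the window
(`sum(a) / sum(a+b+c)`).  Missing genotypes drop out of the per-site
sample sizes; sites monomorphic across the combined panel contribute
nothing.  Negative window values are reported raw so ranking stays well
defined.

**ROD.**  `1 - pi_dom / pi_wild`, undefined (and excluded from ranking)
where the wild window diversity is zero.

**XP-CLR.**  A composite likelihood ratio in the spirit of Chen, Patterson
and Reich.  Per SNP, the domestic ("query") allele count is modelled given
the wild ("reference") frequency `p`:

* *Neutral*: the query frequency is Gaussian with mean `p` and variance
  `omega * p * (1-p)`, truncated to (0,1) with the truncated tails placed
  as point masses on the absorbing boundaries; the binomial sampling of the
  observed counts is integrated over this density (48-node Gauss-Legendre
  quadrature; an independent scipy adaptive-quadrature oracle agrees to
  1e-8 in the tests).
* *Sweep*: a favoured allele at the window centre fixed; a lineage at
  recombination distance `r` Morgans escapes the sweep with probability
  `q = 1 - exp(-r * T(s))`, `T(s) = ln(2Ns)/s` being the approximate sweep
  duration (`N` is `sweep_popsize`, default 10,000; `s <= 1/(2N)` is
  treated as neutral).  The post-sweep frequency is the two-point mixture:
  with probability `p` the swept haplotype carried the allele (mean
  `1-q+q*p`), else mean `q*p`, with the same drift noise around either.

The window score is `2 * (max_s CL(s) - CL(0))` over a fixed grid
(`0, 1e-4 ... 1e-1`); because 0 is in the grid the score is non-negative
by construction.  `omega` is estimated genome-wide by moment matching
`E[(p_dom - p_wild)^2] = omega * p_wild(1-p_wild)` after subtracting the
binomial sampling variance of both sample frequencies.  SNPs correlated in
the reference population (`r^2 > 0.95`) are down-weighted by one over
their cluster size; windows are thinned to at most 600 SNPs.  Genetic
positions come from an interpolated (chrom, pos, cM) map or a uniform
1 cM/Mb fallback.  All of these are package design choices exposed in
`XpclrModelConfig`; published XP-CLR implementations differ in exactly
these internals, so scores are comparable in rank, not in absolute value.

**Consensus and regions.**  Per statistic, the empirical
linear-interpolation quantile (default 0.95) over eligible windows defines
the threshold; "top 5%" means strictly greater.  A window is an outlier
when it exceeds the threshold for at least two of {FST, ROD, XP-CLR}.
Overlapping or book-ended outlier windows merge into sweep regions; genes
are assigned on >= 1 bp overlap of the TSS-TTS span with the half-open
region.

## Promoter selection

Genes are ranked by the Weir-Cockerham ratio-of-sums FST of their
strand-aware 2-kb upstream interval; the top 5% of genes with a defined
score (default `min_snps = 1`; single-SNP promoter scores are noisy, which
is why the knob exists) are flagged as having selected promoters.  Exact
ties with the threshold are excluded, keeping the selected set at or below
nominal size.  Upstream intervals overlapping a neighbouring gene body are
not trimmed; the overlap fraction is reported instead.

Gene-structure profiles place SNP statistics on a fixed grid — 4 kb
upstream in 1-kb bins, a length-normalised gene body (40 proportional
bins), 4 kb downstream — oriented so "upstream" is 5' for every gene.
Per gene, bins without SNPs are dropped; per-bin values (ratio-of-sums FST,
or per-bp `pi_wild - pi_dom` for diversity loss) are then averaged across
genes, each gene weighted equally.  Genes shorter than the bin count
simply occupy fewer proportional bins.

Fixed-SNP enrichment compares the fraction of sites with alt frequency
exactly 0 or 1 (over non-missing alleles; no tolerance) inside selected
upstream intervals against the genome-wide fraction, per population.

## Variant annotation

Positions classify as exon / intron / upstream / downstream / intergenic
with a 2-kb flank.  Gene-body categories beat flank categories; among
several candidate genes the nearest TSS wins, ties broken by gene id —
the behaviour of standard effect annotators.  TSS/TTS metaprofiles count
SNPs segregating within each population in strand-oriented 30-bp offset
bins; the default flank is 2010 bp so the bin width divides the profile
span exactly.

## Synthetic data

The generator emulates the study design at desk scale: one 1-Mb
chromosome, 300 compact genes (alternating strands, 2-8 exons), 40 wild +
45 domestic diploids, ~10 SNPs/kb (the density of a filtered two-species
resequencing callset).  Each gene's slot reserves a private 2-kb upstream
clearance, so promoters never overlap a neighbouring body — without this,
planting a sweep on one promoter would also "select" its divergent-pair
neighbour and the ground truth would be ill-defined.

Background differentiation is Balding-Nichols: ancestral frequency
~ U(0.05, 0.95), each population an independent Beta draw with drift
parameter `background_fst` (default 0.05, a weakly differentiated
wild/domestic pair; the real panel's value is a data property, hence a
knob).  A planted sweep pulls the domestic frequency toward fixation of
the ancestral-minor allele — the derived, favoured variant of a real
sweep — by `sweep_strength` (default 0.8), decaying linearly to zero over
`sweep_halfwidth` (default 2.5 kb, localising the core to the targeted
promoter).  Genotypes are Hardy-Weinberg draws; monomorphic sites are
dropped.  The generator carries no linkage disequilibrium; LD-bearing
panels come from the forward simulator.  DE tables give each gene x tissue
a DE flag whose odds are multiplied by `de_enrichment` for selected genes,
with padj uniform below/above the 0.05 boundary accordingly.

What passing recovery tests on these panels shows: the scan and ranking
machinery find frequency-differentiation signals of the planted size and
shape against Balding-Nichols noise.  What they do not show: robustness to
LD, allele-frequency-spectrum realism, missingness structure, or
population structure beyond the two-deme model.

## Forward simulation

A discrete-site, individual-based diploid Wright-Fisher model of the
domestication scenario: burn-in of the ancestral population (default
10*N generations), then a split into wild (N = 8433) and domestic
(N = 4502) demes — LD-based Sved estimates from the resequencing panels —
evolving independently for 2500 generations (one generation per year).
Mutations arise Poisson over a 608-kb noncoding segment at mu = 1.91e-9
per site per generation; 5% are beneficial (s = +0.05), 4% deleterious
(s = -0.001), the rest neutral.  Fitness is multiplicative across sites
with genotype values {1, 1+h*s, 1+s}, h = 0.5 (the cited class of forward
simulators defaults to semidominance; the source scenario states only s).
Parents are sampled proportional to fitness; gametes recombine with
Poisson(rec*L) crossovers at rec = 1e-8/bp.  Recurrent mutation at an
already-segregating site flips that haplotype's allele (finite sites);
mutations fixed in a deme leave the active matrix but stay in the record,
including their origin and fitness class.

Desk-scale runs rescale by `lam` (default CLI value 50): N/lam, t/lam,
mu*lam, rec*lam, s*lam, preserving 4*N*mu, N*s, N*r and t/N.  Note the
rescaled beneficial coefficient (s*lam = 2.5) leaves the diffusion regime;
sweeps complete in a few generations and hitchhiking spans the whole
segment.  That is a property of the full-scale scenario too (the
hitchhiking scale s/(r*ln(2Ns)) is ~0.7 Mb > 608 kb), which is why the
selection condition elevates FST segment-wide and comparisons are made
*between conditions* (selection vs bottleneck-only replicates), as in the
source experiment's per-condition replicate design, rather than between
windows within a selection replicate.

Sampled panels are built from gametes drawn with replacement, the binomial
sampling the Weir-Cockerham estimator assumes.  (Sampling diploids without
replacement from a small rescaled deme is hypergeometric; the estimator
then over-corrects by exactly one generation of drift — measurable at
desk scale, negligible in a real 8000-strong population.)

**Validation targets** (all Monte-Carlo, 3-SE bands): heterozygosity decay
`(1 - 1/(2N))^t`; neutral fixation probability `1/(2N)`; beneficial
fixation `2*h*s / (1 - exp(-4*N*h*s))` — the per-allele advantage of a
semidominant mutant is `h*s`, so the classic "2s" appears with `s`
read as the heterozygous effect; two-deme neutral FST
`1 - exp(-t/(2*N_h))` at t = 10, where the drift-approximation and
ratio-of-sums biases (~F^2/2) are an order of magnitude below Monte-Carlo
error.  These unit-scale checks run with unlinked sites
(`free_recombination`), isolating single-locus physics from genealogical
correlation.

**Sved Ne.**  From `E[r^2] = 1/(1 + 4Nc)`, each pair inverts to
`Ne = (1/r^2 - 1)/(4c)`; with a known sample size the `1/(2n)` inflation
of r^2 is removed first (flagged in the output).  Pairs are aggregated by
harmonic mean, optionally per recombination-fraction bin; exact inputs
round-trip exactly.

## Expression contrast

The DE-proportion question is a two-sided Fisher exact test on the 2x2
(selected/background x DE/not) table, DE meaning adjusted p < 0.05.  The
fold-change question uses Welch's unequal-variance t test on |log2FC| of
DE genes, up- and down-regulated strata separately ("parameter test" read
as the parametric two-sample test; a pooled-variance Student option
exists).  All strata of one invocation form a single Holm-Bonferroni
family; strata with fewer than two DE genes in either set are flagged and
excluded from the family.

## Lipid metrics

`UI = (sum %monoenes + 2*sum %dienes + 3*sum %trienes)/100` and
`U/S = %UFA / %SFA`.  The printed UI formula stops at trienes; by default
species with more than three double bonds are weighted by their actual
bond count (UI stays interpretable for tetraene-containing tissue), and a
strict mode caps the weight at 3.  Profiles are renormalised to 100% on
load, tolerating up to 0.1% instrument drift; larger discrepancies are
errors, not warnings.

## Problem sizes in the validation suites

The test suite and `scripts/acceptance.py` run the same studies at
different replication, chosen as the smallest sizes at which the
acceptance bands are statistically meaningful: sweep recovery over 8/30
seeds (suite/script), null scan calibration over 6/15, expression null
over 300/500 table draws, drift physics over 60-200 replicates, loop
closure over 4+4 / 10+10 condition replicates, XP-CLR localization over
10/20 seeds.  The recovery scenario scales the scan windows to 4 kb with
an 800-bp step, keeping the window:sweep-footprint ratio of the full-scale
40-kb scan on a 1-Mb toy genome.

## Known limitations

* The analytic generator has no LD, so LD-aware behaviour (XP-CLR
  down-weighting, Sved estimation from panel data) is exercised on
  forward-sim output only.
* XP-CLR absolute scores depend on the documented internals; only ranks
  and thresholds should be compared across implementations.
* The forward simulator tracks no genealogies (no tree-sequence output)
  and models a single uniform recombination rate.
* Window statistics assume biallelic SNPs; indels and SVs are out of
  scope, as is consequence-level annotation.
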