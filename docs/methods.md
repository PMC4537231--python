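# Methods

`ilsweep` analyses the mosaic of incomplete lineage sorting (ILS) along the X
chromosome of the human–chimpanzee–gorilla trio: megabase-scale regions where
ILS nearly vanishes, interpreted as footprints of strong selective sweeps in
the human–chimpanzee (HC) ancestral species. This note documents the models,
the parameter choices, the numerical decisions and what the synthetic-data
generators do and do not emulate.

## Coalescent ILS expectations

For two speciation events in quick succession, a locus is discordant with the
species tree when the H and C lineages fail to coalesce in the HC ancestor
(probability `exp(-Δτ/θ)` over a scaled interval Δτ with ancestral diversity
θ) and then pick one of the two discordant topologies among three equally
likely ones:

    Pr(ILS) = 2/3 · exp(-Δτ/θ).

With the published scaled estimates Δτ = 0.002468 and θ = 0.003232 this gives
31.06% for the autosomes and, with θ_X = 3/4·θ (male hemizygosity), 24.08%
for the X. `x_factor` is a parameter (default 3/4) so the autosomal and X
expectations share one code path. In generation units the same quantity is
`2/3·exp(-(ΔT/g)/(x·π))` with ΔT = 2.25 Myr, g = 20 yr (112,500 generations)
and π the population-scaled diversity of the ancestor (the role of 2·Ne_A);
`pi_from_ils` inverts it. All functions return fractions in [0, 1]; percent
formatting happens only at reporting time.

## Mixture model of the window-ILS distribution

Autosomal window-ILS values are unimodal and left-skewed (skew-normal fit via
`scipy.stats.skewnorm`). On the X the distribution is bimodal and modelled as

    f(x) = p·N(x; μ, σ) + (1-p)·Gamma(x; shape, rate),

fitted by direct bounded maximum likelihood (L-BFGS-B) on the transformed
parameters (logit p, μ, log σ, log shape, log rate) rather than EM — the
transform enforces the constraints and avoids the gamma M-step. Starting
points are deterministic: a moment split of the data at ILS = 0.125 (midway
between the two modes), a robust median/MAD Gaussian start, and near-pure
single-component starts whose inclusion guarantees the fitted mixture
dominates either single-component fit up to optimizer tolerance. Among
near-tied optima (within 2 log-likelihood units — possible for degenerate,
near-constant data where the component labels are interchangeable) the
solution with the Gaussian carrying the mass is preferred, matching the
high-ILS-mode interpretation. Exact zeros are nudged to half the smallest
positive observation before the gamma likelihood is evaluated (gamma support
is open at 0).

Confidence intervals are parametric bootstrap: pseudo-datasets of size `n`
(default: the fitted dataset's size) are sampled from the fitted mixture and
refitted; the interval is the equal-tail quantile range over converged
replicates, with failures counted and discarded. For the reported X fit
(p = 0.632, μ = 0.209, σ = 0.066, shape = 4.139, rate = 83.369) and n = 84 —
the number of 1-Mb windows in an 84-Mb alignment — 1,000 replicates at the
99% level give a Gaussian-mean interval of about [0.18, 0.25].

## Low-ILS region calling

Regions are maximal runs of 100-kb windows (sliding by 20 kb) that each show
at most 10% ILS, kept when the run spans at least 1 Mb. Windows with aligned
fraction below 0.5 are missing: they neither qualify nor break a run unless
the stretch without qualifying windows exceeds a gap tolerance (default 5 Mb,
wide enough to bridge a centromere). A well-aligned high-ILS window always
breaks a run; when the two flanking runs overlap (possible because window
span exceeds the step) they are trimmed at the overlap midpoint so regions
stay disjoint. The per-region mean ILS is averaged over the non-overlapping
100-kb decomposition of the region rather than the sliding windows, which
would double-count sites. Coordinates are 0-based half-open internally and in
BED output; GFF3 output is 1-based inclusive.

Two alignment diagnostics address the alternative explanation of a locally
reduced mutation rate: parsimony-informative triplet site patterns (a column
is informative for a pair when the pair shares one base and the remaining
ingroup species shares a different base with the outgroup — the outgroup must
agree with the singleton) and per-window HC/HG and HC/HO divergence ratios.

## Background selection

The classical reduction `π/π0 = exp(-U/(s+R))` with `U = u·d·L`, `R = r·L`
is contrasted inside versus outside the candidate regions by factors f_U,
f_s, f_R on the inside values. The selection coefficient that maximizes the
effect is the smallest admissible one: the formula loses validity when s
approaches 1/Ne, and with great-ape Ne of 1e4–1e5 the conservative floor is
s = 1e-5. The documented strongest parameterization uses u = 1.2e-8,
d_out = 0.015 (observed exon density outside), inside density twice the
observed 3.1% exon density, recombination 1.62 vs 1.01 cM/Mb (1 cM/Mb =
1e-8/bp/generation), f_s = 1 and L = 100 kb; the exact combination behind the
published inside/outside contrast is not printed, so this reconstruction is
the package's own and is required only to land within one percentage point.
The diversity ratio (0.940) maps through the ILS formula at the observed 21%
outside baseline (giving π0 ≈ 129,850 generations) to ≈19.5% inside: even the
most favourable background selection explains a couple of percentage points,
not the collapse to <5%. Per-window bounds use the window's exon density
(doubled) and deCODE-style recombination estimate with f_s = 0.1; windows
without a recombination estimate are skipped and counted.

## Sweep footprints

Hard sweeps start from one copy in a population of `n_chrom = 2N·3/4`
chromosomes (N = 73,200) and are conditioned on fixation by rejection
sampling of the Wright–Fisher binomial update with success probability
`k/(k + (n-k)(1-s))`. Soft sweeps join a neutral path from one copy —
conditioned to reach `F = f0·n_chrom`, truncated at a uniformly chosen upward
F-crossing (the overshooting binomial jump is snapped to F) — to a selected
path started at F.

Backward in time, two sequences sampled at fixation carry ancestral material
over one 10-cM flank of the selected site (the footprint is symmetric),
tracked in 0.01-cM bins. Each lineage recombines at most once per
generation, with probability equal to the genetic distance from the selected
site to the far end of its material: a crossover within the material splits
it (the detached piece re-draws its background with the current
selected-allele frequency), while a crossover between the site and the
material start moves the whole lineage onto a freshly drawn background —
since it is the selected-site allele of the carrying chromosome that
determines background membership. Restricting recombination to the material
span, as one might naively do, suppresses background switching at distant
loci and biases their TMRCA downward by ~25%; the implemented rule agrees
with an exact independent single-position two-lineage chain (kept as a test
oracle). Parents are drawn uniformly within the selected or unselected
background, so several lineages can merge in one generation, as happens when
the selected class is small.

Once the trajectory is exhausted, each still-uncoalesced bin receives an
independent Geometric(1/n_chrom) remainder. For a sample of two sequences
the per-position marginal coalescence law is exactly Geometric(1/n_chrom)
regardless of recombination (parents are exchangeable), and every reported
statistic — per-bin mean TMRCA, per-bin ILS fraction, footprint width —
depends only on per-bin marginals, so this replaces ~112,500 generations of
neutral coalescent-with-recombination per replicate exactly, not
approximately. Cross-bin correlations are the one thing the shortcut does
not preserve; nothing reported uses them.

A bin is called ILS with probability 2/3 when its TMRCA exceeds the
inter-speciation interval of 112,500 generations; the factor enters
analytically (the expectation of the Bernoulli calling rule). The footprint
width is the contiguous genetic length from the selected site with ILS below
5%, reported both one-sided and doubled ("surrounding" the site, the
symmetric region); physical lengths assume 1 cM/Mb. The neutral control
(2/3·exp(-112,500/109,800) = 0.239) matches the X-chromosome expectation. On
the grid s ∈ {0.01, 0.05, 0.1, 0.2, 0.4} the symmetric width reaches 1 Mb
only at s = 0.4 — a single sweep explains a megabase-wide ILS desert only
under implausibly strong selection, hence recurrent sweeps. Problem sizes:
the acceptance script uses 300 replicates per point for s ≤ 0.1 (long
trajectories, widths far below threshold) and 1,000–2,000 where the megabase
decision is made; the in-suite check uses 200 replicates per point.

## Interval permutation test

The overlap statistic is total intersection length in bp. Under the null the
query intervals are shuffled preserving each length: draw one breakpoint per
interval uniformly on [0, S] (S = chromosome length minus total query
length), sort, and insert the intervals in random order at the breakpoints;
ties give abutting intervals with zero gap. The reference set is never
moved, preserving its autocorrelation. The p-value is the plain count
fraction `#(overlap ≥ observed)/n_perm`; a `(k+1)/(n+1)` estimator is
available by flag, and a preserve-order flag keeps the original interval
order. Multi-chromosome inputs are shuffled per chromosome and overlaps
summed.

## Windowed diversity

Nucleotide diversity per site in non-overlapping 100-kb windows is computed
from allele counts (`2k(n-k)/(n(n-1))` per site). Windows without variants
are 0 (monomorphic), not missing. Diploid VCF genotypes split into two
haplotypes; hemizygous calls contribute one. Per-region summaries divide
mean window π inside by the mean outside all regions and attach a one-sided
Wilcoxon rank-sum test with Benjamini–Hochberg correction across regions;
significance codes follow the standard R convention (`***` <0.001, `**`
<0.01, `*` <0.05, `.` <0.1).

## Synthetic data

The generators are seeded, deterministic, and always return ground-truth
labels.

* **ILS tracks.** Values are generated once per 20-kb step — Gaussian
  component in neutral regimes, gamma component in planted low-ILS/sweep
  regions, with the reported X mixture as the default truth — and each
  sliding window reports the mean of the stretches it covers. Overlapping
  windows therefore share most of their values, emulating the strong
  autocorrelation of posterior-decoded tracks; with step = window the values
  are plain component draws. A second generator realizes window ILS as the
  discordant fraction of per-window block genealogies under the
  two-speciation coalescent, tying the track to Δτ and θ instead of a fitted
  distribution.
* **Triplet alignments.** Per block, the genealogy follows the
  two-speciation coalescent; sequences evolve by infinite sites on A/C/G/T
  (each mutation hits a fresh column, derived base differs), so every
  informative site supports its block's realized topology exactly and
  site-pattern classification has zero error by construction.
* **Haplotype panels.** Segregating-site counts are Poisson with mean
  π·L·a_n per window, derived-allele counts follow the neutral 1/k spectrum,
  so expected per-site π equals the target: 6e-4 for neutral X-linked
  sequence (typical of human X panels) and 40% of it in sweep regions
  (mid-range of observed reductions).
* **Interval fixtures.** Reference intervals on an even grid; each query
  interval straddles its reference's right edge to plant an exact overlap
  fraction.

What the generators do **not** emulate: CoalHMM posterior-decoding noise and
its window-to-window dependence beyond shared subwindows; mutation-rate and
alignment-quality variation along the chromosome; recombination hotspots;
linkage disequilibrium within haplotype panels (sites are independent);
population structure or demography in the panels; sequencing error. Passing
tests therefore demonstrate that each stage recovers a planted truth under
its own statistical assumptions — not that those assumptions hold for real
great-ape alignments.

## Numerical choices and degenerate inputs

Mixture fitting requires ≥20 finite values below 1; constant input is
rejected for the skew-normal (degenerate scale). Optimizer non-convergence
returns parameters with `converged=False`; bootstrap replicates that fail
are discarded and counted. Region calling validates window geometry
(constant width, starts on the step grid) and returns an empty set for an
empty track. An empty query set yields p = 1 with a warning in the
permutation test; a query as long as the chromosome is rejected. Sweep
trajectories have a configurable rejection budget and raise with diagnostics
when exhausted; a hard cap guards against runaway lineage counts.
`footprint_from_tmrca` with threshold 1.0 degenerates to the full flank, as
ILS fractions cannot exceed 2/3.

## Known limitations

* The sweep simulator samples the two sequences at the moment of fixation,
  the configuration that maximizes the sweep's imprint; sweeps older than
  the speciation event would leave weaker footprints.
* Footprint widths from the aggregated ILS profile are a step function of
  the bin size (0.01 cM) and carry Monte-Carlo jitter near the 5% threshold;
  replicate counts are chosen so the megabase decision is stable.
* The background-selection treatment is purely analytic (no interference
  between selected sites, no simulation).
* The permutation test treats each chromosome independently; reference
  intervals are assumed correct and are never randomized.
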