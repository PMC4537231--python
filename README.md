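# ilsweep

Tools for analysing incomplete lineage sorting (ILS) between human,
chimpanzee and gorilla, and for testing what shaped it: megabase-scale
regions of the X chromosome are almost devoid of ILS, which points to
severely reduced diversity in the human–chimpanzee ancestral species.
`ilsweep` implements the full analysis chain at desk scale — coalescent
expectations, distribution fitting, region calling, an analytic
background-selection bound, a structured-coalescent sweep simulator, interval
permutation tests and windowed diversity — together with seeded synthetic
generators so every stage is testable without downloading genome alignments.

## The models in brief

**ILS expectation.** For speciation events separated by a scaled interval Δτ
in an ancestor with scaled diversity θ,

    Pr(ILS) = 2/3 · exp(−Δτ/θ),

two of the three topologies that arise from deep coalescence being
discordant. With Δτ = 0.002468 and θ = 0.003232 this gives 31.06% for the
autosomes; with the X carrying 3/4 of the autosomal effective population it
gives 24.08%.

**Mixture of the window-ILS distribution.** On the X the distribution of
per-window ILS is bimodal and is fitted as p·Normal(μ, σ) +
(1−p)·Gamma(shape, rate) by bounded maximum likelihood, with
parametric-bootstrap confidence intervals.

**Background selection.** Linked purifying selection reduces diversity by
π/π0 = exp(−U/(s+R)); contrasting inside versus outside the low-ILS regions
and mapping through the ILS formula bounds how much of the reduction it can
explain.

**Sweep footprints.** Allele-frequency trajectories conditioned on fixation
(rejection-sampled Wright–Fisher with selection) drive a backward structured
coalescent with recombination for two sequences over a 10-cM flank; segments
whose TMRCA exceeds the inter-speciation interval (112,500 generations) are
ILS with probability 2/3, and the width of the <5%-ILS region around the
selected site measures the footprint.

**Interval association.** A Monte-Carlo test shuffles query intervals
(lengths preserved, reference fixed) and compares overlap in bp.

## Worked example

```python
import ilsweep as iw

# expectation: how much ILS should the X show?
print(round(100 * iw.expected_ils(0.002468, 0.75 * 0.003232), 2))  # 24.08

# simulate an X-like windowed track with two planted low-ILS regions
cfg = iw.SimConfig(seed=4, chrom_length=25_000_000, step_bp=20_000,
                   planted_regions=[(3_000_000, 7_000_000, "low_ils"),
                                    (14_000_000, 19_500_000, "sweep")])
track, _ = iw.simulate_ils_windows(cfg)
regions = iw.call_low_ils_regions(track)
print(regions.intervals[["start", "end", "mean_ils"]])
```

prints

```
      start       end  mean_ils
0   2980000   7020000  0.051322
1  13980000  19540000  0.050509
```

— both planted regions are recovered with boundaries within one 100-kb
window, and their mean ILS sits at the gamma-mode level (~5%), far below the
~21% of the rest of the chromosome. Continuing,

```python
ratio = iw.bgs_diversity_ratio(iw.BgsParams.conservative_x())
print(round(100 * iw.bgs_relative_ils(ratio, iw.IlsBaseline(0.21),
                                      iw.GenerationDemography()), 1))  # 19.5
```

shows that even the most favourable background-selection parameterization
moves the 21% baseline only to 19.5% — nowhere near the observed <5% — while

```python
fp = iw.sweep_footprint(iw.AncestralDemographyX(), s=0.4, replicates=150, seed=3)
print(fp.width_surrounding_mb)  # 0.94
```

shows that even a sweep with s = 0.4 barely carves a megabase-wide ILS
desert, so the observed multi-megabase regions require recurrent sweeps.

The `examples/` directory contains one short script per capability
(expectations, mixture fitting, region calling, background selection, sweep
footprints, interval tests, windowed diversity); each builds a small input,
runs the method and prints annotated numbers.

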