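"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is seeded, deterministic, and returns ground-truth labels
alongside the data, so each analysis stage can be tested for recovery of a
planted truth without any external download:

* windowed ILS tracks whose values come from the two-component truth (a
  Gaussian high-ILS mode in neutral regimes, a gamma low-ILS mode in planted
  regions) or, alternatively, from realized block genealogies under the
  two-speciation coalescent;
* four-taxon alignment blocks with per-block topology labels, mutated under
  an infinite-sites scheme so site-pattern classification is exact;
* haplotype panels whose windowed diversity matches a target pi, with planted
  sweep regions at a stated fraction of it;
* interval fixtures with a planted query/reference overlap fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import ScaledDemography, expected_ils
from .diversity import HaplotypePanel
from .intervals import IntervalSet, overlap_bp
from .mixture import MixtureFit
from .regions import IlsTrack

__all__ = [
    "DEFAULT_X_MIXTURE",
    "SimConfig",
    "simulate_ils_windows",
    "simulate_ils_windows_genealogical",
    "simulate_triplet_alignment",
    "simulate_haplotype_panel",
    "simulate_interval_fixture",
]

#: Two-component truth used as the generator default: the reported mixture
#: describing the X-chromosome window-ILS distribution (Gaussian high-ILS
#: mode at 0.209, gamma low-ILS mode with mean 0.0497, weight 0.632 on the
#: Gaussian).
DEFAULT_X_MIXTURE = MixtureFit(p=0.632, mu=0.209, sigma=0.066, shape=4.139, rate=83.369)


@dataclass
class SimConfig:
    """Shared configuration for the synthetic generators.

    ``planted_regions`` is a list of ``(start, end, regime)`` with regime in
    {"neutral", "low_ils", "sweep"}; unlisted territory is neutral.  The
    per-regime diversity targets are per-site pi: 6e-4 for neutral X-linked
    sequence (typical of human X panels) and 40% of it inside sweep regions
    (the middle of the observed range of relative reductions).
    """

    seed: int = 0
    chrom_length: int = 20_000_000
    window_bp: int = 100_000
    step_bp: int | None = None
    mixture: MixtureFit = field(default_factory=lambda: DEFAULT_X_MIXTURE)
    planted_regions: list = field(default_factory=list)
    pi_neutral: float = 6e-4
    sweep_relative_diversity: float = 0.4
    chrom: str = "chrX"

    def __post_init__(self) -> None:
        if self.step_bp is None:
            self.step_bp = self.window_bp
        prev_end = -1
        for start, end, regime in self.planted_regions:
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError("planted regions must lie within the chromosome")
            if start < prev_end:
                raise ValueError("planted regions must be disjoint and sorted")
            if regime not in ("neutral", "low_ils", "sweep"):
                raise ValueError(f"unknown regime {regime!r}")
            prev_end = end

    def regime_at(self, pos: float) -> str:
        for start, end, regime in self.planted_regions:
            if start <= pos < end:
                return regime
        return "neutral"

    def pi_target(self, regime: str) -> float:
        if regime == "sweep":
            return self.pi_neutral * self.sweep_relative_diversity
        return self.pi_neutral


def _window_grid(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, config.chrom_length - config.window_bp + 1, config.step_bp)
    return starts, starts + config.window_bp


def simulate_ils_windows(config: SimConfig) -> tuple[IlsTrack, pd.DataFrame]:
    """Windowed ILS track sampled from the mixture truth, plus regime labels.

    ILS is generated once per ``step_bp`` stretch of sequence — from the
    Gaussian component in neutral regimes, from the gamma component in
    low-ILS and sweep regimes — and each (possibly sliding) window reports
    the mean of the stretches it covers.  Overlapping windows therefore share
    most of their underlying values and are strongly autocorrelated, as
    posterior-decoded ILS tracks are; with ``step_bp == window_bp`` the
    values are plain component draws.
    """
    rng = np.random.default_rng(config.seed)
    step = config.step_bp
    n_sub = config.window_bp // step
    if config.window_bp % step != 0:
        raise ValueError("window_bp must be a multiple of step_bp")
    sub_starts = np.arange(0, config.chrom_length - step + 1, step)
    sub_mid = sub_starts + step / 2.0
    sub_regimes = np.array([config.regime_at(m) for m in sub_mid])
    m = config.mixture
    sub_ils = np.empty(len(sub_starts))
    neutral = sub_regimes == "neutral"
    sub_ils[neutral] = rng.normal(m.mu, m.sigma, size=int(neutral.sum()))
    sub_ils[~neutral] = rng.gamma(m.shape, 1.0 / m.rate, size=int((~neutral).sum()))
    sub_ils = np.clip(sub_ils, 0.0, 1.0 - 1e-9)

    starts, ends = _window_grid(config)
    n_win = len(starts)
    window_ils = np.array([sub_ils[i : i + n_sub].mean() for i in range(n_win)])
    # a window's regime label is that of the majority of its stretches
    regimes = []
    for i in range(n_win):
        vals, cnt = np.unique(sub_regimes[i : i + n_sub], return_counts=True)
        regimes.append(vals[np.argmax(cnt)])
    track = IlsTrack.from_arrays(config.chrom, starts, ends, window_ils)
    labels = pd.DataFrame({"start": starts, "end": ends, "regime": regimes})
    return track, labels


def simulate_ils_windows_genealogical(
    demog: ScaledDemography,
    n_windows: int = 100,
    blocks_per_window: int = 100,
    window_bp: int = 100_000,
    chrom: str = "chrA",
    seed: int | np.random.Generator | None = None,
) -> tuple[IlsTrack, pd.DataFrame]:
    """Windowed ILS as the realized discordance of simulated block genealogies.

    Each window contains ``blocks_per_window`` independent recombination
    blocks; a block is discordant with probability ``2/3 * exp(-Δτ/θ)``
    (no coalescence in the first ancestral interval, then one of the two
    discordant topologies).  The returned window values therefore tie the
    track directly to the coalescent parameters rather than to a fitted
    distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_disc = expected_ils(demog.delta_tau, demog.theta_hc)
    discordant = rng.binomial(blocks_per_window, p_disc, size=n_windows)
    ils = discordant / blocks_per_window
    starts = np.arange(n_windows) * window_bp
    track = IlsTrack.from_arrays(chrom, starts, starts + window_bp, ils)
    labels = pd.DataFrame(
        {"start": starts, "end": starts + window_bp, "n_discordant": discordant,
         "n_blocks": blocks_per_window}
    )
    return track, labels


def simulate_triplet_alignment(
    demog: ScaledDemography,
    n_blocks: int = 200,
    block_bp: int = 500,
    u_scale: float = 1.0,
    outgroup_factor: float = 4.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Four-taxon alignment blocks with per-block topology labels.

    Per block, the genealogy follows the two-speciation coalescent: the human
    and chimpanzee lineages coalesce within their own ancestor with
    probability ``1 - exp(-Δτ/θ_HC)`` (topology "HC"); otherwise the first
    coalescence in the deeper ancestor picks one of "HC", "HG", "CG"
    uniformly.  Sequences evolve by an infinite-sites scheme (every mutation
    hits a fresh column, derived base differs from the ancestral one), so no
    informative site is ever overwritten.  ``u_scale`` multiplies all branch
    lengths; 0 yields an invariant alignment.

    Returns the concatenated sequences keyed "human", "chimp", "gorilla",
    "orang", and the per-block topology labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if u_scale < 0:
        raise ValueError("u_scale must be non-negative")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    leaves = ("human", "chimp", "gorilla", "orang")
    pair_members = {"HC": ("human", "chimp"), "HG": ("human", "gorilla"), "CG": ("chimp", "gorilla")}
    out: dict[str, list[np.ndarray]] = {name: [] for name in leaves}
    labels: list[str] = []

    tau_root = outgroup_factor * demog.tau_hcg
    for _ in range(n_blocks):
        e = rng.exponential(demog.theta_hc)
        if e < demog.delta_tau:
            topo = "HC"
            t1 = demog.tau_hc + e
            t2 = demog.tau_hcg + rng.exponential(demog.theta_hcg)
        else:
            topo = ("HC", "HG", "CG")[int(rng.integers(3))]
            t1 = demog.tau_hcg + rng.exponential(demog.theta_hcg / 3.0)
            t2 = t1 + rng.exponential(demog.theta_hcg)
        t_root = max(t2, tau_root) + rng.exponential(demog.theta_hcg)
        labels.append(topo)

        a, b = pair_members[topo]
        third = next(n for n in ("human", "chimp", "gorilla") if n not in (a, b))
        # branch lengths in expected substitutions per site
        branches = {
            (a,): t1,
            (b,): t1,
            (third,): t2,
            (a, b): t2 - t1,
            (a, b, third): t_root - t2,
            ("orang",): t_root,
        }

        root_seq = rng.choice(bases, size=block_bp)
        block = {name: root_seq.copy() for name in leaves}
        n_mut = {clade: rng.poisson(length * block_bp * u_scale) for clade, length in branches.items()}
        total = sum(n_mut.values())
        if total > block_bp:
            raise ValueError(
                "more mutations than sites in a block; lower u_scale or raise block_bp"
            )
        sites = rng.choice(block_bp, size=total, replace=False)
        cursor = 0
        for clade, k in n_mut.items():
            for pos in sites[cursor : cursor + k]:
                current = block[clade[0]][pos]
                derived = bases[bases != current][int(rng.integers(3))]
                for name in clade:
                    block[name][pos] = derived
            cursor += k
        for name in leaves:
            out[name].append(block[name])

    seqs = {name: b"".join(chunk.tobytes() for chunk in chunks).decode("ascii")
            for name, chunks in out.items()}
    return seqs, labels


def simulate_haplotype_panel(
    config: SimConfig,
    n_haplotypes: int = 20,
    population: str = "SIM",
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Haplotype panel whose windowed diversity matches per-regime targets.

    Within each non-overlapping window the number of segregating sites is
    Poisson with mean ``pi_target * window_bp * a_n`` (Watterson's constant
    ``a_n``), positions are uniform, and derived-allele counts follow the
    neutral frequency spectrum (probability proportional to 1/k) — so the
    expected per-site pi equals the target.  Sweep regions use
    ``sweep_relative_diversity`` times the neutral target.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    rng = np.random.default_rng(config.seed)
    n = n_haplotypes
    ks = np.arange(1, n)
    sfs = (1.0 / ks) / np.sum(1.0 / ks)
    a_n = float(np.sum(1.0 / ks))

    starts = np.arange(0, config.chrom_length, config.window_bp)
    truth_rows = []
    positions: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    for start in starts:
        end = min(start + config.window_bp, config.chrom_length)
        regime = config.regime_at((start + end) / 2.0)
        target = config.pi_target(regime)
        n_sites = rng.poisson(target * (end - start) * a_n)
        n_sites = min(n_sites, end - start)
        pos = np.sort(rng.choice(end - start, size=n_sites, replace=False)) + start
        positions.append(pos)
        counts.append(rng.choice(ks, size=n_sites, p=sfs))
        truth_rows.append({"start": start, "end": end, "regime": regime, "pi_target": target})

    all_pos = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
    all_counts = np.concatenate(counts) if counts else np.array([], dtype=np.int64)
    hap = np.zeros((n, all_pos.size), dtype=np.int8)
    for j, k in enumerate(all_counts):
        carriers = rng.choice(n, size=int(k), replace=False)
        hap[carriers, j] = 1
    panel = HaplotypePanel(all_pos, hap, population=population, chrom=config.chrom)
    return panel, pd.DataFrame(truth_rows)


def simulate_interval_fixture(
    chrom_length: int,
    n_query: int = 8,
    lengths: Sequence[int] | int = 200_000,
    planted_overlap_fraction: float = 0.5,
    seed: int | np.random.Generator | None = None,
    reference_length: int | None = None,
    chrom: str = "chrX",
) -> tuple[IntervalSet, IntervalSet]:
    """Query and reference interval sets with a planted overlap fraction.

    Reference intervals are fixed on an even grid; each query interval is
    placed so that ``round(planted_overlap_fraction * length)`` of its bp
    fall inside its designated reference interval (straddling its right
    edge).  Raises if the requested geometry is infeasible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not (0.0 <= planted_overlap_fraction <= 1.0):
        raise ValueError("planted_overlap_fraction must lie in [0, 1]")
    if isinstance(lengths, (int, np.integer)):
        lengths = [int(lengths)] * n_query
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_query:
        raise ValueError("need one length per query interval")
    if reference_length is None:
        reference_length = 2 * max(lengths)

    slot = chrom_length // n_query
    if reference_length + max(lengths) + 2 > slot:
        raise ValueError("chromosome too short for the requested fixture")
    ref_starts = np.arange(n_query) * slot + slot // 4
    ref_ends = ref_starts + reference_length
    reference = IntervalSet(chrom, ref_starts, ref_ends)

    q_starts, q_ends = [], []
    for i, L in enumerate(lengths):
        o = int(round(planted_overlap_fraction * L))
        if o > min(L, reference_length):
            raise ValueError("requested overlap exceeds interval or reference length")
        if o > 0:
            start = int(ref_ends[i]) - o
        else:
            start = int(ref_ends[i]) + (slot - slot // 4 - reference_length - L) // 2
            start = max(start, int(ref_ends[i]) + 1)
        end = start + L
        if end > chrom_length or (i + 1 < n_query and end > ref_starts[i + 1]):
            raise ValueError("fixture infeasible: query spills into the next slot")
        q_starts.append(start)
        q_ends.append(end)
    query = IntervalSet(chrom, np.array(q_starts), np.array(q_ends))

    planted = sum(int(round(planted_overlap_fraction * L)) for L in lengths)
    if overlap_bp(query, reference) != planted:
        raise AssertionError("internal error: planted overlap not achieved")
    return query, reference
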