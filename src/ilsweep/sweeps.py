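"""Selective-sweep footprints on ILS in the human–chimpanzee ancestor.

A beneficial variant that fixes in the HC ancestral population drags linked
variation with it: near the selected site the two sampled sequences coalesce
during the sweep, long before the HC–gorilla speciation interval has elapsed
backward in time, so the locus cannot show incomplete lineage sorting.  The
footprint narrows with genetic distance as recombination lets lineages escape
the sweeping background.

The machinery has three parts:

1. :func:`sample_fixation_trajectory` draws an allele-frequency path
   conditioned on fixation by rejection sampling of a Wright–Fisher binomial
   process with selection (hard sweeps start from one copy; soft sweeps join a
   neutral path, truncated at a random upward crossing of the standing
   frequency, to a selected path started there).
2. :func:`simulate_sweep_tmrca` runs a discrete, structured
   coalescent-with-recombination backward through the trajectory for a sample
   of two sequences spanning one 10-cM flank of the selected site, tracking
   ancestral material in 10-kb (0.01 cM) bins.  Each lineage recombines at
   most once per generation, with probability equal to the genetic distance
   from the selected site to the far end of its material (a crossover anywhere
   in that stretch either splits the material or moves the lineage onto a
   freshly drawn background — it is the selected-site allele that determines
   which background a chromosome belongs to); parents are chosen uniformly
   within the selected or unselected background, so simultaneous multiple
   mergers can occur.  Once
   the trajectory is exhausted, each still-uncoalesced bin receives an
   independent Geometric(1/n_chrom) neutral remainder — the exact per-bin
   marginal TMRCA law for a two-sequence sample, which is all the reported
   statistics depend on.
3. :func:`footprint_from_tmrca` converts replicate TMRCA profiles into an ILS
   profile (a segment is ILS with probability 2/3 when its TMRCA exceeds the
   inter-speciation interval) and measures the width of the region with ILS
   below a threshold around the selected site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AncestralDemographyX",
    "Trajectory",
    "SweepFootprint",
    "sample_fixation_trajectory",
    "simulate_sweep_tmrca",
    "neutral_tmrca",
    "footprint_from_tmrca",
    "sweep_footprint",
    "sweep_footprint_grid",
]


@dataclass(frozen=True)
class AncestralDemographyX:
    """X-chromosome demography of the human–chimpanzee ancestor.

    Defaults: diploid Ne = 73,200 (so the X carries ``2*Ne*3/4 = 109,800``
    chromosomes), HC speciation 3.7 Myr and HCG speciation 5.95 Myr at 20-year
    generations (inter-speciation interval 112,500 generations), mutation rate
    1e-9 per site per generation, a 10-cM sampled flank in 0.01-cM (10-kb)
    bins, and 1 cM/Mb to convert genetic to physical length.
    """

    Ne: float = 73_200.0
    t_hc_years: float = 3.7e6
    t_hcg_years: float = 5.95e6
    g: float = 20.0
    u: float = 1e-9
    segment_genetic_length_cm: float = 10.0
    r_cm_per_mb: float = 1.0
    bin_cm: float = 0.01

    def __post_init__(self) -> None:
        if self.t_hcg_years <= self.t_hc_years:
            raise ValueError("t_hcg_years must exceed t_hc_years")
        for name in ("Ne", "g", "u", "segment_genetic_length_cm", "r_cm_per_mb", "bin_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_chrom(self) -> int:
        """Population size in X chromosomes, ``2*Ne*3/4``."""
        return int(round(2 * self.Ne * 0.75))

    @property
    def delta_tau_generations(self) -> float:
        """Generations between the HC and HCG speciation events."""
        return (self.t_hcg_years - self.t_hc_years) / self.g

    @property
    def n_bins(self) -> int:
        return int(round(self.segment_genetic_length_cm / self.bin_cm))


@dataclass(frozen=True)
class Trajectory:
    """Allele-frequency path of a variant conditioned on fixation.

    ``counts[t]`` is the number of chromosomes carrying the selected allele at
    forward generation ``t``; the path starts at one copy and ends at
    ``n_chrom`` (fixation).  For soft sweeps, ``onset_index`` marks the
    generation at which selection begins (the standing frequency ``f0`` is
    reached); it is 0 for hard sweeps.
    """

    counts: np.ndarray
    n_chrom: int
    s: float
    f0: float
    mode: Literal["hard", "soft"]
    onset_index: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts[-1] != self.n_chrom:
            raise ValueError("trajectory must end at fixation (n_chrom copies)")
        if counts[0] != 1:
            raise ValueError("trajectory must begin at one copy")
        if np.any(counts <= 0) or np.any(counts > self.n_chrom):
            raise ValueError("counts must stay in (0, n_chrom]")

    @property
    def duration(self) -> int:
        """Number of generations from the first copy to fixation."""
        return len(self.counts) - 1


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _neutral_path_through(
    rng: np.random.Generator, n: int, target: int, max_attempts: int
) -> np.ndarray:
    """Neutral WF path from one copy conditioned to reach ``target`` copies,
    truncated at a uniformly chosen upward crossing of ``target``."""
    for _ in range(max_attempts):
        path = [1]
        k = 1
        crossings = []
        while 0 < k < n:
            prev = k
            k = int(rng.binomial(n, k / n))
            path.append(k)
            if prev < target <= k:
                crossings.append(len(path) - 1)
        if crossings:
            cut = crossings[int(rng.integers(len(crossings)))]
            out = np.array(path[: cut + 1], dtype=np.int64)
            out[-1] = target  # snap the overshooting binomial jump to F
            return out
    raise RuntimeError(
        f"rejection budget exhausted: no neutral path reached {target} copies "
        f"in {max_attempts} attempts"
    )


def sample_fixation_trajectory(
    demog: AncestralDemographyX,
    s: float,
    mode: Literal["hard", "soft"] = "hard",
    f0: float | None = None,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 1_000_000,
) -> Trajectory:
    """Sample a selected-allele trajectory conditioned on fixation.

    Hard sweeps start from a single copy under selection and are rejected
    until one fixes; the per-generation update is binomial with success
    probability ``k/(k + (n-k)(1-s))``.  Soft sweeps first draw a neutral path
    from one copy conditioned to reach ``F = round(f0*n_chrom)`` at least
    once, truncate it at a random upward F-crossing, and append a selected
    path started at ``F`` and conditioned on fixation.
    """
    if not (0.0 < s <= 1.0):
        raise ValueError("s must lie in (0, 1]")
    rng = _as_rng(seed)
    n = demog.n_chrom

    if mode == "soft":
        if f0 is None:
            raise ValueError("soft sweeps require f0")
        F = int(round(f0 * n))
        if not (1 <= F < n):
            raise ValueError("f0 must satisfy 1/n_chrom <= f0 < 1")
    elif mode == "hard":
        F = 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # selected segment: from F copies to fixation, rejection-sampled
    for _ in range(max_attempts):
        k = F
        sel = [k]
        while 0 < k < n:
            p = k / (k + (n - k) * (1.0 - s))
            k = int(rng.binomial(n, p))
            sel.append(k)
        if k == n:
            break
    else:
        raise RuntimeError(
            f"rejection budget exhausted: no fixing trajectory in {max_attempts} "
            f"attempts (s={s}, F={F}, n_chrom={n})"
        )
    selected = np.array(sel, dtype=np.int64)

    if F == 1:
        counts = selected
        onset = 0
    else:
        pre = _neutral_path_through(rng, n, F, max_attempts)
        counts = np.concatenate([pre[:-1], selected])
        onset = len(pre) - 1
    return Trajectory(
        counts=counts, n_chrom=n, s=s, f0=F / n, mode=mode, onset_index=onset
    )


def simulate_sweep_tmrca(
    traj: Trajectory | None,
    demog: AncestralDemographyX,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-bin TMRCA (generations) of two sequences sampled at fixation.

    One flank of the selected site is tracked in ``demog.n_bins`` genetic
    bins (the sweep's effect is symmetric, so one side suffices).  Passing
    ``traj=None`` runs the neutral control: every bin's TMRCA is then a plain
    Geometric(1/n_chrom) draw, the marginal coalescence-time law of two
    Wright–Fisher lineages.
    """
    rng = _as_rng(seed)
    n = demog.n_chrom
    B = demog.n_bins
    if traj is None:
        return rng.geometric(1.0 / n, size=B).astype(float)
    if traj.n_chrom != n:
        raise ValueError("trajectory and demography disagree on n_chrom")

    # genetic positions (Morgans): index 0 = selected site, 1..B bin centres
    pos = np.empty(B + 1)
    pos[0] = 0.0
    pos[1:] = (np.arange(B) + 0.5) * demog.bin_cm / 100.0
    pos_flat = np.concatenate([pos, pos])

    # lineage id carried by each sample copy at each position; -1 = coalesced
    lin = np.empty(2 * (B + 1), dtype=np.int64)
    lin[: B + 1] = 0
    lin[B + 1 :] = 1

    cap = 4096
    bg = np.zeros(cap, dtype=np.int8)  # 0 = selected background, 1 = neutral
    next_id = 2
    tmrca = np.full(B + 1, np.nan)

    counts = traj.counts
    T = len(counts) - 1
    max_lineages = 2 * (B + 1)

    for j in range(1, T + 1):
        k_child = int(counts[T - j + 1])
        k_parent = int(counts[T - j])
        freq = k_child / n

        act = lin >= 0
        ids, inv_act = np.unique(lin[act], return_inverse=True)
        m = len(ids)
        if m == 0:
            break
        if m > max_lineages:
            raise RuntimeError("lineage count exceeded hard cap")

        # recombination-relevant genetic length per lineage: from the selected
        # site (which fixes the background) to the far end of its material —
        # a crossover below the material start does not split anything but
        # moves the whole lineage onto a freshly drawn background
        p_act = pos_flat[act]
        hi = np.full(m, -np.inf)
        np.maximum.at(hi, inv_act, p_act)

        # at most one recombination event per lineage per generation
        rec = rng.random(m) < np.minimum(hi, 1.0)
        nrec = int(rec.sum())
        if nrec:
            bp = rng.random(m) * hi
            new_id_of = np.full(m, -1, dtype=np.int64)
            new_id_of[rec] = next_id + np.arange(nrec)
            while next_id + nrec > cap:
                bg = np.concatenate([bg, np.zeros(cap, dtype=np.int8)])
                cap *= 2
            # detached piece re-draws its background at the current frequency
            bg[next_id : next_id + nrec] = (rng.random(nrec) >= freq).astype(np.int8)
            detach = rec[inv_act] & (p_act > bp[inv_act])
            sub = lin[act]
            sub[detach] = new_id_of[inv_act[detach]]
            lin[act] = sub
            next_id += nrec
            ids, inv_act = np.unique(lin[act], return_inverse=True)
            m = len(ids)

        # coalescence: uniform parent within each background; multiple
        # lineages drawing the same parent merge simultaneously
        bgs = bg[ids]
        on_sel = bgs == 0
        parents = np.empty(m, dtype=np.int64)
        parents[on_sel] = rng.integers(max(k_parent, 1), size=int(on_sel.sum()))
        parents[~on_sel] = rng.integers(max(n - k_parent, 1), size=int((~on_sel).sum()))
        key = bgs.astype(np.int64) * (n + 1) + parents
        uniq, ginv = np.unique(key, return_inverse=True)
        if len(uniq) < m:
            rep = np.full(len(uniq), m, dtype=np.int64)
            np.minimum.at(rep, ginv, np.arange(m))
            mapping = ids[rep]  # representative id per parent group
            lin[act] = mapping[ginv][inv_act]

        # record coalescence where both sample copies share a lineage
        l0 = lin[: B + 1]
        l1 = lin[B + 1 :]
        both = (l0 >= 0) & (l0 == l1)
        if both.any():
            tmrca[both] = j
            l0[both] = -1
            l1[both] = -1

        if not (np.any(l0[1:] >= 0) or np.any(l1[1:] >= 0)):
            break

    # neutral remainder for bins not coalesced during the sweep phase
    out = tmrca[1:].copy()
    open_bins = np.isnan(out)
    if open_bins.any():
        out[open_bins] = T + rng.geometric(1.0 / n, size=int(open_bins.sum()))
    return out


def neutral_tmrca(
    demog: AncestralDemographyX,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Neutral control: per-bin TMRCA without any sweep."""
    return simulate_sweep_tmrca(None, demog, seed)


@dataclass(frozen=True)
class SweepFootprint:
    """Binned ILS footprint of a sweep, aggregated over replicates.

    ``ils_fraction[b]`` is ``2/3`` times the fraction of replicates whose bin
    ``b`` TMRCA exceeds the inter-speciation interval.  ``width_below_cm`` is
    the contiguous genetic length, extending away from the selected site, with
    ILS below the threshold (one-sided); ``width_surrounding_cm`` doubles it
    for the symmetric region around the site.
    """

    bin_edges_cm: np.ndarray
    mean_tmrca: np.ndarray
    ils_fraction: np.ndarray
    threshold: float
    width_below_cm: float
    r_cm_per_mb: float
    n_replicates: int = 0

    @property
    def width_below_mb(self) -> float:
        """One-sided width converted to physical distance."""
        return self.width_below_cm / self.r_cm_per_mb

    @property
    def width_surrounding_cm(self) -> float:
        return 2.0 * self.width_below_cm

    @property
    def width_surrounding_mb(self) -> float:
        return self.width_surrounding_cm / self.r_cm_per_mb


def footprint_from_tmrca(
    tmrca: np.ndarray,
    demog: AncestralDemographyX,
    threshold: float = 0.05,
) -> SweepFootprint:
    """Aggregate replicate TMRCA profiles into an ILS footprint.

    Parameters
    ----------
    tmrca:
        Array of shape (replicates, n_bins) of per-bin TMRCA in generations.
    threshold:
        ILS level below which a bin counts as part of the sweep footprint.
        A threshold of 1.0 makes the width degenerate to the whole flank,
        since ILS fractions never exceed 2/3.
    """
    tmrca = np.atleast_2d(np.asarray(tmrca, dtype=float))
    if tmrca.size == 0:
        raise ValueError("at least one replicate is required")
    boundary = demog.delta_tau_generations
    ils = (2.0 / 3.0) * np.mean(tmrca > boundary, axis=0)
    below = ils < threshold
    width_bins = len(below) if below.all() else int(np.argmax(~below))
    edges = np.arange(len(below) + 1) * demog.bin_cm
    return SweepFootprint(
        bin_edges_cm=edges,
        mean_tmrca=tmrca.mean(axis=0),
        ils_fraction=ils,
        threshold=threshold,
        width_below_cm=width_bins * demog.bin_cm,
        r_cm_per_mb=demog.r_cm_per_mb,
        n_replicates=tmrca.shape[0],
    )


def sweep_footprint(
    demog: AncestralDemographyX,
    s: float,
    replicates: int = 1000,
    mode: Literal["hard", "soft"] = "hard",
    f0: float | None = None,
    threshold: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> SweepFootprint:
    """Simulate ``replicates`` sweeps (fresh trajectory each) and aggregate."""
    rng = _as_rng(seed)
    profiles = np.empty((replicates, demog.n_bins))
    for i in range(replicates):
        traj = sample_fixation_trajectory(demog, s, mode=mode, f0=f0, seed=rng)
        profiles[i] = simulate_sweep_tmrca(traj, demog, seed=rng)
    return footprint_from_tmrca(profiles, demog, threshold=threshold)


def sweep_footprint_grid(
    demog: AncestralDemographyX,
    s_values: Sequence[float],
    replicates: int = 1000,
    mode: Literal["hard", "soft"] = "hard",
    f0: float | None = None,
    threshold: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Footprint widths over a grid of selection coefficients."""
    rng = _as_rng(seed)
    rows = []
    for s in s_values:
        fp = sweep_footprint(
            demog, s, replicates=replicates, mode=mode, f0=f0,
            threshold=threshold, seed=rng,
        )
        rows.append(
            {
                "s": s,
                "mode": mode,
                "f0": f0 if f0 is not None else 1.0 / demog.n_chrom,
                "replicates": replicates,
                "width_below_cm": fp.width_below_cm,
                "width_below_mb": fp.width_below_mb,
                "width_surrounding_mb": fp.width_surrounding_mb,
            }
        )
    return pd.DataFrame(rows)
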