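"""Windowed nucleotide diversity and per-region diversity contrasts.

Nucleotide diversity (pi) is the mean pairwise difference per site among
sampled haplotypes.  Regions that underwent recent selective sweeps show
depleted windowed diversity relative to the chromosomal background; the
contrast is summarized per region as a ratio of mean window pi inside versus
outside all candidate regions, with a Wilcoxon rank-sum test and
Benjamini–Hochberg correction across regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HaplotypePanel",
    "window_nucleotide_diversity",
    "relative_region_diversity",
    "significance_code",
]


@dataclass
class HaplotypePanel:
    """Biallelic haplotypes at segregating sites on one chromosome.

    ``haplotypes`` is an (n_haplotypes, n_sites) 0/1 array; ``positions`` are
    strictly increasing bp coordinates.  Diploid VCF genotypes are split into
    two haplotypes each; hemizygous (haploid) calls contribute one.
    """

    positions: np.ndarray
    haplotypes: np.ndarray
    population: str = ""
    chrom: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        if hap.ndim != 2 or hap.shape[1] != pos.size:
            raise ValueError("haplotypes must be (n_haplotypes, n_sites)")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        self.positions = pos
        self.haplotypes = hap

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


def _per_site_pi(panel: HaplotypePanel) -> np.ndarray:
    """Mean pairwise difference at each site: 2k(n-k) / (n(n-1))."""
    n = panel.n_haplotypes
    if n < 2:
        raise ValueError("need at least two haplotypes")
    k = panel.haplotypes.sum(axis=0).astype(float)
    return 2.0 * k * (n - k) / (n * (n - 1))


def window_nucleotide_diversity(
    panel: HaplotypePanel,
    window_bp: int = 100_000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per site in non-overlapping windows.

    Returns columns ``start``, ``end``, ``pi`` (per site) and ``n_sites``.
    Windows without variants have pi = 0 (monomorphic, not missing).
    """
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1 if panel.n_sites else window_bp
    n_windows = max(1, math.ceil(chrom_length / window_bp))
    edges = np.arange(n_windows + 1) * window_bp
    site_pi = _per_site_pi(panel)
    idx = np.searchsorted(edges, panel.positions, side="right") - 1
    idx = np.clip(idx, 0, n_windows - 1)
    pi_sum = np.bincount(idx, weights=site_pi, minlength=n_windows)
    counts = np.bincount(idx, minlength=n_windows)
    widths = np.minimum(edges[1:], chrom_length) - edges[:-1]
    return pd.DataFrame(
        {
            "start": edges[:-1],
            "end": np.minimum(edges[1:], chrom_length),
            "pi": pi_sum / widths,
            "n_sites": counts,
        }
    )


def significance_code(p: float) -> str:
    """Conventional significance stars for an (adjusted) p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "NS"


def relative_region_diversity(
    track: pd.DataFrame,
    regions,
    alternative: str = "less",
) -> pd.DataFrame:
    """Diversity inside each region relative to the chromosome outside all regions.

    Parameters
    ----------
    track:
        Output of :func:`window_nucleotide_diversity` (columns start, end, pi).
    regions:
        A :class:`~ilsweep.regions.RegionSet`, an
        :class:`~ilsweep.intervals.IntervalSet`, or a DataFrame with
        ``start``/``end`` (and optional ``label``) columns.
    alternative:
        Direction of the Wilcoxon rank-sum test (default: diversity inside is
        lower).

    Returns
    -------
    DataFrame with one row per region: ratio (mean window pi inside / mean
    outside all regions), window count, rank-sum statistic, raw and
    BH-adjusted p-values and a significance code.  Regions containing no
    windows get missing values.
    """
    reg = getattr(regions, "intervals", regions)
    if not isinstance(reg, pd.DataFrame):
        reg = pd.DataFrame({"start": regions.starts, "end": regions.ends})
    if "label" not in reg.columns:
        reg = reg.assign(label=[f"R{i + 1}" for i in range(len(reg))])

    mid = (track["start"].to_numpy() + track["end"].to_numpy()) / 2.0
    pi = track["pi"].to_numpy(dtype=float)
    inside_any = np.zeros(len(track), dtype=bool)
    masks = []
    for _, r in reg.iterrows():
        m = (mid >= r["start"]) & (mid < r["end"])
        masks.append(m)
        inside_any |= m
    outside = pi[~inside_any]
    mean_out = outside.mean() if outside.size else np.nan

    rows = []
    for (_, r), m in zip(reg.iterrows(), masks):
        inside = pi[m]
        if inside.size == 0 or outside.size == 0 or mean_out == 0:
            rows.append(
                {"label": r["label"], "start": r["start"], "end": r["end"],
                 "n_windows": int(inside.size), "ratio": np.nan,
                 "statistic": np.nan, "p_value": np.nan}
            )
            continue
        stat, p = stats.mannwhitneyu(inside, outside, alternative=alternative)
        rows.append(
            {"label": r["label"], "start": r["start"], "end": r["end"],
             "n_windows": int(inside.size), "ratio": inside.mean() / mean_out,
             "statistic": float(stat), "p_value": float(p)}
        )
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    adjusted = np.full(len(out), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = multipletests(
            out.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    out["p_adjusted"] = adjusted
    out["code"] = [significance_code(p) if np.isfinite(p) else "NA" for p in adjusted]
    return out
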