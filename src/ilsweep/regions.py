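"""Low-ILS region calling and alignment-based ILS diagnostics.

Regions with strongly reduced incomplete lineage sorting are called from a
windowed ILS track (100-kb windows sliding by 20 kb) as maximal runs of
windows that each show at most 10% ILS, keeping runs that span at least a
megabase.  Poorly aligned windows are treated as missing: they neither
qualify nor break a run, unless the missing stretch exceeds a gap tolerance
(by default 5 Mb, wide enough to bridge a centromere).

Two alignment-level diagnostics guard against the alternative explanation of
a locally reduced mutation rate: counts of parsimony-informative sites
supporting each rooted triplet topology (a genuine ILS reduction depletes
only the discordant ones), and ratios of pairwise divergences per window (a
more recent human–chimpanzee coalescence lowers HC divergence relative to HG
and HO).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IlsTrack",
    "RegionSet",
    "SitePatternCounts",
    "call_low_ils_regions",
    "classify_triplet_site_patterns",
    "divergence_ratios",
]


@dataclass
class IlsTrack:
    """Windowed ILS fractions along one chromosome.

    ``windows`` has columns ``start``, ``end`` (bp, 0-based half-open),
    ``ils`` (fraction in [0, 1]) and ``aligned_fraction``.
    """

    chrom: str
    windows: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.windows
        required = {"start", "end", "ils"}
        if not required.issubset(w.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if "aligned_fraction" not in w.columns:
            w = w.assign(aligned_fraction=1.0)
        w = w.sort_values("start", ignore_index=True)
        if len(w):
            if (w["end"] <= w["start"]).any():
                raise ValueError("windows must satisfy start < end")
            if ((w["ils"] < 0) | (w["ils"] > 1)).any():
                raise ValueError("ils must lie in [0, 1]")
        self.windows = w

    @classmethod
    def from_arrays(cls, chrom, starts, ends, ils, aligned_fraction=None) -> "IlsTrack":
        df = pd.DataFrame({"start": starts, "end": ends, "ils": ils})
        df["aligned_fraction"] = 1.0 if aligned_fraction is None else aligned_fraction
        return cls(chrom, df)


@dataclass
class RegionSet:
    """Called regions: ``intervals`` with columns start, end, label, mean_ils."""

    chrom: str
    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["start", "end", "label", "mean_ils"])
    )

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        if len(df):
            df = df.sort_values("start", ignore_index=True)
            if (df["end"].values[:-1] > df["start"].values[1:]).any():
                raise ValueError("regions must be disjoint")
            if ((df["mean_ils"] < 0) | (df["mean_ils"] > 1)).any():
                raise ValueError("mean_ils must lie in [0, 1]")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)


def _validate_geometry(w: pd.DataFrame, window_bp: int, step_bp: int) -> None:
    widths = (w["end"] - w["start"]).to_numpy()
    if len(w) and not np.all(widths == window_bp):
        raise ValueError(f"all windows must be {window_bp} bp wide")
    starts = w["start"].to_numpy()
    if len(starts) > 1:
        diffs = np.diff(starts)
        if np.any(diffs % step_bp != 0) or np.any(diffs <= 0):
            raise ValueError(f"window starts must advance by multiples of {step_bp} bp")


def call_low_ils_regions(
    track: IlsTrack,
    window_bp: int = 100_000,
    step_bp: int = 20_000,
    max_ils: float = 0.10,
    min_span_bp: int = 1_000_000,
    min_aligned_fraction: float = 0.5,
    gap_tolerance_bp: int = 5_000_000,
    label_prefix: str | None = None,
) -> RegionSet:
    """Call maximal low-ILS regions from a windowed track.

    A window qualifies when its ILS is at most ``max_ils`` and at least
    ``min_aligned_fraction`` of it is aligned.  Runs of qualifying windows are
    merged by the union of their spans; they are broken by a disqualifying
    (well-aligned, high-ILS) window, or by a stretch without qualifying
    windows longer than ``gap_tolerance_bp``.  Runs spanning at least
    ``min_span_bp`` are returned, with ``mean_ils`` averaged over the
    non-overlapping ``window_bp`` decomposition of the run (sliding windows
    would double-count sites).
    """
    w = track.windows
    if len(w) == 0:
        return RegionSet(track.chrom)
    _validate_geometry(w, window_bp, step_bp)

    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    ils = w["ils"].to_numpy(dtype=float)
    aligned = w["aligned_fraction"].to_numpy(dtype=float)

    qualifies = (ils <= max_ils) & (aligned >= min_aligned_fraction)
    missing = aligned < min_aligned_fraction

    runs: list[tuple[int, int]] = []  # index ranges into qualifying windows
    run: list[int] = []
    for i in range(len(w)):
        if missing[i]:
            continue
        if qualifies[i]:
            if run and starts[i] - ends[run[-1]] > gap_tolerance_bp:
                runs.append((run[0], run[-1]))
                run = []
            run.append(i)
        else:  # well-aligned high-ILS window breaks the run
            if run:
                runs.append((run[0], run[-1]))
                run = []
    if run:
        runs.append((run[0], run[-1]))

    # adjacent runs from overlapping sliding windows can overlap when split by
    # a single disqualifying window; trim such neighbours at the midpoint
    spans = [[int(starts[f]), int(ends[l])] for f, l in runs]
    for a, b in zip(spans, spans[1:]):
        if a[1] > b[0]:
            mid = (a[1] + b[0]) // 2
            a[1] = mid
            b[0] = mid

    prefix = label_prefix if label_prefix is not None else f"{track.chrom}-L"
    rows = []
    k = 0
    for region_start, region_end in spans:
        if region_end - region_start < min_span_bp:
            continue
        k += 1
        members = (
            qualifies
            & (starts >= region_start)
            & (ends <= region_end)
        )
        tiled = members & ((starts - region_start) % window_bp == 0)
        mean_ils = float(ils[tiled].mean()) if tiled.any() else float(ils[members].mean())
        rows.append(
            {"start": region_start, "end": region_end, "label": f"{prefix}{k}", "mean_ils": mean_ils}
        )
    return RegionSet(track.chrom, pd.DataFrame(rows, columns=["start", "end", "label", "mean_ils"]))


@dataclass(frozen=True)
class SitePatternCounts:
    """Parsimony-informative site counts for the three rooted triplets.

    A column is informative for a pair when the pair shares one base and the
    remaining ingroup species shares a different base with the outgroup.
    ``n_hc_g`` supports the species topology ((H,C),G); the other two support
    discordant (ILS) topologies.
    """

    n_hc_g: int
    n_hg_c: int
    n_cg_h: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_hc_g, self.n_hg_c, self.n_cg_h, self.n_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_hc_g + self.n_hg_c + self.n_cg_h > self.n_total:
            raise ValueError("informative sites cannot exceed total aligned sites")

    @property
    def n_informative(self) -> int:
        return self.n_hc_g + self.n_hg_c + self.n_cg_h

    @property
    def discordant_fraction(self) -> float:
        """Fraction of informative sites supporting an ILS topology."""
        n = self.n_informative
        return (self.n_hg_c + self.n_cg_h) / n if n else math.nan


def _seq_codes(seq) -> np.ndarray:
    s = str(seq).upper().encode("ascii")
    return np.frombuffer(s, dtype=np.uint8)


def classify_triplet_site_patterns(h, c, g, o) -> SitePatternCounts:
    """Count informative site patterns in a human/chimp/gorilla/outgroup alignment.

    Gapped or ambiguous columns are skipped entirely (not counted in
    ``n_total``); sequences of unequal length are truncated to the shortest
    with a warning.
    """
    seqs = [_seq_codes(s) for s in (h, c, g, o)]
    n = min(len(s) for s in seqs)
    if len({len(s) for s in seqs}) > 1:
        warnings.warn("sequences have unequal lengths; truncating to the shortest")
        seqs = [s[:n] for s in seqs]
    H, C, G, O = seqs
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid = np.ones(n, dtype=bool)
    for s in seqs:
        valid &= np.isin(s, acgt)
    H, C, G, O = H[valid], C[valid], G[valid], O[valid]
    hc = (H == C) & (H != G) & (G == O)
    hg = (H == G) & (H != C) & (C == O)
    cg = (C == G) & (C != H) & (H == O)
    return SitePatternCounts(
        n_hc_g=int(hc.sum()),
        n_hg_c=int(hg.sum()),
        n_cg_h=int(cg.sum()),
        n_total=int(valid.sum()),
    )


def divergence_ratios(h, c, g, o, window_bp: int = 100_000) -> pd.DataFrame:
    """Per-window divergence ratios HC/HG and HC/HO.

    Mismatch fractions are computed over columns where both compared species
    carry unambiguous bases.  Windows whose denominator divergence is zero or
    that contain no comparable sites get a missing ratio.
    """
    seqs = [_seq_codes(s) for s in (h, c, g, o)]
    n = min(len(s) for s in seqs)
    if len({len(s) for s in seqs}) > 1:
        warnings.warn("sequences have unequal lengths; truncating to the shortest")
    H, C, G, O = (s[:n] for s in seqs)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    ok = {name: np.isin(s, acgt) for name, s in zip("HCGO", (H, C, G, O))}

    rows = []
    for start in range(0, n, window_bp):
        end = min(start + window_bp, n)
        sl = slice(start, end)
        divs = {}
        for pair, (a, b) in {
            "hc": (("H", H), ("C", C)),
            "hg": (("H", H), ("G", G)),
            "ho": (("H", H), ("O", O)),
        }.items():
            both = ok[a[0]][sl] & ok[b[0]][sl]
            m = int(both.sum())
            divs[pair] = (np.count_nonzero(a[1][sl][both] != b[1][sl][both]) / m) if m else np.nan
        ratio_hg = divs["hc"] / divs["hg"] if divs["hg"] and not np.isnan(divs["hg"]) else np.nan
        ratio_ho = divs["hc"] / divs["ho"] if divs["ho"] and not np.isnan(divs["ho"]) else np.nan
        rows.append(
            {
                "start": start,
                "end": end,
                "div_hc": divs["hc"],
                "div_hg": divs["hg"],
                "div_ho": divs["ho"],
                "ratio_hc_hg": ratio_hg,
                "ratio_hc_ho": ratio_ho,
            }
        )
    return pd.DataFrame(rows)
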