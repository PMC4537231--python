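"""Monte-Carlo permutation test for genomic interval overlap.

Tests whether a set of query intervals (e.g. low-ILS regions) overlaps a set
of reference intervals (e.g. ampliconic regions, or regions devoid of
Neanderthal introgression) more than expected by chance.  The statistic is
the total overlap in base pairs.  Under the null, the query intervals are
shuffled along the chromosome preserving every interval length, while the
reference set is never moved — so any autocorrelation in the reference
structure is respected.

The shuffle follows a free-space construction: compute the total size ``S``
of the chromosome outside the query intervals, draw one breakpoint per query
interval uniformly in ``[0, S]``, and insert the intervals (in random order)
at the sorted breakpoints.  Ties are allowed, so shuffled intervals may abut
with zero gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "IntervalSet",
    "PermutationResult",
    "overlap_bp",
    "shuffle_query_intervals",
    "permutation_overlap_test",
    "permutation_overlap_test_multi",
]


@dataclass(frozen=True)
class IntervalSet:
    """Non-overlapping, sorted intervals (0-based half-open) on one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    labels: tuple | None = None

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have equal length")
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        labels = self.labels
        if labels is not None:
            if len(labels) != len(starts):
                raise ValueError("labels length mismatch")
            labels = tuple(np.asarray(labels, dtype=object)[order])
        if len(starts):
            if np.any(starts < 0) or np.any(ends <= starts):
                raise ValueError("intervals must satisfy 0 <= start < end")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("intervals must be non-overlapping")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_tuples(cls, chrom: str, intervals: Sequence[tuple]) -> "IntervalSet":
        if not intervals:
            return cls(chrom, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        starts, ends = zip(*[(iv[0], iv[1]) for iv in intervals])
        labels = tuple(iv[2] for iv in intervals) if len(intervals[0]) > 2 else None
        return cls(chrom, np.array(starts), np.array(ends), labels)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_length(self) -> int:
        return int(np.sum(self.ends - self.starts))

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts


def overlap_bp(query: IntervalSet, reference: IntervalSet) -> int:
    """Total intersection length in bp; symmetric in its arguments."""
    if query.chrom != reference.chrom:
        raise ValueError(
            f"chromosome mismatch: {query.chrom!r} vs {reference.chrom!r}"
        )
    return _overlap_arrays(query.starts, query.ends, reference.starts, reference.ends)


def _overlap_arrays(qs, qe, rs, re) -> int:
    if len(qs) == 0 or len(rs) == 0:
        return 0
    lo = np.maximum(qs[:, None], rs[None, :])
    hi = np.minimum(qe[:, None], re[None, :])
    return int(np.maximum(hi - lo, 0).sum())


def shuffle_query_intervals(
    query: IntervalSet,
    chrom_length: int,
    seed: int | np.random.Generator | None = None,
    preserve_order: bool = False,
) -> IntervalSet:
    """Random placement of the query intervals preserving their lengths.

    Draws one breakpoint per interval uniformly over the free space
    ``S = chrom_length - total query length``, sorts the breakpoints and
    inserts the intervals at them in random order (or in their original
    order with ``preserve_order=True``).  Zero gaps between shuffled
    intervals are allowed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = query.lengths
    total = int(lengths.sum())
    if total >= chrom_length:
        raise ValueError("total query length must be smaller than the chromosome")
    if len(query) == 0:
        return query
    S = chrom_length - total
    breakpoints = np.sort(rng.integers(0, S + 1, size=len(query)))
    placed = lengths if preserve_order else rng.permutation(lengths)
    starts = breakpoints + np.concatenate([[0], np.cumsum(placed[:-1])])
    return IntervalSet(query.chrom, starts, starts + placed)


@dataclass(frozen=True)
class PermutationResult:
    """Observed overlap and its Monte-Carlo null summary."""

    observed_bp: int
    p_value: float
    n_perm: int
    n_ge: int
    null_mean: float
    null_sd: float


def permutation_overlap_test(
    query: IntervalSet,
    reference: IntervalSet,
    chrom_length: int,
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
    add_one: bool = False,
    preserve_order: bool = False,
) -> PermutationResult:
    """Monte-Carlo test of query/reference overlap.

    The p-value is the fraction of shuffles whose overlap is at least the
    observed one (``(k+1)/(n+1)`` with ``add_one=True``); the reference set is
    never moved.  An empty query yields p = 1 with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = overlap_bp(query, reference)
    if len(query) == 0:
        warnings.warn("empty query set: p-value is 1 by convention")
        return PermutationResult(0, 1.0, n_perm, n_perm, 0.0, 0.0)
    rs, re = reference.starts, reference.ends
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_query_intervals(query, chrom_length, rng, preserve_order)
        null[i] = _overlap_arrays(shuffled.starts, shuffled.ends, rs, re)
    n_ge = int(np.sum(null >= observed))
    p = (n_ge + 1) / (n_perm + 1) if add_one else n_ge / n_perm
    return PermutationResult(
        observed_bp=observed,
        p_value=float(p),
        n_perm=n_perm,
        n_ge=n_ge,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )


def permutation_overlap_test_multi(
    query: Mapping[str, IntervalSet],
    reference: Mapping[str, IntervalSet],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
    add_one: bool = False,
) -> PermutationResult:
    """Multi-chromosome extension: shuffle per chromosome, sum the overlaps."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(query)
    observed = sum(
        overlap_bp(query[c], reference[c]) for c in chroms if c in reference
    )
    null = np.zeros(n_perm)
    for c in chroms:
        if c not in reference:
            continue
        rs, re = reference[c].starts, reference[c].ends
        for i in range(n_perm):
            sh = shuffle_query_intervals(query[c], chrom_lengths[c], rng)
            null[i] += _overlap_arrays(sh.starts, sh.ends, rs, re)
    n_ge = int(np.sum(null >= observed))
    p = (n_ge + 1) / (n_perm + 1) if add_one else n_ge / n_perm
    return PermutationResult(
        observed_bp=int(observed),
        p_value=float(p),
        n_perm=n_perm,
        n_ge=n_ge,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )
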