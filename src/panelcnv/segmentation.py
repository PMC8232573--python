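"""Circular binary segmentation (CBS) of genome-ordered log2-ratio tracks.

The classical recursive formulation: on each interval the arc maximising
the |t| statistic (arc mean vs complement mean, pooled variance) is found
over all circular arcs; the split is accepted when a permutation test on
the max-|t| statistic is significant, and the procedure recurses on the
implied sub-intervals. A final undo pass merges adjacent segments whose
mean difference is small relative to a robust noise estimate. Segments
never cross chromosome boundaries.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import TargetRegion

__all__ = [
    "SegmentationConfig",
    "Segment",
    "MaxTResult",
    "max_t_statistic",
    "permutation_p",
    "segment_chromosome",
    "segment_genome",
]


@dataclass
class SegmentationConfig:
    """CBS tuning parameters.

    alpha : permutation significance level required to accept a split.
    n_permutations : permutations per split test.
    min_width : minimum markers in an arc (and its complement).
    seed : RNG seed for the permutation tests (mandatory for
        reproducibility; identical inputs + seed give identical segments).
    prune_sd : undo-splits threshold in units of the robust noise SD of
        the vector; adjacent segments whose means differ by less are
        merged. 0 disables pruning.
    """

    alpha: float = 0.01
    n_permutations: int = 10_000
    min_width: int = 2
    seed: int = 0
    prune_sd: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if self.prune_sd < 0:
            raise ValueError("prune_sd must be >= 0")


@dataclass(frozen=True)
class Segment:
    """A maximal run of markers sharing one copy-number level.

    ``start_index``/``end_index`` are half-open indices into the unmasked,
    genome-ordered marker list; ``start``/``end`` are the genomic span
    (start of the first member region to end of the last). ``mean`` is the
    arithmetic mean log2 ratio of the member markers.
    """

    chrom: str
    start_index: int
    end_index: int
    start: int
    end: int
    mean: float
    n_markers: int

    def __post_init__(self) -> None:
        if self.n_markers < 1 or self.end_index - self.start_index != self.n_markers:
            raise ValueError("inconsistent segment marker count")
        if not np.isfinite(self.mean):
            raise ValueError("segment mean must be finite")


@dataclass(frozen=True)
class MaxTResult:
    """Best circular arc (i, j] and its |t| statistic; ``arc`` is None
    when the vector is too short to admit a split."""

    arc: tuple[int, int] | None
    t: float


def _var_tolerance(total_ss: float, n: int) -> float:
    # guards against catastrophic cancellation when the arc and its
    # complement are each exactly constant (noiseless steps)
    return 1e-10 * max(1.0, total_ss) / n


def max_t_statistic(values: Sequence[float], min_width: int = 2) -> MaxTResult:
    """Best arc of a circular binary split and its |t| statistic.

    Scans all arcs (i, j] with width in [min_width, n - min_width] and
    returns the arc maximising |t|, where t compares the arc mean against
    the complement mean with pooled variance. Arcs wrapping the circle are
    complements of scanned arcs and score identically, so only contiguous
    arcs are enumerated; arcs ending at the boundary (i > 0, j = n) are
    likewise skipped because they define the same partition as (0, i].
    Ties break towards the smallest i, then the smallest j. Arcs with zero
    pooled variance score +inf when the means differ (a perfect step
    always splits) and 0 when they do not.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2 * min_width:
        return MaxTResult(arc=None, t=0.0)
    S = np.concatenate(([0.0], np.cumsum(v)))
    SS = np.concatenate(([0.0], np.cumsum(v * v)))
    total, total_ss = S[-1], SS[-1]
    tol = _var_tolerance(total_ss, n)
    best_t = -1.0
    best_arc: tuple[int, int] | None = None
    for k in range(min_width, n - min_width + 1):
        m = n - k
        sum_a = (S[k:] - S[:-k])[:-1] if m >= 1 else S[k:] - S[:-k]
        ss_a = (SS[k:] - SS[:-k])[: len(sum_a)]  # arc sums, i = 0 .. n-k-1
        mean_diff = sum_a / k - (total - sum_a) / m
        sp2_num = (ss_a - sum_a**2 / k) + ((total_ss - ss_a) - (total - sum_a) ** 2 / m)
        denom = max(n - 2, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean_diff) / np.sqrt((sp2_num / denom) * (1.0 / k + 1.0 / m))
        degenerate = sp2_num <= tol
        t[degenerate & (np.abs(mean_diff) > np.sqrt(tol))] = np.inf
        t[degenerate & (np.abs(mean_diff) <= np.sqrt(tol))] = 0.0
        i = int(np.argmax(t))           # first max -> smallest i at this width
        tk = float(t[i])
        if tk > best_t or (tk == best_t and best_arc is not None and i < best_arc[0]):
            best_t = tk
            best_arc = (i, i + k)
    return MaxTResult(arc=best_arc, t=best_t)


def _batch_max_t(matrix: np.ndarray, min_width: int) -> np.ndarray:
    """Max-|t| statistic per row of a (permutations x n) matrix."""
    P, n = matrix.shape
    S = np.concatenate((np.zeros((P, 1)), np.cumsum(matrix, axis=1)), axis=1)
    SS = np.concatenate(
        (np.zeros((P, 1)), np.cumsum(matrix * matrix, axis=1)), axis=1
    )
    total = S[:, -1:]
    total_ss = SS[:, -1:]
    tol = 1e-10 * np.maximum(1.0, total_ss) / n
    best = np.zeros(P)
    denom = max(n - 2, 1)
    for k in range(min_width, n - min_width + 1):
        m = n - k
        sum_a = S[:, k:] - S[:, :-k]
        ss_a = SS[:, k:] - SS[:, :-k]
        mean_diff = sum_a / k - (total - sum_a) / m
        sp2_num = (ss_a - sum_a**2 / k) + ((total_ss - ss_a) - (total - sum_a) ** 2 / m)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean_diff) / np.sqrt((sp2_num / denom) * (1.0 / k + 1.0 / m))
        degenerate = sp2_num <= tol
        t[degenerate & (np.abs(mean_diff) > np.sqrt(tol))] = np.inf
        t[degenerate & (np.abs(mean_diff) <= np.sqrt(tol))] = 0.0
        best = np.maximum(best, t.max(axis=1))
    return best


def permutation_p(
    values: Sequence[float],
    observed_t: float,
    config: SegmentationConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value of an observed max-|t| statistic.

    p = (1 + #{permutations with max-|t| >= observed}) / (1 + B), with B
    value shuffles drawn from the seeded generator; deterministic given
    the seed.
    """
    v = np.asarray(values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    n = len(v)
    exceed = 0
    block = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < B:
        b = min(block, B - done)
        perm = rng.permuted(np.broadcast_to(v, (b, n)).copy(), axis=1)
        exceed += int(np.sum(_batch_max_t(perm, config.min_width) >= observed_t))
        done += b
    return (1 + exceed) / (1 + B)


def _prune(
    values: np.ndarray, bounds: list[tuple[int, int]], prune_sd: float
) -> list[tuple[int, int]]:
    """Merge adjacent segments whose mean difference is below the noise gate.

    Noise SD is estimated robustly from successive differences:
    1.4826 * median|diff| / sqrt(2). The closest-mean adjacent pair is
    merged first; merging repeats until every adjacent difference clears
    the gate.
    """
    if prune_sd <= 0 or len(bounds) < 2 or len(values) < 2:
        return bounds
    noise = 1.4826 * float(np.median(np.abs(np.diff(values)))) / np.sqrt(2.0)
    gate = prune_sd * noise
    bounds = list(bounds)
    while len(bounds) > 1:
        means = [float(values[a:b].mean()) for a, b in bounds]
        diffs = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
        i = int(np.argmin(diffs))
        if diffs[i] >= gate:
            break
        bounds[i] = (bounds[i][0], bounds[i + 1][1])
        del bounds[i + 1]
    return bounds


def _make_segments(
    values: np.ndarray,
    bounds: list[tuple[int, int]],
    chrom: str,
    regions: Sequence[TargetRegion] | None,
    index_offset: int,
) -> list[Segment]:
    segs = []
    for a, b in bounds:
        if regions is not None:
            start, end = regions[a].start, regions[b - 1].end
        else:
            start, end = a, b
        segs.append(
            Segment(
                chrom=chrom,
                start_index=index_offset + a,
                end_index=index_offset + b,
                start=start,
                end=end,
                mean=float(values[a:b].mean()),
                n_markers=b - a,
            )
        )
    return segs


def segment_chromosome(
    values: Sequence[float],
    config: SegmentationConfig,
    chrom: str = "",
    regions: Sequence[TargetRegion] | None = None,
    rng: np.random.Generator | None = None,
    index_offset: int = 0,
) -> list[Segment]:
    """Segment one chromosome's genome-ordered log2-ratio vector.

    Recursively accepts the max-|t| arc split while the permutation test
    is significant at ``alpha``, then applies the SD-gated undo pass.
    Without ``regions`` the genomic span of each segment is reported in
    marker indices.
    """
    v = np.asarray(values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(v) == 0:
        return []
    bounds: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * config.min_width:
            bounds.append((lo, hi))
            return
        res = max_t_statistic(v[lo:hi], config.min_width)
        if res.arc is None or res.t == 0.0:
            bounds.append((lo, hi))
            return
        p = permutation_p(v[lo:hi], res.t, config, rng)
        if p < config.alpha:
            i, j = res.arc
            for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                if b > a:
                    recurse(a, b)
        else:
            bounds.append((lo, hi))

    recurse(0, len(v))
    bounds.sort()
    bounds = _prune(v, bounds, config.prune_sd)
    return _make_segments(v, bounds, chrom, regions, index_offset)


def _chrom_rng(seed: int, chrom: str) -> np.random.Generator:
    # per-chromosome stream keyed on the chromosome name, so a genome run
    # and a standalone run of the same chromosome agree exactly
    return np.random.default_rng([seed, zlib.crc32(chrom.encode())])


def segment_genome(
    values: Sequence[float],
    regions: Sequence[TargetRegion],
    config: SegmentationConfig,
) -> list[Segment]:
    """Segment a whole-panel ratio track chromosome by chromosome.

    ``values``/``regions`` are the aligned, genome-ordered unmasked track
    (see :func:`panelcnv.normalization.log2_ratios`). Chromosomes are
    segmented independently — segments never span a chromosome boundary —
    and results are concatenated in genome order.
    """
    v = np.asarray(values, dtype=float)
    if len(v) != len(regions):
        raise ValueError("values and regions must align")
    out: list[Segment] = []
    i = 0
    while i < len(regions):
        chrom = regions[i].chrom
        j = i
        while j < len(regions) and regions[j].chrom == chrom:
            j += 1
        out.extend(
            segment_chromosome(
                v[i:j],
                config,
                chrom=chrom,
                regions=regions[i:j],
                rng=_chrom_rng(config.seed, chrom),
                index_offset=i,
            )
        )
        i = j
    return out
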