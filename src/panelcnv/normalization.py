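"""Coverage normalisation and panel-of-normals baseline construction.

The calling pipeline normalises raw per-region read counts in two steps
(library size, then GC content), selects control samples by coverage
correlation against the case (R-squared >= 0.9 by default), builds a
robust per-region baseline from the accepted controls, and forms
per-region log2 ratios of case over baseline.

Order of operations: counts are fully normalised (library size + GC)
before control selection, so that the selection R-squared measures
coverage-profile similarity rather than sequencing yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CoverageMatrix, TargetRegion

__all__ = [
    "NormalizationConfig",
    "Baseline",
    "RatioTrack",
    "ControlSelectionError",
    "library_size_factors",
    "gc_correct",
    "normalize_matrix",
    "select_controls",
    "build_baseline",
    "log2_ratios",
]


@dataclass
class NormalizationConfig:
    """Tuning knobs for normalisation and control selection.

    r2_threshold : minimum squared Pearson correlation (on log2 normalised
        coverage) for a candidate control to be accepted; 0.9 default.
    min_controls : minimum number of accepted controls for a baseline.
    gc_bin_width : width of the GC-fraction bins used for bias correction.
    pseudocount : additive constant wherever a ratio or log is formed.
    min_baseline : regions whose baseline centre falls below this
        normalised coverage are masked out of calling.
    """

    r2_threshold: float = 0.9
    min_controls: int = 3
    gc_bin_width: float = 0.02
    pseudocount: float = 0.5
    min_baseline: float = 10.0
    min_bin_regions: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.min_controls < 1:
            raise ValueError("min_controls must be >= 1")
        if not (0 < self.gc_bin_width <= 0.5):
            raise ValueError("gc_bin_width must be in (0, 0.5]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class Baseline:
    """Per-region centre/spread of normalised control coverage.

    centre = median across controls, spread = median absolute deviation;
    ``mask`` is True for regions excluded from calling (centre below
    ``min_baseline``).
    """

    center: np.ndarray
    spread: np.ndarray
    mask: np.ndarray
    n_controls: int = 0

    def __post_init__(self) -> None:
        if not (len(self.center) == len(self.spread) == len(self.mask)):
            raise ValueError("baseline arrays must share one length")
        if np.any(self.center < 0) or np.any(self.spread < 0):
            raise ValueError("baseline centre/spread must be non-negative")


@dataclass
class RatioTrack:
    """Per-region log2 ratios over the unmasked regions, genome order."""

    regions: list[TargetRegion]
    values: np.ndarray
    masked_regions: list[TargetRegion] = field(default_factory=list)


class ControlSelectionError(RuntimeError):
    """Raised when fewer than ``min_controls`` candidates pass the R² gate."""

    def __init__(self, message: str, r2_report: list[tuple[str, float]]):
        super().__init__(message)
        #: all candidates with their R², best first
        self.r2_report = r2_report


def library_size_factors(
    matrix: CoverageMatrix, pseudocount: float = 0.5
) -> np.ndarray:
    """Median-of-ratios library-size factor per sample (used as divisors).

    Each region's pseudo-reference is the geometric mean of
    (count + pseudocount) across samples; a sample's factor is the median
    over regions of its counts over the pseudo-reference. Factors are
    rescaled to mean 1. If more than half of the regions contain a zero
    count (so the raw geometric reference collapses), total-count factors
    scaled to mean 1 are used instead.
    """
    counts = matrix.counts
    zero_sums = np.sum(counts, axis=0) == 0
    if np.any(zero_sums):
        bad = [s for s, z in zip(matrix.samples, zero_sums) if z]
        raise ValueError(f"samples with all-zero counts: {bad}")
    if counts.shape[1] == 1:
        return np.ones(1)
    frac_zero_ref = np.mean(np.any(counts == 0, axis=1))
    if frac_zero_ref > 0.5:
        totals = counts.sum(axis=0)
        factors = totals / totals.mean()
        return factors
    log_ref = np.mean(np.log(counts + pseudocount), axis=1)
    ratios = counts / np.exp(log_ref)[:, None]
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        totals = counts.sum(axis=0)
        factors = totals / totals.mean()
        return factors
    return factors / factors.mean()


def _gc_bins(
    gc: np.ndarray, bin_width: float, min_bin_regions: int
) -> np.ndarray:
    """Assign regions to GC bins, merging bins with too few regions.

    Bins are fixed-width over [0, 1]; occupied bins with fewer than
    ``min_bin_regions`` members are merged with the occupied neighbour
    whose bin centre is nearest (ties towards lower GC), repeatedly,
    until every group is large enough or a single group remains.
    Returns a group id per region.
    """
    raw = np.minimum((gc / bin_width).astype(int), int(np.ceil(1.0 / bin_width)) - 1)
    # groups: ordered list of (member bin ids); group centre = mean of bin centres
    occupied = sorted(set(raw.tolist()))
    groups: list[list[int]] = [[b] for b in occupied]

    def group_sizes() -> list[int]:
        lookup = {b: gi for gi, grp in enumerate(groups) for b in grp}
        sizes = [0] * len(groups)
        for b in raw:
            sizes[lookup[b]] += 1
        return sizes

    while len(groups) > 1:
        sizes = group_sizes()
        small = [gi for gi, s in enumerate(sizes) if s < min_bin_regions]
        if not small:
            break
        gi = min(small, key=lambda g: sizes[g])
        centres = [bin_width * (np.mean(grp) + 0.5) for grp in groups]
        neighbours = []
        if gi > 0:
            neighbours.append((abs(centres[gi] - centres[gi - 1]), gi - 1))
        if gi < len(groups) - 1:
            neighbours.append((abs(centres[gi] - centres[gi + 1]), gi + 1))
        _, gj = min(neighbours)  # ties resolve to the lower-GC neighbour
        lo, hi = sorted((gi, gj))
        groups[lo] = groups[lo] + groups[hi]
        del groups[hi]
    lookup = {b: gi for gi, grp in enumerate(groups) for b in grp}
    return np.array([lookup[b] for b in raw])


def gc_correct(
    coverage: np.ndarray,
    regions: Sequence[TargetRegion],
    config: NormalizationConfig | None = None,
) -> np.ndarray:
    """Remove GC-dependent coverage bias by binned median scaling.

    Regions are grouped into GC bins of width ``gc_bin_width`` (small bins
    merged with their nearest neighbour); each value is multiplied by
    (global median) / (median of its bin). A bin whose median is zero gets
    factor 1; an all-zero input is returned unchanged.
    """
    config = config or NormalizationConfig()
    coverage = np.asarray(coverage, dtype=float)
    if len(coverage) != len(regions):
        raise ValueError("coverage length does not match regions")
    global_median = float(np.median(coverage))
    if global_median == 0 and not np.any(coverage):
        return coverage.copy()
    gc = np.array([r.gc for r in regions])
    group = _gc_bins(gc, config.gc_bin_width, config.min_bin_regions)
    corrected = coverage.copy()
    for g in np.unique(group):
        members = group == g
        bin_median = float(np.median(coverage[members]))
        factor = 1.0 if bin_median == 0 else global_median / bin_median
        corrected[members] = coverage[members] * factor
    return corrected


def normalize_matrix(
    matrix: CoverageMatrix, config: NormalizationConfig | None = None
) -> np.ndarray:
    """Fully normalised coverage: library-size scaling then GC correction.

    Returns an array of the same shape as ``matrix.counts``.
    """
    config = config or NormalizationConfig()
    factors = library_size_factors(matrix, config.pseudocount)
    scaled = matrix.counts / factors[None, :]
    out = np.empty_like(scaled)
    for j in range(scaled.shape[1]):
        out[:, j] = gc_correct(scaled[:, j], matrix.regions, config)
    return out


def _log_r2(x: np.ndarray, y: np.ndarray, pseudocount: float) -> float:
    lx = np.log2(x + pseudocount)
    ly = np.log2(y + pseudocount)
    sx, sy = np.std(lx), np.std(ly)
    if sx == 0 or sy == 0:
        # a flat profile carries no shape information; treat identical flat
        # profiles as perfectly correlated
        return 1.0 if np.allclose(lx, ly) else 0.0
    r = float(np.corrcoef(lx, ly)[0, 1])
    return r * r


def select_controls(
    case: str,
    pool: CoverageMatrix,
    config: NormalizationConfig | None = None,
    normalized: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    allow_best: bool = False,
) -> list[tuple[str, float]]:
    """Select control samples for a case by normalised-coverage correlation.

    R² is the squared Pearson correlation of log2(normalised coverage +
    pseudocount) between case and candidate over unmasked regions; a
    candidate is accepted when R² >= ``r2_threshold``. Returns accepted
    (sample, R²) pairs sorted by descending R² (the case itself is never a
    candidate). With fewer than ``min_controls`` acceptances a
    :class:`ControlSelectionError` carrying the full R² report is raised,
    unless ``allow_best`` is set, in which case the top ``min_controls``
    candidates are returned regardless of the threshold.
    """
    config = config or NormalizationConfig()
    if normalized is None:
        normalized = normalize_matrix(pool, config)
    keep = np.ones(len(pool.regions), dtype=bool) if mask is None else ~mask
    ci = pool.sample_index(case)
    x = normalized[keep, ci]
    report: list[tuple[str, float]] = []
    for j, sample in enumerate(pool.samples):
        if j == ci:
            continue
        report.append((sample, _log_r2(x, normalized[keep, j], config.pseudocount)))
    report.sort(key=lambda t: (-t[1], t[0]))
    accepted = [(s, r2) for s, r2 in report if r2 >= config.r2_threshold]
    if len(accepted) < config.min_controls:
        if allow_best:
            return report[: config.min_controls]
        raise ControlSelectionError(
            f"only {len(accepted)} of {len(report)} candidates reach "
            f"R^2 >= {config.r2_threshold} for case {case!r} "
            f"(best: {report[:3]})",
            report,
        )
    return accepted


def build_baseline(
    controls: np.ndarray, config: NormalizationConfig | None = None
) -> Baseline:
    """Panel-of-normals baseline from normalised control coverage.

    ``controls`` is regions x controls. Centre = per-region median,
    spread = per-region median absolute deviation (unscaled); regions with
    centre < ``min_baseline`` are masked.
    """
    config = config or NormalizationConfig()
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    if controls.ndim != 2:
        raise ValueError("controls must be a 2-D regions x controls array")
    center = np.median(controls, axis=1)
    spread = np.median(np.abs(controls - center[:, None]), axis=1)
    mask = center < config.min_baseline
    return Baseline(center=center, spread=spread, mask=mask,
                    n_controls=controls.shape[1])


def log2_ratios(
    case: np.ndarray,
    baseline: Baseline,
    regions: Sequence[TargetRegion],
    config: NormalizationConfig | None = None,
) -> RatioTrack:
    """Per-region log2(case / baseline centre) over unmasked regions.

    ratio_r = log2((case_r + pseudocount) / (centre_r + pseudocount)).
    Masked regions are dropped from the track and recorded in
    ``masked_regions``.
    """
    config = config or NormalizationConfig()
    case = np.asarray(case, dtype=float)
    if len(case) != len(baseline.center) or len(case) != len(regions):
        raise ValueError("case vector, baseline and regions must align")
    pc = config.pseudocount
    keep = ~baseline.mask
    values = np.log2((case[keep] + pc) / (baseline.center[keep] + pc))
    return RatioTrack(
        regions=[r for r, k in zip(regions, keep) if k],
        values=values,
        masked_regions=[r for r, k in zip(regions, keep) if not k],
    )
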