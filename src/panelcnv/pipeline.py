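"""End-to-end case calling: normalisation through annotated CNV calls."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import CallingConfig, CnvCall, LabelAssignment, annotate_calls, call_segments
from .core import AlterationCatalog, CoverageMatrix
from .normalization import (
    Baseline,
    NormalizationConfig,
    RatioTrack,
    build_baseline,
    log2_ratios,
    normalize_matrix,
    select_controls,
)
from .segmentation import Segment, SegmentationConfig, segment_genome

__all__ = ["CaseResult", "call_case"]


@dataclass
class CaseResult:
    """Everything the pipeline produced for one case sample."""

    case: str
    controls: list[tuple[str, float]]
    baseline: Baseline
    track: RatioTrack
    segments: list[Segment]
    calls: list[CnvCall]
    label_report: list[LabelAssignment] = field(default_factory=list)


def call_case(
    pool: CoverageMatrix,
    case: str,
    norm_config: NormalizationConfig | None = None,
    seg_config: SegmentationConfig | None = None,
    call_config: CallingConfig | None = None,
    catalog: AlterationCatalog | None = None,
    controls: list[str] | None = None,
    allow_best: bool = False,
) -> CaseResult:
    """Call CNVs for ``case`` against controls drawn from ``pool``.

    Runs the read-depth pipeline end to end: library-size and GC
    normalisation, correlation-gated control selection (unless an
    explicit ``controls`` list is given), panel-of-normals baseline,
    per-region log2 ratios, circular binary segmentation, threshold
    calling and — when a catalog is supplied — label annotation.
    """
    norm_config = norm_config or NormalizationConfig()
    seg_config = seg_config or SegmentationConfig()
    call_config = call_config or CallingConfig()

    normalized = normalize_matrix(pool, norm_config)
    if controls is None:
        selected = select_controls(
            case, pool, norm_config, normalized=normalized, allow_best=allow_best
        )
    else:
        selected = [(s, float("nan")) for s in controls]
    control_idx = [pool.sample_index(s) for s, _ in selected]
    baseline = build_baseline(normalized[:, control_idx], norm_config)
    track = log2_ratios(
        normalized[:, pool.sample_index(case)], baseline, pool.regions, norm_config
    )
    segments = segment_genome(track.values, track.regions, seg_config)
    calls = call_segments(segments, call_config)
    report: list[LabelAssignment] = []
    if catalog is not None:
        calls, report = annotate_calls(calls, catalog, track.regions, call_config)
    return CaseResult(
        case=case,
        controls=selected,
        baseline=baseline,
        track=track,
        segments=segments,
        calls=calls,
        label_report=report,
    )
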