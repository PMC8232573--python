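"""Copy-number estimation, threshold calling and catalog annotation.

A segment's copy number is CN = 2 * 2^mean (diploid autosomal reference).
Segments at or beyond the duplication / deletion cutoffs (2.5 and 1.5 by
default) become calls; everything strictly between is reported as diploid.
Calls are then matched against the panel's recurrent-alteration catalog by
targeted-base overlap, and each call carries the clonal fraction a
single-copy event would need to produce its copy number (gain: f = CN - 2,
loss: f = 2 - CN) — which is why events below ~50% clonality sit under the
default cutoffs and go uncalled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .core import AlterationCatalog, TargetRegion
from .segmentation import Segment

__all__ = [
    "CallingConfig",
    "CnvCall",
    "LabelAssignment",
    "estimate_copy_number",
    "estimate_clonal_fraction",
    "call_segments",
    "annotate_calls",
]


@dataclass
class CallingConfig:
    """Calling thresholds and catalog-annotation overlap rules.

    dup_cutoff / del_cutoff : copy-number cutoffs; both inclusive
        (CN >= 2.5 gain, CN <= 1.5 loss).
    label_overlap : fraction of a region/arm catalog entry's targeted
        bases that must fall inside same-direction called segments for the
        label to be assigned.
    whole_chrom_overlap : the same fraction for whole-chromosome
        (aneuploidy) entries, stricter by default.
    sex_chromosome_ploidy : reference copy number used on chrX/chrY; 2 by
        default (set per sample sex when known).
    """

    dup_cutoff: float = 2.5
    del_cutoff: float = 1.5
    label_overlap: float = 0.5
    whole_chrom_overlap: float = 0.8
    sex_chromosome_ploidy: float = 2.0

    def __post_init__(self) -> None:
        if not (self.del_cutoff < 2 < self.dup_cutoff):
            raise ValueError("require del_cutoff < 2 < dup_cutoff")
        for name in ("label_overlap", "whole_chrom_overlap"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class CnvCall:
    """One reported CNV: a called segment with its interpretation."""

    segment: Segment
    cn: float
    direction: str  # "gain" | "loss"
    clonal_fraction: float
    out_of_model: bool = False
    labels: frozenset[str] = field(default_factory=frozenset)

    def with_labels(self, labels: set[str]) -> "CnvCall":
        return replace(self, labels=frozenset(self.labels | labels))


@dataclass(frozen=True)
class LabelAssignment:
    """Annotation-report row: how much of a catalog entry is called."""

    label: str
    direction: str | None
    covered_fraction: float
    assigned: bool
    note: str = ""


def estimate_copy_number(segment_mean: float) -> float:
    """CN = 2 * 2^mean against a diploid reference."""
    return 2.0 * 2.0**segment_mean


def estimate_clonal_fraction(cn: float, direction: str) -> tuple[float, bool]:
    """Clonal fraction implied by a single-copy event, with an
    out-of-model flag.

    gain: f = cn - 2; loss: f = 2 - cn. Values outside [0, 1] (multi-copy
    amplification, homozygous or over-complete loss) are clipped and
    flagged out-of-model.
    """
    if cn <= 0:
        raise ValueError("copy number must be positive")
    if direction == "gain":
        f = cn - 2.0
    elif direction == "loss":
        f = 2.0 - cn
    else:
        raise ValueError(f"unknown direction {direction!r}")
    out_of_model = not (0.0 <= f <= 1.0)
    return min(max(f, 0.0), 1.0), out_of_model


def call_segments(
    segments: Sequence[Segment], config: CallingConfig | None = None
) -> list[CnvCall]:
    """Report a CNV for every segment at or beyond the CN cutoffs.

    Segments strictly between the cutoffs produce no call; the boundary
    values themselves are inclusive.
    """
    config = config or CallingConfig()
    calls = []
    for seg in segments:
        cn = estimate_copy_number(seg.mean)
        if cn >= config.dup_cutoff:
            direction = "gain"
        elif cn <= config.del_cutoff:
            direction = "loss"
        else:
            continue
        f, oom = estimate_clonal_fraction(cn, direction)
        calls.append(
            CnvCall(segment=seg, cn=cn, direction=direction,
                    clonal_fraction=f, out_of_model=oom)
        )
    return calls


def annotate_calls(
    calls: Sequence[CnvCall],
    catalog: AlterationCatalog,
    regions: Sequence[TargetRegion],
    config: CallingConfig | None = None,
) -> tuple[list[CnvCall], list[LabelAssignment]]:
    """Assign catalog labels to calls by targeted-base overlap.

    ``regions`` is the unmasked region list the segment indices refer to.
    For each catalog entry the targeted bases covered by same-direction
    called segments are summed; the label is assigned when the covered
    fraction reaches ``label_overlap`` (``whole_chrom_overlap`` for
    whole-chromosome entries). Calls in the wrong direction never receive
    the label — the mismatch is recorded in the report instead. Returns
    (annotated calls, per-label report).
    """
    config = config or CallingConfig()
    annotated = list(calls)
    report: list[LabelAssignment] = []
    for entry in catalog:
        if entry.scope == "rearrangement":
            continue
        member_idx = catalog.regions_for(entry.label, regions)
        targeted = sum(regions[i].length for i in member_idx)
        if targeted == 0:
            report.append(
                LabelAssignment(entry.label, entry.direction, 0.0, False,
                                "no targeted bases on panel")
            )
            continue
        member_set = set(member_idx)
        covered = 0
        wrong_direction = 0
        contributing: list[int] = []
        for ci, call in enumerate(annotated):
            seg_members = member_set.intersection(
                range(call.segment.start_index, call.segment.end_index)
            )
            if not seg_members:
                continue
            bases = sum(regions[i].length for i in seg_members)
            if call.direction == entry.direction:
                covered += bases
                contributing.append(ci)
            else:
                wrong_direction += bases
        frac = covered / targeted
        threshold = (
            config.whole_chrom_overlap
            if entry.scope == "whole_chromosome"
            else config.label_overlap
        )
        assigned = frac >= threshold
        note = ""
        if wrong_direction and not assigned:
            note = "direction mismatch over part of the entry"
        report.append(
            LabelAssignment(entry.label, entry.direction, frac, assigned, note)
        )
        if assigned:
            for ci in contributing:
                annotated[ci] = annotated[ci].with_labels({entry.label})
    return annotated, report
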