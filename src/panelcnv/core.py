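"""Core domain containers for targeted-panel CNV analysis.

Coordinates are 0-based half-open throughout (BED convention); the VCF
writer converts to 1-based on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "TargetRegion",
    "CoverageMatrix",
    "CatalogEntry",
    "AlterationCatalog",
    "genome_sort_key",
]


def _chrom_rank(chrom: str) -> tuple[int, str]:
    """Natural ordering for chromosome names: numeric first, then X, Y, M, rest."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (special[name.upper()], "")
    return (1000, name)


def genome_sort_key(chrom: str, start: int) -> tuple[tuple[int, str], int]:
    return (_chrom_rank(chrom), start)


@dataclass(frozen=True)
class TargetRegion:
    """One captured interval of the panel.

    Parameters
    ----------
    chrom : chromosome name, taken verbatim from the input (no prefix
        harmonisation is attempted).
    start, end : 0-based half-open interval.
    gc : GC fraction of the interval in [0, 1].
    gene : gene symbol, or "" when the region is not gene-annotated.
    catalog_labels : recurrent-alteration labels this region belongs to.
    """

    chrom: str
    start: int
    end: int
    gc: float
    gene: str = ""
    catalog_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc fraction {self.gc!r} outside [0, 1]")
        if not isinstance(self.catalog_labels, frozenset):
            object.__setattr__(self, "catalog_labels", frozenset(self.catalog_labels))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def sort_key(self):
        return genome_sort_key(self.chrom, self.start)

    def with_labels(self, labels: Iterable[str]) -> "TargetRegion":
        return TargetRegion(
            self.chrom, self.start, self.end, self.gc, self.gene,
            frozenset(self.catalog_labels | set(labels)),
        )


class CoverageMatrix:
    """Deduplicated read counts per (region, sample).

    Rows follow ``regions`` (genome order), columns follow ``samples``.
    Counts are overlapping-read counts, not mean depth: a read contributes
    one to every region it overlaps by at least one aligned base.
    """

    def __init__(
        self,
        regions: Sequence[TargetRegion],
        samples: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(regions), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(regions)} regions x {len(samples)} samples"
            )
        if np.any(counts < 0):
            raise ValueError("negative counts are not allowed")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        keys = [r.key for r in regions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate regions in panel")
        order = [r.sort_key() for r in regions]
        if order != sorted(order):
            raise ValueError("regions must be in genome order")
        self.regions: list[TargetRegion] = list(regions)
        self.samples: list[str] = list(samples)
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample)]

    def subset_samples(self, samples: Sequence[str]) -> "CoverageMatrix":
        idx = [self.sample_index(s) for s in samples]
        return CoverageMatrix(self.regions, list(samples), self.counts[:, idx])


@dataclass(frozen=True)
class CatalogEntry:
    """One recurrent-alteration label of the panel catalog.

    ``scope`` is one of ``region`` (a focal span, e.g. a gene), ``arm``
    (a chromosome-arm span such as del(5q)), ``whole_chromosome``
    (aneuploidy; carries no span), or ``rearrangement`` (translocations /
    inversions, categorical only — never called from read depth).
    ``direction`` is the expected copy direction, ``None`` for
    rearrangements.
    """

    label: str
    chroms: tuple[str, ...]
    direction: str | None  # "gain" | "loss" | None
    scope: str  # "region" | "arm" | "whole_chromosome" | "rearrangement"
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.scope not in {"region", "arm", "whole_chromosome", "rearrangement"}:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.direction not in {"gain", "loss", None}:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.scope == "whole_chromosome" and (
            self.start is not None or self.end is not None
        ):
            raise ValueError("whole_chromosome entries carry no start/end")
        if self.scope in {"region", "arm"} and (
            self.start is None or self.end is None or len(self.chroms) != 1
        ):
            raise ValueError(f"{self.scope} entry {self.label!r} needs chrom+span")

    @property
    def chrom(self) -> str:
        if len(self.chroms) != 1:
            raise ValueError(f"{self.label!r} spans multiple chromosomes")
        return self.chroms[0]

    def covers(self, region: TargetRegion) -> bool:
        """Whether a target region belongs to this catalog entry."""
        if self.scope == "rearrangement":
            return False
        if region.chrom not in self.chroms:
            return False
        if self.scope == "whole_chromosome":
            return True
        return region.start < self.end and self.start < region.end  # type: ignore[operator]


class AlterationCatalog:
    """Catalog of recurrent ("frequent") alterations covered by the panel."""

    def __init__(self, entries: Iterable[CatalogEntry]) -> None:
        self.entries: dict[str, CatalogEntry] = {}
        for e in entries:
            if e.label in self.entries:
                raise ValueError(f"duplicate catalog label {e.label!r}")
            self.entries[e.label] = e

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> CatalogEntry:
        try:
            return self.entries[label]
        except KeyError:
            raise KeyError(f"unknown catalog label {label!r}") from None

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def chromosomes_of(self, label: str) -> tuple[str, ...]:
        return self[label].chroms

    def regions_for(self, label: str, regions: Sequence[TargetRegion]) -> list[int]:
        """Indices of panel regions belonging to a catalog entry.

        Membership is the union of the entry's genomic span and any
        explicit per-region label annotation.
        """
        entry = self[label]
        return [
            i
            for i, r in enumerate(regions)
            if entry.covers(r) or label in r.catalog_labels
        ]

    def annotate_regions(
        self, regions: Sequence[TargetRegion]
    ) -> list[TargetRegion]:
        """Return regions with ``catalog_labels`` filled in from entry spans."""
        out = []
        for r in regions:
            labels = {e.label for e in self if e.covers(r)}
            out.append(r.with_labels(labels) if labels else r)
        return out

    def to_mapping(self) -> Mapping[str, dict]:
        return {
            e.label: {
                "chroms": list(e.chroms),
                "direction": e.direction,
                "scope": e.scope,
                "start": e.start,
                "end": e.end,
            }
            for e in self
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping]) -> "AlterationCatalog":
        entries = []
        for label, spec in mapping.items():
            entries.append(
                CatalogEntry(
                    label=label,
                    chroms=tuple(spec["chroms"]),
                    direction=spec.get("direction"),
                    scope=spec["scope"],
                    start=spec.get("start"),
                    end=spec.get("end"),
                )
            )
        return cls(entries)
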