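"""NGS-vs-cytogenetics concordance accounting.

Each recurrent alteration observed in a cohort is recorded with the set
of techniques that detected it (karyotype, FISH, NGS). Records are
categorised as detected by *both* methodologies (NGS plus at least one
cytogenetic technique), by *cytogenetics only*, or by *NGS only*, and
summarised as shares, per-chromosome frequencies and per-alteration
counts.

The package ships the discordant-alteration tables and aggregate counts
of a published 138-patient myeloid-neoplasm cohort study as fixtures
(``load_study_records`` / ``load_study_aggregates``); concordant
alterations of that cohort are available only as an aggregate count, so
the study-level tally combines the record tables with that aggregate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import AlterationCatalog

__all__ = [
    "TECHNIQUES",
    "ConcordanceRecord",
    "ConcordanceTally",
    "categorize",
    "tally_shares",
    "chromosome_frequencies",
    "records_chromosome_counts",
    "count_by_alteration",
    "below_fish_cutoff",
    "frequency_percent",
    "read_records",
    "write_records",
    "load_study_records",
    "load_study_aggregates",
    "load_study_catalog",
    "study_tally",
]

TECHNIQUES = frozenset({"karyotype", "FISH", "NGS"})
CYTOGENETIC_TECHNIQUES = frozenset({"karyotype", "FISH"})

DISEASES = frozenset({"AML", "MDS", "MPN", "MDS/MPN", "MPAL", "ALL"})


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the printed precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate_to(x: float, ndigits: int = 0) -> float:
    """Truncate towards zero at the given precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


@dataclass(frozen=True)
class ConcordanceRecord:
    """One alteration in one patient, with the techniques that saw it."""

    patient: str
    disease: str
    alteration: str
    detected_by: frozenset[str]
    validation: str = ""
    fish_pct_uncultured: float | None = None
    fish_pct_cultured: float | None = None
    karyotype_clone: tuple[int, int] | None = None  # (abnormal, total) metaphases
    note: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.detected_by, frozenset):
            object.__setattr__(self, "detected_by", frozenset(self.detected_by))
        if not self.detected_by:
            raise ValueError(
                f"record {self.patient}/{self.alteration}: empty detected_by"
            )
        unknown = self.detected_by - TECHNIQUES
        if unknown:
            raise ValueError(f"unknown techniques {sorted(unknown)}")
        if self.disease not in DISEASES:
            raise ValueError(f"unknown disease {self.disease!r}")
        for pct in (self.fish_pct_uncultured, self.fish_pct_cultured):
            if pct is not None and not (0 <= pct <= 100):
                raise ValueError(f"FISH percentage {pct} outside [0, 100]")
        if self.karyotype_clone is not None:
            ab, tot = self.karyotype_clone
            if not (0 <= ab <= tot):
                raise ValueError(f"abnormal metaphases {ab} exceed total {tot}")


@dataclass
class ConcordanceTally:
    """Counts of alterations by detecting methodology."""

    n_both: int = 0
    n_cyto_only: int = 0
    n_ngs_only: int = 0

    @property
    def total(self) -> int:
        return self.n_both + self.n_cyto_only + self.n_ngs_only

    def __add__(self, other: "ConcordanceTally") -> "ConcordanceTally":
        return ConcordanceTally(
            self.n_both + other.n_both,
            self.n_cyto_only + other.n_cyto_only,
            self.n_ngs_only + other.n_ngs_only,
        )


def categorize(records: Iterable[ConcordanceRecord]) -> ConcordanceTally:
    """Tally records by detecting methodology.

    Cytogenetics = karyotype or FISH. An alteration seen by NGS and by at
    least one cytogenetic technique counts as *both*.
    """
    tally = ConcordanceTally()
    for rec in records:
        cyto = bool(rec.detected_by & CYTOGENETIC_TECHNIQUES)
        ngs = "NGS" in rec.detected_by
        if cyto and ngs:
            tally.n_both += 1
        elif cyto:
            tally.n_cyto_only += 1
        else:
            tally.n_ngs_only += 1
    return tally


def tally_shares(tally: ConcordanceTally) -> tuple[float, float, float]:
    """Percent shares (both, cytogenetics-only, NGS-only) at one decimal.

    The displayed precision truncates towards zero (e.g. 10/66 ->
    15.1515% -> 15.1), the convention the source tables follow for
    shares; integer chromosome percents instead round half-up (see
    :func:`frequency_percent`).
    """
    if tally.total == 0:
        raise ValueError("cannot compute shares of an empty tally")
    return tuple(  # type: ignore[return-value]
        truncate_to(100.0 * n / tally.total, 1)
        for n in (tally.n_both, tally.n_cyto_only, tally.n_ngs_only)
    )


def frequency_percent(count: int, total: int, ndigits: int = 0) -> float:
    """Percent frequency at the requested precision, half-up rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def chromosome_frequencies(
    counts: Mapping[str, int], total: int
) -> dict[str, tuple[int, float]]:
    """Per-chromosome (count, integer percent of ``total``)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {
        chrom: (n, frequency_percent(n, total, ndigits=0))
        for chrom, n in counts.items()
    }


def records_chromosome_counts(
    records: Iterable[ConcordanceRecord], catalog: AlterationCatalog
) -> dict[str, int]:
    """Count alterations per involved chromosome.

    Labels are resolved through the catalog; alterations touching several
    chromosomes (translocations) count once per involved chromosome.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if rec.alteration not in catalog:
            raise KeyError(f"alteration label {rec.alteration!r} not in catalog")
        for chrom in catalog.chromosomes_of(rec.alteration):
            counts[chrom] = counts.get(chrom, 0) + 1
    return counts


def count_by_alteration(
    records: Iterable[ConcordanceRecord], label: str
) -> int:
    """Number of records whose alteration label matches exactly."""
    return sum(1 for rec in records if rec.alteration == label)


def below_fish_cutoff(
    records: Iterable[ConcordanceRecord], threshold_pct: float
) -> list[ConcordanceRecord]:
    """Records whose uncultured-sample FISH percentage is below the
    threshold; records without a FISH value are excluded."""
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold must be in (0, 100]")
    return [
        rec
        for rec in records
        if rec.fish_pct_uncultured is not None
        and rec.fish_pct_uncultured < threshold_pct
    ]


# ---------------------------------------------------------------- records IO

_COLUMNS = [
    "patient",
    "disease",
    "alteration",
    "detected_by",
    "validation",
    "fish_pct_uncultured",
    "fish_pct_cultured",
    "karyotype_abnormal",
    "karyotype_total",
    "note",
]


def read_records(path: str | Path) -> list[ConcordanceRecord]:
    """Read concordance records from a TSV with the packaged table schema."""
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    missing = [c for c in ("patient", "disease", "alteration", "detected_by")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        clone = None
        ab, tot = row.get("karyotype_abnormal"), row.get("karyotype_total")
        if pd.notna(ab) and pd.notna(tot):
            clone = (int(ab), int(tot))

        def _opt(v):
            return None if pd.isna(v) else float(v)

        records.append(
            ConcordanceRecord(
                patient=str(row["patient"]),
                disease=str(row["disease"]),
                alteration=str(row["alteration"]),
                detected_by=frozenset(str(row["detected_by"]).split(",")),
                validation="" if pd.isna(row.get("validation")) else str(row["validation"]),
                fish_pct_uncultured=_opt(row.get("fish_pct_uncultured")),
                fish_pct_cultured=_opt(row.get("fish_pct_cultured")),
                karyotype_clone=clone,
                note="" if pd.isna(row.get("note")) else str(row["note"]),
            )
        )
    return records


def write_records(records: Sequence[ConcordanceRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient": r.patient,
                "disease": r.disease,
                "alteration": r.alteration,
                "detected_by": ",".join(sorted(r.detected_by)),
                "validation": r.validation,
                "fish_pct_uncultured": r.fish_pct_uncultured,
                "fish_pct_cultured": r.fish_pct_cultured,
                "karyotype_abnormal": r.karyotype_clone[0] if r.karyotype_clone else None,
                "karyotype_total": r.karyotype_clone[1] if r.karyotype_clone else None,
                "note": r.note,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- packaged fixtures


def _data_path(name: str):
    return resources.files("panelcnv.data").joinpath(name)


def load_study_records() -> tuple[list[ConcordanceRecord], list[ConcordanceRecord]]:
    """The discordant-alteration tables of the packaged cohort study.

    Returns (cytogenetics-only records, NGS-detected records). The second
    table contains nine rows: eight NGS-only alterations plus one
    rearrangement whose presence was also flagged by a break-apart FISH
    probe (detected_by includes FISH), which therefore categorises as
    *both* rather than NGS-only.
    """
    with resources.as_file(_data_path("cyto_only_alterations.tsv")) as p:
        cyto = read_records(p)
    with resources.as_file(_data_path("ngs_only_alterations.tsv")) as p:
        ngs = read_records(p)
    return cyto, ngs


def load_study_aggregates() -> dict:
    """Aggregate counts of the packaged cohort study (totals, chromosome
    counts, disease-level frequencies)."""
    with resources.as_file(_data_path("study_aggregates.json")) as p:
        return json.loads(Path(p).read_text())


def load_study_catalog() -> AlterationCatalog:
    """Label -> chromosome/direction/scope catalog for the study's
    alteration vocabulary."""
    with resources.as_file(_data_path("study_catalog.json")) as p:
        return AlterationCatalog.from_mapping(json.loads(Path(p).read_text()))


def study_tally() -> ConcordanceTally:
    """Full-cohort tally: the discordant record tables plus the aggregate
    count of concordant alterations not listed per patient."""
    cyto, ngs = load_study_records()
    agg = load_study_aggregates()
    return categorize(cyto + ngs) + ConcordanceTally(n_both=agg["n_both_unlisted"])
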