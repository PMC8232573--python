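"""Readers and writers for panel definitions, coverage matrices, catalogs
and call sets, plus optional per-region depth extraction from aligned reads.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .core import AlterationCatalog, CoverageMatrix, TargetRegion

if TYPE_CHECKING:  # pragma: no cover
    from .calling import CnvCall

__all__ = [
    "read_targets",
    "read_coverage_matrix",
    "write_coverage_matrix",
    "extract_region_depths",
    "read_catalog",
    "write_catalog",
    "write_calls",
    "read_calls_tsv",
]

#: read filters applied when counting depth from a BAM: keep primary,
#: properly-paired, mapped, non-duplicate alignments with mapQ >= 60.
MIN_MAPQ = 60


def gc_fraction(sequence: str) -> float:
    """GC fraction of a sequence; ambiguous bases excluded from the denominator."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / acgt


def read_targets(
    bed_path: str | Path,
    fasta_path: str | Path | None = None,
    catalog: AlterationCatalog | None = None,
) -> list[TargetRegion]:
    """Read panel target regions from a BED file, sorted in genome order.

    BED columns: chrom, start, end, then optional column 4 = gene symbol
    and optional numeric column 5 = GC fraction. When GC is not supplied,
    ``fasta_path`` must point to an indexed FASTA from which it is
    computed as (G+C)/(A+C+G+T) over the interval. If a ``catalog`` is
    given, each region is annotated with the catalog labels whose span
    covers it.
    """
    fasta = None
    regions: list[TargetRegion] = []
    try:
        with open(bed_path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{bed_path}: line {lineno}: expected >=3 tab-separated "
                        f"columns, got {len(fields)}"
                    )
                try:
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{bed_path}: line {lineno}: malformed coordinates"
                    ) from exc
                gene = fields[3] if len(fields) > 3 else ""
                if len(fields) > 4 and fields[4] not in ("", "."):
                    try:
                        gc = float(fields[4])
                    except ValueError as exc:
                        raise ValueError(
                            f"{bed_path}: line {lineno}: GC column is not numeric"
                        ) from exc
                else:
                    if fasta is None:
                        if fasta_path is None:
                            raise ValueError(
                                f"{bed_path}: line {lineno}: no GC column and no "
                                "FASTA supplied to compute it"
                            )
                        from pyfaidx import Fasta

                        fasta = Fasta(str(fasta_path))
                    if chrom not in fasta:
                        raise KeyError(
                            f"{bed_path}: line {lineno}: contig {chrom!r} absent "
                            "from FASTA"
                        )
                    gc = gc_fraction(str(fasta[chrom][start:end]))
                try:
                    regions.append(TargetRegion(chrom, start, end, gc, gene))
                except ValueError as exc:
                    raise ValueError(f"{bed_path}: line {lineno}: {exc}") from exc
    finally:
        if fasta is not None:
            fasta.close()
    regions.sort(key=lambda r: r.sort_key())
    keys = [r.key for r in regions]
    if len(set(keys)) != len(keys):
        raise ValueError(f"{bed_path}: duplicate regions in panel")
    if catalog is not None:
        regions = catalog.annotate_regions(regions)
    return regions


def read_coverage_matrix(
    tsv_path: str | Path, regions: Sequence[TargetRegion]
) -> CoverageMatrix:
    """Read a regions x samples coverage TSV keyed by (chrom, start, end).

    The TSV has a header row with columns chrom, start, end followed by one
    numeric column per sample. Every panel region must be present exactly
    once and no extra rows are tolerated.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{tsv_path}: first three columns must be {required}, "
            f"got {list(df.columns[:3])}"
        )
    samples = list(df.columns[3:])
    if not samples:
        raise ValueError(f"{tsv_path}: no sample columns")
    df = df.set_index(["chrom", "start", "end"])
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{tsv_path}: duplicate region rows: {dupes}")
    wanted = pd.MultiIndex.from_tuples([r.key for r in regions])
    missing = wanted.difference(df.index)
    if len(missing):
        raise ValueError(
            f"{tsv_path}: missing coverage rows for regions: {list(missing)}"
        )
    extra = df.index.difference(wanted)
    if len(extra):
        raise ValueError(
            f"{tsv_path}: rows for regions not in the panel: {list(extra)}"
        )
    counts = df.loc[wanted, samples].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError(f"{tsv_path}: negative counts present")
    return CoverageMatrix(regions, samples, counts)


def write_coverage_matrix(matrix: CoverageMatrix, tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in matrix.regions],
            "start": [r.start for r in matrix.regions],
            "end": [r.end for r in matrix.regions],
        }
    )
    for j, sample in enumerate(matrix.samples):
        df[sample] = matrix.counts[:, j]
    df.to_csv(tsv_path, sep="\t", index=False)


def extract_region_depths(
    bam_path: str | Path, regions: Sequence[TargetRegion]
) -> np.ndarray:
    """Count retained reads overlapping each region in a coordinate-sorted BAM.

    Retained reads are primary, properly paired, mapped, not flagged as PCR
    duplicates, and have mapping quality >= 60. A read is counted in every
    region it overlaps by at least one aligned base.
    """
    import pysam

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path}: BAM index required (run samtools index)")
        bam_contigs = set(bam.references)
        bad = sorted({r.chrom for r in regions} - bam_contigs)
        if bad:
            raise ValueError(
                f"{bam_path}: contigs in panel but not in BAM header: {bad}"
            )
        out = np.zeros(len(regions), dtype=float)
        for i, region in enumerate(regions):
            n = 0
            for read in bam.fetch(region.chrom, region.start, region.end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or not read.is_proper_pair
                    or read.mapping_quality < MIN_MAPQ
                ):
                    continue
                n += 1
            out[i] = n
    return out


def read_catalog(path: str | Path) -> AlterationCatalog:
    """Read an alteration catalog from JSON (label -> entry mapping)."""
    with open(path) as fh:
        mapping = json.load(fh)
    return AlterationCatalog.from_mapping(mapping)


def write_catalog(catalog: AlterationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(catalog.to_mapping(), fh, indent=2)
        fh.write("\n")


_TSV_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_regions",
    "log2_ratio",
    "copy_number",
    "direction",
    "clonal_fraction",
    "out_of_model",
    "labels",
]


def write_calls(
    calls: Sequence["CnvCall"],
    out_path: str | Path,
    dialect: str = "tsv",
    sample: str = "SAMPLE",
) -> None:
    """Write CNV calls as TSV or as VCFv4.2 with symbolic <DEL>/<DUP> alleles."""
    if dialect == "tsv":
        _write_calls_tsv(calls, out_path)
    elif dialect == "vcf":
        _write_calls_vcf(calls, out_path, sample)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_calls_tsv(calls: Sequence["CnvCall"], out_path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.segment.chrom,
                "start": c.segment.start,
                "end": c.segment.end,
                "n_regions": c.segment.n_markers,
                "log2_ratio": f"{c.segment.mean:.6g}",
                "copy_number": f"{c.cn:.6g}",
                "direction": c.direction,
                "clonal_fraction": f"{c.clonal_fraction:.6g}",
                "out_of_model": int(c.out_of_model),
                "labels": ",".join(sorted(c.labels)) if c.labels else ".",
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(out_path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV call file back into a DataFrame (labels as sets)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["labels"] = [
        set() if lab in (".", "", None) or pd.isna(lab) else set(str(lab).split(","))
        for lab in df["labels"]
    ]
    return df


def _write_calls_vcf(
    calls: Sequence["CnvCall"], out_path: str | Path, sample: str
) -> None:
    # VCF output is deliberately minimal: symbolic alleles with the segment
    # summary in INFO; POS is start+1 (0-based half-open -> 1-based).
    contigs: list[str] = []
    for c in calls:
        if c.segment.chrom not in contigs:
            contigs.append(c.segment.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={chrom}>" for chrom in contigs],
        '##ALT=<ID=DEL,Description="Copy number loss">',
        '##ALT=<ID=DUP,Description="Copy number gain">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the segment">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="DEL or DUP">',
        '##INFO=<ID=CN,Number=1,Type=Float,Description="Copy-number estimate">',
        '##INFO=<ID=LOG2,Number=1,Type=Float,Description="Mean log2 ratio">',
        '##INFO=<ID=LABELS,Number=.,Type=String,Description="Catalog labels">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for k, c in enumerate(calls, start=1):
        svtype = "DUP" if c.direction == "gain" else "DEL"
        info = (
            f"END={c.segment.end};SVTYPE={svtype};CN={c.cn:.4f};"
            f"LOG2={c.segment.mean:.4f}"
        )
        if c.labels:
            safe = [lab.replace(" ", "_").replace(";", "_") for lab in sorted(c.labels)]
            info += ";LABELS=" + ",".join(safe)
        lines.append(
            f"{c.segment.chrom}\t{c.segment.start + 1}\tcnv{k}\tN\t<{svtype}>\t."
            f"\tPASS\t{info}\tGT\t./."
        )
    Path(out_path).write_text("\n".join(lines) + "\n")
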