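"""Synthetic capture-panel cohorts with known copy-number truth.

Emulates the data a ~3 Mb myeloid capture panel produces: per-region
deduplicated read counts with per-region capture efficiency, per-sample
library size and GC-response bias, and negative-binomial count noise; a
recurrent-alteration catalog over the simulated panel; clonal-fraction-
scaled spiked CNVs; and cytogenetic detection emulators (metaphase
karyotyping and interphase FISH) so NGS-vs-cytogenetics concordance can
be studied end to end against a known truth table.

The count model for region r in sample s is

    mu_rs = N_s * p_r * g_s(gc_r) * CN_rs / 2

with library size N_s log-normal around the depth anchor (median target
coverage ~300x), capture weight p_r proportional to region length times a
log-normal capture efficiency, g_s a per-sample quadratic GC response
normalised to mean 1, and CN_rs = 2 + copies * f inside a spiked event.
Counts are negative-binomial around mu (gamma-Poisson mixture), Poisson
in the dispersion -> 0 limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlterationCatalog, CatalogEntry, CoverageMatrix, TargetRegion

__all__ = [
    "SimulationConfig",
    "SpikedEvent",
    "simulate_panel",
    "simulate_coverage",
    "emulate_karyotype",
    "emulate_fish",
    "make_concordance_cohort",
]

#: FISH positivity cutoffs (percent of nuclei) by probe type
FISH_CUTOFFS = {"single_locus": 7.0, "break_apart": 7.0, "dual_fusion": 2.3}

# genes carried by the panel for mutation screening; a subset doubles as
# single-gene CNV catalog entries (secondary CNVs)
_PANEL_GENES: dict[str, str] = {
    "MPL": "chr1", "NRAS": "chr1", "DNMT3A": "chr2", "IDH1": "chr2",
    "SF3B1": "chr2", "GATA2": "chr3", "KIT": "chr4", "TET2": "chr4",
    "NPM1": "chr5", "EZH2": "chr7", "IKZF1": "chr7", "JAK2": "chr9",
    "CBL": "chr11", "WT1": "chr11", "ETV6": "chr12", "KRAS": "chr12",
    "FLT3": "chr13", "IDH2": "chr15", "NF1": "chr17", "SRSF2": "chr17",
    "TP53": "chr17", "CALR": "chr19", "CEBPA": "chr19", "ASXL1": "chr20",
    "RUNX1": "chr21", "U2AF1": "chr21",
}

_CNV_GENES = [
    "RUNX1", "IKZF1", "EZH2", "NF1", "WT1", "TP53", "ETV6", "TET2",
    "DNMT3A", "ASXL1", "CBL", "JAK2", "MPL", "GATA2", "KIT", "NPM1",
    "SF3B1", "CEBPA",
]


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a 3 Mb capture panel sequenced to a median
    deduplicated target coverage of ~300x (about four million retained
    2 x 101 bp read pairs per sample), with modest sample-to-sample
    library-size and GC-response variation and mildly overdispersed
    counts.
    """

    n_regions: int = 2000
    target_size_bp: int = 3_000_000
    chromosomes: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
    region_length_sigma: float = 0.3
    gc_beta_a: float = 12.0
    gc_beta_b: float = 14.0
    target_depth: float = 300.0
    read_length: int = 101
    library_size_sigma: float = 0.25
    capture_sigma: float = 0.5
    gc_center: float = 0.45
    gc_linear_sd: float = 0.5
    gc_quadratic_sd: float = 2.0
    dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < len(self.chromosomes):
            raise ValueError("need at least one region per chromosome")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass(frozen=True)
class SpikedEvent:
    """Ground-truth CNV spiked into a simulated sample.

    Either a catalog ``label`` or an explicit (chrom, start, end) span;
    ``copies`` is the integer copy change in carrier cells (+1 trisomy /
    duplication, -1 deletion); ``clonal_fraction`` is the fraction of
    cells carrying it, so bulk CN = 2 + copies * clonal_fraction.
    """

    clonal_fraction: float
    label: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    copies: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.clonal_fraction <= 1):
            raise ValueError("clonal_fraction must be in (0, 1]")
        if self.copies == 0:
            raise ValueError("copies must be non-zero")
        if self.label is None and (
            self.chrom is None or self.start is None or self.end is None
        ):
            raise ValueError("event needs a catalog label or an explicit span")

    @property
    def direction(self) -> str:
        return "gain" if self.copies > 0 else "loss"

    @property
    def expected_cn(self) -> float:
        return 2.0 + self.copies * self.clonal_fraction

    def member_regions(
        self,
        regions: Sequence[TargetRegion],
        catalog: AlterationCatalog | None,
    ) -> list[int]:
        if self.label is not None:
            if catalog is None:
                raise ValueError("catalog required to resolve labeled events")
            idx = catalog.regions_for(self.label, regions)
        else:
            idx = [
                i
                for i, r in enumerate(regions)
                if r.chrom == self.chrom
                and r.start < self.end  # type: ignore[operator]
                and self.start < r.end  # type: ignore[operator]
            ]
        if not idx:
            raise ValueError(f"event {self} overlaps no panel region")
        return idx


def _panel_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 101])


def _coverage_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 202])


def simulate_panel(
    config: SimulationConfig,
) -> tuple[list[TargetRegion], AlterationCatalog]:
    """Build a synthetic target panel and its recurrent-alteration catalog.

    Regions are spread over the configured chromosomes with log-normal
    lengths rescaled so the total targeted span matches
    ``target_size_bp``, and Beta-distributed GC. The catalog carries the
    classic recurrent myeloid lesions (del(5q), del(7q)/monosomy 7,
    trisomy 8, del(12p), del(17p), del(20q)) as arm or whole-chromosome
    entries anchored to the simulated coordinates, plus per-gene gain and
    loss entries for the CNV genes. Deterministic given (config, seed).
    """
    rng = _panel_rng(config)
    chroms = list(config.chromosomes)
    n_chrom = len(chroms)
    per = np.full(n_chrom, config.n_regions // n_chrom)
    per[: config.n_regions - per.sum()] += 1

    lengths = rng.lognormal(mean=0.0, sigma=config.region_length_sigma,
                            size=config.n_regions)
    lengths = np.maximum(
        50, np.round(lengths * config.target_size_bp / lengths.sum()).astype(int)
    )
    gcs = rng.beta(config.gc_beta_a, config.gc_beta_b, size=config.n_regions)

    regions: list[TargetRegion] = []
    arm_boundaries: dict[str, int] = {}
    chrom_spans: dict[str, tuple[int, int]] = {}
    k = 0
    for ci, chrom in enumerate(chroms):
        pos = 1_000_000
        n_here = int(per[ci])
        boundary_region = int(np.floor(0.4 * n_here))  # p-arm = first 40%
        for local in range(n_here):
            pos += int(rng.integers(5_000, 100_000))
            length = int(lengths[k])
            regions.append(
                TargetRegion(chrom, pos, pos + length, float(gcs[k]))
            )
            if local == boundary_region:
                arm_boundaries[chrom] = pos - 2_500
            pos += length
            k += 1
        chrom_spans[chrom] = (0, pos + 1_000_000)
        arm_boundaries.setdefault(chrom, pos // 2)

    entries: list[CatalogEntry] = []

    def arm(label, chrom, which, direction):
        b = arm_boundaries[chrom]
        lo, hi = chrom_spans[chrom]
        start, end = (lo, b) if which == "p" else (b, hi)
        entries.append(CatalogEntry(label, (chrom,), direction, "arm", start, end))

    arm("del(5q)", "chr5", "q", "loss")
    arm("del(7q)", "chr7", "q", "loss")
    arm("del(12p)", "chr12", "p", "loss")
    arm("del(17p)", "chr17", "p", "loss")
    arm("del(20q)", "chr20", "q", "loss")
    entries.append(CatalogEntry("Monosomy 7", ("chr7",), "loss", "whole_chromosome"))
    entries.append(CatalogEntry("Trisomy 8", ("chr8",), "gain", "whole_chromosome"))
    entries.append(CatalogEntry("Trisomy 19", ("chr19",), "gain", "whole_chromosome"))

    # place each panel gene on a short run of consecutive regions of its
    # host chromosome, away from the first/last region
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    gene_regions: dict[str, tuple[int, int]] = {}
    used: dict[str, int] = {c: 1 for c in chroms}
    for gene, chrom in _PANEL_GENES.items():
        if chrom not in by_chrom:
            continue
        idxs = by_chrom[chrom]
        run = min(6, max(2, len(idxs) // 12))
        lo = used[chrom]
        hi = min(lo + run, len(idxs) - 1)
        if hi <= lo:
            continue
        used[chrom] = hi + 1
        first, last = idxs[lo], idxs[hi - 1]
        gene_regions[gene] = (regions[first].start, regions[last].end)
        for i in idxs[lo:hi]:
            r = regions[i]
            regions[i] = TargetRegion(r.chrom, r.start, r.end, r.gc, gene,
                                      r.catalog_labels)
    for gene in _CNV_GENES:
        if gene not in gene_regions:
            continue
        start, end = gene_regions[gene]
        chrom = _PANEL_GENES[gene]
        for direction in ("loss", "gain"):
            entries.append(
                CatalogEntry(f"{gene} {direction}", (chrom,), direction,
                             "region", start, end)
            )

    catalog = AlterationCatalog(entries)
    return catalog.annotate_regions(regions), catalog


def simulate_coverage(
    regions: Sequence[TargetRegion],
    config: SimulationConfig,
    events: Mapping[str, Sequence[SpikedEvent]],
    catalog: AlterationCatalog | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CoverageMatrix, pd.DataFrame]:
    """Simulate a coverage matrix for the given samples and spiked events.

    ``events`` maps sample id -> its spiked events (empty list = diploid).
    Returns the matrix and a truth table (one row per spiked event with
    its resolved span, direction, clonal fraction and expected bulk CN).
    Deterministic given (config, seed).
    """
    if rng is None:
        rng = _coverage_rng(config)
    samples = list(events.keys())
    n_regions, n_samples = len(regions), len(samples)
    if n_samples == 0:
        raise ValueError("no samples requested")

    lengths = np.array([r.length for r in regions], dtype=float)
    gc = np.array([r.gc for r in regions])

    efficiency = rng.lognormal(0.0, config.capture_sigma, size=n_regions)
    p = lengths * efficiency
    p /= p.sum()

    n0 = config.target_depth * lengths.sum() / (2 * config.read_length)
    lib = n0 * rng.lognormal(0.0, config.library_size_sigma, size=n_samples)

    a = rng.normal(0.0, config.gc_linear_sd, size=n_samples)
    b = rng.normal(0.0, config.gc_quadratic_sd, size=n_samples)
    centred = gc - config.gc_center
    g = 1.0 + a[None, :] * centred[:, None] + b[None, :] * centred[:, None] ** 2
    g = np.maximum(g, 0.05)
    g /= g.mean(axis=0, keepdims=True)

    cn = np.full((n_regions, n_samples), 2.0)
    truth_rows = []
    for j, sample in enumerate(samples):
        for ev in events[sample]:
            idx = ev.member_regions(regions, catalog)
            cn[idx, j] = 2.0 + ev.copies * ev.clonal_fraction
            truth_rows.append(
                {
                    "sample": sample,
                    "label": ev.label or "",
                    "chrom": ev.chrom or regions[idx[0]].chrom,
                    "start": ev.start if ev.start is not None else regions[idx[0]].start,
                    "end": ev.end if ev.end is not None else regions[idx[-1]].end,
                    "n_regions": len(idx),
                    "direction": ev.direction,
                    "copies": ev.copies,
                    "clonal_fraction": ev.clonal_fraction,
                    "expected_cn": ev.expected_cn,
                }
            )

    mu = lib[None, :] * p[:, None] * g * cn / 2.0
    if config.dispersion > 0:
        lam = rng.gamma(shape=1.0 / config.dispersion,
                        scale=mu * config.dispersion)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "label", "chrom", "start", "end", "n_regions",
                 "direction", "copies", "clonal_fraction", "expected_cn"],
    )
    return CoverageMatrix(list(regions), samples, counts), truth


def emulate_karyotype(
    f: float,
    n_metaphases: int = 20,
    growth_bias: float = 1.3,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[int, int, bool]:
    """Metaphase karyotyping of a clone at fraction ``f``.

    The abnormal-metaphase count is Binomial(n, min(1, f * growth_bias));
    ``growth_bias`` > 1 models over-representation of the abnormal clone
    in culture. The alteration is reported when at least two abnormal
    metaphases are seen (clonality convention for gains and structural
    events). Returns (abnormal, total, detected).
    """
    if not (0 <= f <= 1):
        raise ValueError("clonal fraction must be in [0, 1]")
    if n_metaphases < 1:
        raise ValueError("need at least one metaphase")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = min(1.0, f * growth_bias)
    abnormal = int(rng.binomial(n_metaphases, p))
    return abnormal, n_metaphases, abnormal >= 2


def emulate_fish(
    f: float,
    n_nuclei: int = 200,
    probe_type: str = "single_locus",
    fp_floor: float = 0.01,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[float, bool]:
    """Interphase FISH of a clone at fraction ``f``.

    Positive nuclei are Binomial(n, min(1, f + fp_floor)) where
    ``fp_floor`` is a small technical false-positive rate; the observed
    percentage is compared against the probe-type cutoff (7% for
    single-locus and break-apart probes, 2.3% for dual-fusion probes).
    Returns (observed percent, positive flag).
    """
    if not (0 <= f <= 1):
        raise ValueError("clonal fraction must be in [0, 1]")
    if probe_type not in FISH_CUTOFFS:
        raise ValueError(f"unknown probe type {probe_type!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = min(1.0, f + fp_floor)
    k = int(rng.binomial(n_nuclei, p))
    pct = 100.0 * k / n_nuclei
    return pct, pct >= FISH_CUTOFFS[probe_type]


def make_concordance_cohort(
    regions: Sequence[TargetRegion],
    catalog: AlterationCatalog,
    patient_events: Mapping[str, Sequence[SpikedEvent]],
    config: SimulationConfig,
    n_controls: int = 8,
    diseases: Mapping[str, str] | None = None,
    norm_config=None,
    seg_config=None,
    call_config=None,
):
    """Run the full NGS pipeline and the cytogenetics emulators on one
    simulated cohort, producing concordance records against known truth.

    Each patient's events must be catalog-labelled. Patients share a pool
    of ``n_controls`` event-free control samples. Returns
    (records, missed) where ``records`` are
    :class:`~panelcnv.concordance.ConcordanceRecord` objects for every
    alteration detected by at least one technique and ``missed`` lists
    (patient, label) pairs no technique detected.
    """
    from .calling import CallingConfig
    from .concordance import ConcordanceRecord
    from .normalization import NormalizationConfig
    from .pipeline import call_case
    from .segmentation import SegmentationConfig

    norm_config = norm_config or NormalizationConfig()
    seg_config = seg_config or SegmentationConfig(seed=config.seed)
    call_config = call_config or CallingConfig()
    diseases = diseases or {}

    controls = {f"control{i + 1}": [] for i in range(n_controls)}
    all_events: dict[str, Sequence[SpikedEvent]] = {**controls, **patient_events}
    matrix, _truth = simulate_coverage(regions, config, all_events, catalog)
    emu_rng = np.random.default_rng([config.seed, 303])

    records: list[ConcordanceRecord] = []
    missed: list[tuple[str, str]] = []
    for patient, evs in patient_events.items():
        result = call_case(
            matrix, patient, norm_config, seg_config, call_config, catalog,
            allow_best=True,
        )
        ngs_labels = set().union(*(c.labels for c in result.calls)) \
            if result.calls else set()
        for ev in evs:
            if ev.label is None:
                raise ValueError("concordance cohorts need labelled events")
            detected = set()
            if ev.label in ngs_labels:
                detected.add("NGS")
            ab, tot, karyo_hit = emulate_karyotype(
                ev.clonal_fraction, rng=emu_rng
            )
            if karyo_hit:
                detected.add("karyotype")
            fish_pct, fish_hit = emulate_fish(ev.clonal_fraction, rng=emu_rng)
            if fish_hit:
                detected.add("FISH")
            if not detected:
                missed.append((patient, ev.label))
                continue
            records.append(
                ConcordanceRecord(
                    patient=patient,
                    disease=diseases.get(patient, "AML"),
                    alteration=ev.label,
                    detected_by=frozenset(detected),
                    fish_pct_uncultured=round(fish_pct, 1),
                    karyotype_clone=(ab, tot),
                )
            )
    return records, missed
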