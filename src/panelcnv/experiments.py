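"""Replicated synthetic experiments characterising the caller.

Three standing experiments, each run under the package's study
conditions (2000-region ~3 Mb panel, ~300x median deduplicated coverage,
eight event-free controls) unless scaled down explicitly:

* detection limit — a whole-chromosome single-copy gain is callable when
  its bulk copy number clears the 2.5 cutoff (clonal fraction >= 0.5)
  and invisible below it;
* parameter recovery — an 80%-clonal del(12p) is recovered, labelled and
  its copy number estimated accurately;
* false-positive control — all-diploid samples yield (nearly) no calls.

Each experiment returns plain numbers so callers can summarise or assert
on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import CallingConfig
from .core import AlterationCatalog, TargetRegion
from .normalization import NormalizationConfig
from .pipeline import call_case
from .segmentation import SegmentationConfig
from .simulate import SimulationConfig, SpikedEvent, simulate_coverage, simulate_panel

__all__ = [
    "DetectionLimitResult",
    "RecoveryResult",
    "detection_limit_experiment",
    "recovery_experiment",
    "false_positive_experiment",
]

#: permutations per CBS split test in the replicated experiments; enough
#: resolution for the 0.01 split level while keeping replicates cheap
_EXPERIMENT_PERMUTATIONS = 500


def _configs(seed: int):
    norm = NormalizationConfig()
    seg = SegmentationConfig(seed=seed, n_permutations=_EXPERIMENT_PERMUTATIONS)
    call = CallingConfig()
    return norm, seg, call


def _replicate_seed(seed: int, replicate: int) -> int:
    return int(np.random.SeedSequence([seed, replicate]).generate_state(1)[0] % (2**31))


@dataclass
class DetectionLimitResult:
    """Call rates of a single-copy gain at two clonal fractions."""

    called_rate_clonal: float     # fraction of replicates called at f = 1.0
    called_rate_subclonal: float  # fraction of replicates called at f = 0.3
    mean_cn_clonal: float
    mean_cn_subclonal: float
    n_replicates: int


@dataclass
class RecoveryResult:
    """Recovery of a spiked arm-level deletion."""

    label_rate: float       # fraction of replicates with the correct label
    mean_cn_error: float    # mean |estimated CN - expected CN| when called
    mean_cn: float
    n_replicates: int


def _spiked_case(
    regions: list[TargetRegion],
    catalog: AlterationCatalog,
    sim: SimulationConfig,
    events: list[SpikedEvent],
    n_controls: int,
):
    samples: dict[str, list[SpikedEvent]] = {
        f"control{i + 1}": [] for i in range(n_controls)
    }
    samples["case"] = events
    matrix, _ = simulate_coverage(regions, sim, samples, catalog)
    norm, seg, call = _configs(sim.seed)
    return call_case(matrix, "case", norm, seg, call, catalog, allow_best=True)


def _event_cn(result, label: str, catalog, direction: str) -> float | None:
    """Copy number of the call(s) carrying a label, marker-weighted."""
    hits = [c for c in result.calls if label in c.labels and c.direction == direction]
    if not hits:
        return None
    w = np.array([c.segment.n_markers for c in hits], dtype=float)
    cn = np.array([c.cn for c in hits])
    return float(np.average(cn, weights=w))


def detection_limit_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    n_regions: int = 2000,
    n_controls: int = 8,
    f_clonal: float = 1.0,
    f_subclonal: float = 0.3,
    label: str = "Trisomy 8",
) -> DetectionLimitResult:
    """Call rate of a single-copy whole-chromosome gain at a fully clonal
    and a subclonal fraction.

    At f = 1.0 the bulk CN is ~3.0, above the 2.5 cutoff; at f = 0.3 it is
    ~2.3, below it — the subclonal event should stay uncalled even though
    metaphase karyotyping can see clones of that size.
    """
    called_hi = called_lo = 0
    cns_hi, cns_lo = [], []
    for rep in range(n_replicates):
        sim = SimulationConfig(n_regions=n_regions, seed=_replicate_seed(seed, rep))
        regions, catalog = simulate_panel(sim)
        for f, bucket_called, bucket_cn in (
            (f_clonal, "hi", cns_hi),
            (f_subclonal, "lo", cns_lo),
        ):
            res = _spiked_case(
                regions, catalog, sim,
                [SpikedEvent(clonal_fraction=f, label=label, copies=1)],
                n_controls,
            )
            cn = _event_cn(res, label, catalog, "gain")
            if cn is not None:
                if bucket_called == "hi":
                    called_hi += 1
                else:
                    called_lo += 1
                bucket_cn.append(cn)
            else:
                # CN of the covering segments even when below the cutoff
                idx = set(catalog.regions_for(label, res.track.regions))
                covered = [
                    s for s in res.segments
                    if idx.intersection(range(s.start_index, s.end_index))
                ]
                if covered:
                    w = np.array([s.n_markers for s in covered], dtype=float)
                    m = np.array([s.mean for s in covered])
                    bucket_cn.append(float(2 * 2 ** np.average(m, weights=w)))
    return DetectionLimitResult(
        called_rate_clonal=called_hi / n_replicates,
        called_rate_subclonal=called_lo / n_replicates,
        mean_cn_clonal=float(np.mean(cns_hi)) if cns_hi else float("nan"),
        mean_cn_subclonal=float(np.mean(cns_lo)) if cns_lo else float("nan"),
        n_replicates=n_replicates,
    )


def recovery_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    n_regions: int = 2000,
    n_controls: int = 8,
    label: str = "del(12p)",
    clonal_fraction: float = 0.8,
) -> RecoveryResult:
    """Recovery of a spiked arm-level deletion at the given clonality.

    The expected bulk copy number is 2 - f (1.2 at f = 0.8); success means
    the deletion is called and carries the arm label.
    """
    expected_cn = 2.0 - clonal_fraction
    labelled = 0
    errors, cns = [], []
    for rep in range(n_replicates):
        sim = SimulationConfig(n_regions=n_regions, seed=_replicate_seed(seed, rep))
        regions, catalog = simulate_panel(sim)
        res = _spiked_case(
            regions, catalog, sim,
            [SpikedEvent(clonal_fraction=clonal_fraction, label=label, copies=-1)],
            n_controls,
        )
        cn = _event_cn(res, label, catalog, "loss")
        if cn is not None:
            labelled += 1
            errors.append(abs(cn - expected_cn))
            cns.append(cn)
    return RecoveryResult(
        label_rate=labelled / n_replicates,
        mean_cn_error=float(np.mean(errors)) if errors else float("nan"),
        mean_cn=float(np.mean(cns)) if cns else float("nan"),
        n_replicates=n_replicates,
    )


def false_positive_experiment(
    n_samples: int = 100,
    seed: int = 0,
    n_regions: int = 2000,
    n_controls: int = 8,
    samples_per_batch: int = 10,
) -> float:
    """Mean number of called segments per all-diploid sample.

    Cases are simulated in batches sharing a panel and control pool; every
    call on any case is a false positive.
    """
    total_calls = 0
    done = 0
    batch = 0
    while done < n_samples:
        b = min(samples_per_batch, n_samples - done)
        sim = SimulationConfig(n_regions=n_regions, seed=_replicate_seed(seed, batch))
        regions, catalog = simulate_panel(sim)
        events: dict[str, list[SpikedEvent]] = {
            f"control{i + 1}": [] for i in range(n_controls)
        }
        for i in range(b):
            events[f"case{i + 1}"] = []
        matrix, _ = simulate_coverage(regions, sim, events, catalog)
        norm, seg, call = _configs(sim.seed)
        for i in range(b):
            res = call_case(matrix, f"case{i + 1}", norm, seg, call, catalog,
                            allow_best=True)
            total_calls += len(res.calls)
        done += b
        batch += 1
    return total_calls / n_samples
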