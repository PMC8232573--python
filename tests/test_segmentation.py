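"""Circular binary segmentation: statistic, permutation test, recursion."""

import numpy as np
import pytest

from panelcnv import (
    SegmentationConfig,
    TargetRegion,
    max_t_statistic,
    permutation_p,
    segment_chromosome,
    segment_genome,
)


def oracle_max_t(values, min_width):
    """Exhaustive O(n^2) arc search, computed independently from slices."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2 * min_width:
        return None, 0.0
    best_t, best_arc = -1.0, None
    tol = 1e-10 * max(1.0, float(np.sum(v * v))) / n
    for i in range(n):
        for j in range(i + min_width, n + 1):
            k, m = j - i, n - (j - i)
            if m < min_width:
                continue
            if i > 0 and j == n:
                continue  # same partition as the arc (0, i]
            arc = v[i:j]
            comp = np.concatenate([v[:i], v[j:]])
            diff = arc.mean() - comp.mean()
            sp2_num = np.sum((arc - arc.mean()) ** 2) + np.sum(
                (comp - comp.mean()) ** 2
            )
            if sp2_num <= tol:
                t = np.inf if abs(diff) > np.sqrt(tol) else 0.0
            else:
                t = abs(diff) / np.sqrt(
                    sp2_num / max(n - 2, 1) * (1 / k + 1 / m)
                )
            if t > best_t:
                best_t, best_arc = t, (i, j)
    return best_arc, best_t


def _fast_config(seed=0, **kw):
    kw.setdefault("n_permutations", 300)
    return SegmentationConfig(seed=seed, **kw)


class TestMaxT:
    def test_constant_vector_scores_zero(self):
        res = max_t_statistic(np.ones(10), min_width=2)
        assert res.t == 0.0

    def test_perfect_step_isolates_the_high_arc_with_infinite_t(self):
        res = max_t_statistic([0, 0, 0, 1, 1, 1], min_width=1)
        # (0, 3] is the canonical representation of the partition that
        # isolates the three 1s (its circular complement)
        assert res.arc == (0, 3)
        assert np.isinf(res.t)

    def test_too_short_vector_signals_no_split(self):
        res = max_t_statistic([1.0, 2.0, 3.0], min_width=2)
        assert res.arc is None and res.t == 0.0

    @pytest.mark.parametrize("min_width", [1, 2, 3])
    def test_matches_exhaustive_search_on_random_vectors(self, min_width, rng):
        for _ in range(60):
            n = int(rng.integers(2 * min_width, 26))
            v = rng.normal(size=n)
            res = max_t_statistic(v, min_width)
            arc, t = oracle_max_t(v, min_width)
            assert res.arc == arc
            assert res.t == pytest.approx(t, abs=1e-10)


class TestPermutationP:
    def test_constant_vector_has_p_one(self):
        v = np.full(12, 3.0)
        res = max_t_statistic(v, 2)
        assert permutation_p(v, res.t, _fast_config()) == 1.0

    def test_noiseless_step_attains_minimum_p(self):
        # 12 + 12 markers: the chance that a shuffle recreates a perfect
        # two-block arrangement (the only way to tie the infinite
        # statistic) is ~24/C(24,12) per draw, negligible here
        v = np.concatenate([np.zeros(12), 3 * np.ones(12)])
        res = max_t_statistic(v, 2)
        cfg = _fast_config(n_permutations=199)
        p = permutation_p(v, res.t, cfg)
        assert p == pytest.approx(1 / 200)

    def test_deterministic_given_seed_and_noise_scores_high(self, rng):
        v = rng.normal(size=30)
        res = max_t_statistic(v, 2)
        cfg = _fast_config(seed=5)
        p1 = permutation_p(v, res.t, cfg)
        p2 = permutation_p(v, res.t, _fast_config(seed=5))
        assert p1 == p2
        assert p1 > 0.05  # pure noise should not look significant


def _step_vector(rng, n=100, height=1.0, sigma=0.1, breakpoint=50):
    v = rng.normal(0, sigma, size=n)
    v[breakpoint:] += height
    return v


class TestSegmentChromosome:
    def test_flat_noiseless_vector_is_one_segment(self):
        segs = segment_chromosome(np.full(40, 0.3), _fast_config())
        assert len(segs) == 1
        assert segs[0].n_markers == 40
        assert segs[0].mean == pytest.approx(0.3)

    def test_recovers_single_step_breakpoint_and_means(self, rng):
        v = _step_vector(rng)
        segs = segment_chromosome(v, _fast_config())
        assert len(segs) == 2
        assert abs(segs[0].end_index - 50) <= 1
        assert segs[0].mean == pytest.approx(0.0, abs=0.05)
        assert segs[1].mean == pytest.approx(1.0, abs=0.05)

    def test_two_flanked_events_give_alternating_sign_pattern(self, rng):
        v = rng.normal(0, 0.1, size=100)
        v[20:30] += 0.58
        v[60:70] -= 0.58
        segs = segment_chromosome(v, _fast_config())
        assert len(segs) >= 3
        signs = []
        for s in segs:
            if s.mean > 0.2:
                signs.append("+")
            elif s.mean < -0.2:
                signs.append("-")
            else:
                signs.append("0")
        assert "".join(signs) == "0+0-0"

    def test_segments_tile_the_markers_exactly_once(self, rng):
        v = rng.normal(size=75)
        v[30:50] += 2
        segs = segment_chromosome(v, _fast_config())
        covered = []
        for s in segs:
            covered.extend(range(s.start_index, s.end_index))
        assert covered == list(range(75))

    def test_marker_weighted_mean_is_conserved(self, rng):
        v = rng.normal(size=80)
        v[10:40] += 1.2
        segs = segment_chromosome(v, _fast_config())
        weighted = sum(s.mean * s.n_markers for s in segs) / 80
        assert weighted == pytest.approx(v.mean(), abs=1e-9)

    def test_detection_rate_monotone_in_step_height(self, rng):
        heights = [0.1, 0.3, 0.58, 1.0]
        rates = []
        for h in heights:
            hits = 0
            reps = 40
            for rep in range(reps):
                v = _step_vector(rng, n=60, height=h, sigma=0.1, breakpoint=30)
                segs = segment_chromosome(v, _fast_config(seed=rep))
                hits += len(segs) >= 2
            rates.append(hits / reps)
        assert rates == sorted(rates)
        assert rates[-1] == 1.0


class TestSegmentGenome:
    def _regions(self, spec):
        out = []
        for chrom, n in spec:
            for i in range(n):
                out.append(TargetRegion(chrom, i * 1000, i * 1000 + 100, 0.5))
        return out

    def test_chromosomes_never_merge(self):
        regions = self._regions([("chr1", 10), ("chr2", 10)])
        v = np.concatenate([np.zeros(10), np.ones(10)])
        segs = segment_genome(v, regions, _fast_config())
        assert [(s.chrom, s.n_markers) for s in segs] == [("chr1", 10), ("chr2", 10)]

    def test_single_marker_chromosome_is_its_own_segment(self):
        regions = self._regions([("chr1", 5), ("chr2", 1)])
        v = np.zeros(6)
        segs = segment_genome(v, regions, _fast_config())
        assert segs[-1].chrom == "chr2"
        assert segs[-1].n_markers == 1

    def test_genome_run_equals_concatenated_per_chromosome_runs(self, rng):
        regions = self._regions([("chr3", 40), ("chr7", 40)])
        v = rng.normal(0, 0.1, size=80)
        v[50:65] -= 1.0  # event on chr7
        cfg = _fast_config(seed=11)
        whole = segment_genome(v, regions, cfg)
        parts = segment_genome(v[:40], regions[:40], cfg) + [
            # re-offset the second chromosome's indices for comparison
            s for s in segment_genome(v[40:], regions[40:], cfg)
        ]
        assert len(whole) == len(parts)
        for w, p in zip(whole[:1], parts[:1]):
            assert (w.chrom, w.n_markers, w.mean) == (p.chrom, p.n_markers, p.mean)
        chr7_whole = [s for s in whole if s.chrom == "chr7"]
        chr7_part = [s for s in parts if s.chrom == "chr7"]
        assert [(s.n_markers, round(s.mean, 12)) for s in chr7_whole] == [
            (s.n_markers, round(s.mean, 12)) for s in chr7_part
        ]

    def test_determinism(self, rng):
        regions = self._regions([("chr1", 50)])
        v = rng.normal(size=50)
        cfg = _fast_config(seed=3)
        a = segment_genome(v, regions, cfg)
        b = segment_genome(v, regions, _fast_config(seed=3))
        assert a == b
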