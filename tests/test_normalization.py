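"""Library-size and GC normalisation, control selection, baseline, ratios."""

import numpy as np
import pytest

from panelcnv import (
    Baseline,
    CoverageMatrix,
    NormalizationConfig,
    TargetRegion,
    build_baseline,
    gc_correct,
    library_size_factors,
    log2_ratios,
    normalize_matrix,
    select_controls,
)
from panelcnv.normalization import ControlSelectionError


def _regions(gcs, chrom="chr1", length=100):
    return [
        TargetRegion(chrom, i * 1000, i * 1000 + length, float(g))
        for i, g in enumerate(gcs)
    ]


def _matrix(counts, gcs=None):
    counts = np.asarray(counts, dtype=float)
    gcs = gcs if gcs is not None else [0.5] * counts.shape[0]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CoverageMatrix(_regions(gcs), samples, counts)


class TestLibrarySizeFactors:
    def test_identical_samples_get_unit_factors(self):
        col = np.array([10.0, 20, 30, 40, 50])
        m = _matrix(np.column_stack([col, col, col]))
        np.testing.assert_allclose(library_size_factors(m), 1.0)

    def test_doubled_sample_has_double_factor(self):
        # 5-region toy, pseudocount -> 0 limit: geomean = a*sqrt(2), so
        # ratios are 1/sqrt(2) and sqrt(2); after mean-1 scaling the
        # factors are exactly (2/3, 4/3)
        a = np.array([10.0, 20, 30, 40, 50])
        m = _matrix(np.column_stack([a, 2 * a]))
        factors = library_size_factors(m, pseudocount=1e-9)
        np.testing.assert_allclose(factors, [2 / 3, 4 / 3], rtol=1e-6)
        assert factors[1] / factors[0] == pytest.approx(2.0, rel=1e-6)

    def test_single_sample_factor_is_one(self):
        m = _matrix(np.array([[5.0], [10.0], [15.0]]))
        np.testing.assert_allclose(library_size_factors(m), 1.0)

    def test_all_zero_sample_is_an_error(self):
        m = _matrix(np.array([[1.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="s1"):
            library_size_factors(m)

    def test_median_ratio_to_pseudo_reference_is_one_after_scaling(self, rng):
        # after dividing by the factors, the per-sample median ratio to
        # the geometric-mean reference is a single shared constant
        counts = rng.poisson(1000, size=(200, 5)).astype(float) * rng.uniform(
            0.5, 2.0, size=5
        )
        m = _matrix(counts)
        factors = library_size_factors(m)
        scaled = counts / factors
        ref = np.exp(np.mean(np.log(counts + 0.5), axis=1))
        medians = np.median(scaled / ref[:, None], axis=0)
        np.testing.assert_allclose(medians, medians[0], rtol=1e-9)

    def test_sparse_matrix_falls_back_to_total_count_factors(self, rng):
        counts = rng.poisson(0.3, size=(100, 3)).astype(float)
        counts[0] = [10, 20, 30]  # keep samples non-empty
        m = _matrix(counts)
        factors = library_size_factors(m)
        totals = counts.sum(axis=0)
        np.testing.assert_allclose(factors, totals / totals.mean())


class TestGcCorrect:
    def test_single_gc_bin_is_identity(self):
        cov = np.array([10.0, 20, 30, 40])
        regions = _regions([0.41, 0.412, 0.409, 0.411])
        np.testing.assert_allclose(gc_correct(cov, regions), cov)

    def test_bin_medians_equal_global_median_after_correction(self):
        # deterministic GC grid: 20 full bins of width 0.02, 20 regions
        # each; coverage is a tent function of GC, so bins have distinct
        # medians before correction
        gcs = np.linspace(0.3, 0.6999, 400)
        cov = 100.0 * (1.5 - np.abs(gcs - 0.5) * 2)
        regions = _regions(gcs)
        corrected = gc_correct(cov, regions)
        global_median = np.median(cov)
        for b in range(15, 35):
            members = (gcs >= b * 0.02) & (gcs < (b + 1) * 0.02)
            assert members.sum() >= 10
            assert np.median(corrected[members]) == pytest.approx(
                global_median, abs=1e-9
            )

    def test_all_zero_vector_stays_zero(self):
        regions = _regions([0.3, 0.5, 0.7])
        np.testing.assert_array_equal(
            gc_correct(np.zeros(3), regions), np.zeros(3)
        )

    def test_removes_quadratic_gc_trend(self, rng):
        n = 600
        gcs = rng.beta(12, 14, size=n)
        base = rng.lognormal(np.log(300), 0.1, size=n)
        biased = base * (1.0 + 2.5 * (gcs - 0.45) ** 2 - 0.8 * (gcs - 0.45))
        regions = _regions(gcs)
        before = np.corrcoef(np.log(biased), gcs)[0, 1]
        corrected = gc_correct(biased, regions)
        after = np.corrcoef(np.log(corrected + 0.5), gcs)[0, 1]
        assert abs(before) > 0.5
        assert abs(after) < 0.1


def _pool_with_correlated_candidate(r, n=400, seed=3):
    """Case + candidate whose log2-coverage Pearson r is exact, plus three
    clean copies of the case so the control minimum can be met."""
    rng = np.random.default_rng(seed)
    x = np.log2(rng.lognormal(np.log(2000), 0.4, size=n) + 0.5)
    z = rng.normal(size=n)
    xc = x - x.mean()
    zc = z - z.mean()
    zc -= zc @ xc / (xc @ xc) * xc  # orthogonal to x and to the constant
    y = r * xc / np.linalg.norm(xc) + np.sqrt(1 - r * r) * zc / np.linalg.norm(zc)
    y = x.mean() + y * np.linalg.norm(xc)  # same scale/centre as x
    case_counts = 2.0**x - 0.5
    cand_counts = np.maximum(2.0**y - 0.5, 0.0)
    cols = {
        "case": case_counts,
        "cand": cand_counts,
        "c1": case_counts,
        "c2": case_counts,
        "c3": case_counts,
    }
    counts = np.column_stack(list(cols.values()))
    return CoverageMatrix(_regions([0.5] * n), list(cols), counts)


class TestSelectControls:
    def test_exact_copy_has_r2_one_and_is_accepted(self):
        pool = _pool_with_correlated_candidate(r=0.999)
        accepted = dict(select_controls("case", pool))
        assert accepted["c1"] == pytest.approx(1.0)

    def test_gate_accepts_095_and_rejects_085_at_threshold_09(self):
        r95, r85 = np.sqrt(0.95), np.sqrt(0.85)
        pool95 = _pool_with_correlated_candidate(r=r95)
        pool85 = _pool_with_correlated_candidate(r=r85)
        accepted95 = dict(select_controls("case", pool95))
        accepted85 = dict(select_controls("case", pool85))
        assert accepted95["cand"] == pytest.approx(0.95, abs=0.005)
        assert "cand" in accepted95
        assert "cand" not in accepted85

    def test_outlier_region_r2_matches_brute_force_pearson(self):
        # 10-region toy: candidate = case with one region scaled x1000
        counts_case = np.array([100.0, 120, 90, 110, 95, 105, 130, 85, 115, 100])
        counts_cand = counts_case.copy()
        counts_cand[0] *= 1000
        cols = {"case": counts_case, "cand": counts_cand,
                "c1": counts_case, "c2": counts_case, "c3": counts_case}
        pool = CoverageMatrix(
            _regions([0.5] * 10), list(cols), np.column_stack(list(cols.values()))
        )
        norm = normalize_matrix(pool)
        x = np.log2(norm[:, 0] + 0.5)
        y = np.log2(norm[:, 1] + 0.5)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        r2_hand = sxy**2 / (np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        report = select_controls("case", pool, allow_best=True)
        r2_cand = dict(report).get("cand")
        if r2_cand is not None:
            assert r2_cand == pytest.approx(r2_hand, abs=1e-9)
        accepted = dict(select_controls("case", pool))
        assert ("cand" in accepted) == (r2_hand >= 0.9)

    def test_case_never_selects_itself_and_r2_is_symmetric(self, diploid_pool):
        rep_a = dict(select_controls("s0", diploid_pool, allow_best=True))
        rep_b = dict(select_controls("s1", diploid_pool, allow_best=True))
        assert "s0" not in rep_a
        report_a = select_controls(
            "s0", diploid_pool, NormalizationConfig(r2_threshold=0.01)
        )
        assert dict(report_a)["s1"] == pytest.approx(
            dict(select_controls("s1", diploid_pool,
                                 NormalizationConfig(r2_threshold=0.01)))["s0"]
        )
        del rep_b

    def test_failure_reports_best_r2_and_override_proceeds(self, rng):
        n = 200
        cols = {f"s{j}": rng.lognormal(np.log(500), 0.8, size=n) for j in range(4)}
        pool = CoverageMatrix(
            _regions([0.5] * n), list(cols), np.column_stack(list(cols.values()))
        )
        with pytest.raises(ControlSelectionError) as exc:
            select_controls("s0", pool)
        assert len(exc.value.r2_report) == 3
        best = select_controls("s0", pool, allow_best=True)
        assert len(best) == 3
        assert [s for s, _ in best] == [s for s, _ in exc.value.r2_report]


class TestBaseline:
    def test_identical_controls_have_zero_spread(self):
        col = np.array([20.0, 30, 40])
        b = build_baseline(np.column_stack([col, col, col]))
        np.testing.assert_array_equal(b.center, col)
        np.testing.assert_array_equal(b.spread, 0.0)

    def test_median_and_mad_by_definition(self):
        b = build_baseline(np.array([[8.0, 10.0, 12.0]]))
        assert b.center[0] == 10.0
        assert b.spread[0] == 2.0

    def test_low_coverage_region_is_masked(self):
        controls = np.array([[4.0, 4.0, 4.0], [50.0, 50.0, 50.0]])
        b = build_baseline(controls, NormalizationConfig(min_baseline=10))
        assert b.mask.tolist() == [True, False]


class TestLog2Ratios:
    def _baseline(self, center):
        center = np.asarray(center, dtype=float)
        return Baseline(center=center, spread=np.zeros_like(center),
                        mask=center < 10)

    def test_case_equal_to_center_gives_zero_everywhere(self):
        center = np.array([15.0, 300.0, 47.5])
        track = log2_ratios(center.copy(), self._baseline(center),
                            _regions([0.5] * 3))
        np.testing.assert_array_equal(track.values, 0.0)

    def test_gain_ratio_approaches_closed_form(self):
        center = np.full(5, 4000.0)
        track = log2_ratios(1.5 * center, self._baseline(center),
                            _regions([0.5] * 5))
        np.testing.assert_allclose(track.values, np.log2(1.5), atol=1e-3)

    def test_loss_ratio_matches_pseudocount_closed_form(self):
        c = 100.0
        center = np.full(2, c)
        track = log2_ratios(0.5 * center, self._baseline(center),
                            _regions([0.5] * 2))
        expected = np.log2((0.5 * c + 0.5) / (c + 0.5))
        np.testing.assert_allclose(track.values, expected)

    def test_masked_regions_are_excluded_and_recorded(self):
        center = np.array([5.0, 500.0])
        regions = _regions([0.5, 0.5])
        track = log2_ratios(np.array([5.0, 500.0]), self._baseline(center), regions)
        assert track.regions == [regions[1]]
        assert track.masked_regions == [regions[0]]
        assert len(track.values) == 1
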