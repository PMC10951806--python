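"""Weighted PCF: kernel, hand values, brute-force oracle, reductions."""

import numpy as np
import pytest

from spatcorr import (
    Domain,
    PointPattern,
    RadialGrid,
    WeightingParams,
    cross_pcf,
    generate_csr,
    generate_dataset_1,
    weight,
    wpcf,
    wpcf_continuous,
)
from spatcorr.geometry import annulus_area_in_domain


def wpcf_brute(pattern, categorical_mark, column, targets, grid, params):
    """Direct double-loop evaluation of the weighted cross-PCF."""
    idx_c = np.nonzero(pattern.mask(categorical_mark))[0]
    marks = pattern.continuous(column)
    finite = np.isfinite(marks)
    values = np.full((len(targets), grid.n_bins), np.nan)
    for t, target in enumerate(targets):
        w_total = sum(weight(m, target, params) for m in marks[finite])
        if w_total == 0:
            continue
        for k, r in enumerate(grid.r_values):
            total = 0.0
            for i in idx_c:
                area = annulus_area_in_domain(pattern.coords[i], r, grid.width, pattern.domain)
                for j in range(pattern.n_points):
                    if j == i or not finite[j]:
                        continue
                    d = np.hypot(*(pattern.coords[i] - pattern.coords[j]))
                    if r <= d < r + grid.width:
                        total += weight(marks[j], target, params) / area
            values[t, k] = pattern.domain.area() / (len(idx_c) * w_total) * total
    return values


class TestWeightKernel:
    def test_exact_match_is_one(self):
        assert weight(0.3, 0.3, WeightingParams(0.1)) == 1.0

    def test_half_width_is_half(self):
        assert weight(0.35, 0.3, WeightingParams(0.1)) == pytest.approx(0.5)

    def test_compact_support(self):
        p = WeightingParams(0.1)
        assert weight(0.4, 0.3, p) == 0.0
        assert weight(0.9, 0.3, p) == 0.0

    def test_nan_mark_has_zero_weight(self):
        assert weight(float("nan"), 0.3, WeightingParams(0.1)) == 0.0

    def test_bad_delta_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            WeightingParams(0.0)


class TestWPCF:
    def test_hand_value_single_weighted_pair(self, small_domain):
        """One anchor and one point at distance 8 with w = 1/2: the weight
        cancels through W_M, value = |D| / (100 pi)."""
        pts = np.array([[50.0, 50.0], [50.0, 58.0]])
        m = np.array([np.nan, 0.25])
        pp = PointPattern(pts, small_domain, ["C", "other"], {"m": m})
        params = WeightingParams(delta=0.5)
        surf = wpcf(pp, "C", "m", target_grid=[0.5], radial_grid=RadialGrid(0, 10, 10),
                    params=params)
        assert weight(0.25, 0.5, params) == pytest.approx(0.5)
        assert surf.values[0, 0] == pytest.approx(100 / np.pi)

    def test_degenerate_marks_reduce_to_cross_pcf(self, rng):
        """All continuous marks equal M0: the row at M0 is the cross-PCF
        between the anchor type and the marked points."""
        dom = Domain(0, 200, 0, 200)
        pts = rng.uniform(0, 200, (40, 2))
        labels = np.array(["C"] * 15 + ["B"] * 25, dtype=object)
        m = np.where(labels == "B", 0.7, np.nan)
        pp = PointPattern(pts, dom, labels, {"m": m})
        grid = RadialGrid(0, 100, 10)
        surf = wpcf(pp, "C", "m", target_grid=[0.7], radial_grid=grid,
                    params=WeightingParams(0.2))
        ref = cross_pcf(pp, "C", "B", grid)
        np.testing.assert_allclose(surf.values[0], ref.value, rtol=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        dom = Domain(0, 100, 0, 100)
        pts = rng.uniform(0, 100, (22, 2))
        labels = np.array(["C"] * 8 + ["x"] * 14, dtype=object)
        m = np.concatenate([np.full(8, np.nan), rng.uniform(0, 1, 14)])
        pp = PointPattern(pts, dom, labels, {"m": m})
        grid = RadialGrid(0, 60, 15)
        targets = np.array([0.2, 0.5, 0.8])
        params = WeightingParams(0.25)
        got = wpcf(pp, "C", "m", targets, grid, params).values
        want = wpcf_brute(pp, "C", "m", targets, grid, params)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_dataset1_mark_split(self):
        """Low-mark rows cluster with C1 at small r; high-mark rows exclude."""
        pat = generate_dataset_1(seed=0)
        grid = RadialGrid(0, 100, 10)
        surf = wpcf(pat, "C1", "m", target_grid=np.linspace(0, 1, 21), radial_grid=grid)
        low = surf.row(0.2)
        high = surf.row(0.8)
        small_r = (surf.r >= 10) & (surf.r <= 40)
        assert np.nanmean(low[small_r]) > 2.0
        assert np.nanmean(high[small_r]) < 1.0

    def test_hard_classification_agreement(self):
        """With binary-concentrated marks and delta below the gap, wPCF rows
        at the two levels reproduce the cross-PCFs after thresholding."""
        pat = generate_dataset_1(seed=0)
        m = pat.continuous("m").copy()
        binary = np.where(np.isfinite(m), np.where(m < 0.5, 0.0, 1.0), np.nan)
        labels = pat.categorical_marks.copy()
        labels[np.isfinite(binary) & (binary == 0)] = "C2low"
        labels[np.isfinite(binary) & (binary == 1)] = "C2high"
        hard = PointPattern(pat.coords, pat.domain, labels, {"mb": binary})
        grid = RadialGrid(0, 150, 10)
        surf = wpcf(hard, "C1", "mb", target_grid=[0.0, 1.0], radial_grid=grid,
                    params=WeightingParams(0.4))
        lo_ref = cross_pcf(hard, "C1", "C2low", grid)
        hi_ref = cross_pcf(hard, "C1", "C2high", grid)
        np.testing.assert_allclose(surf.values[0], lo_ref.value, rtol=1e-10)
        np.testing.assert_allclose(surf.values[1], hi_ref.value, rtol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        dom = Domain(0, 200, 0, 200)
        pts = rng.uniform(0, 200, (30, 2))
        labels = np.array(["C"] * 10 + ["x"] * 20, dtype=object)
        m = np.concatenate([np.full(10, np.nan), rng.uniform(0, 1, 20)])
        pp = PointPattern(pts, dom, labels, {"m": m})
        grid = RadialGrid(0, 80, 20)
        targets = np.array([0.25, 0.5, 0.75])
        a, b = 7.0, -3.0
        pp2 = PointPattern(pts, dom, labels, {"m": a * m + b})
        s1 = wpcf(pp, "C", "m", targets, grid, WeightingParams(0.2))
        s2 = wpcf(pp2, "C", "m", a * targets + b, grid, WeightingParams(0.2 * a))
        np.testing.assert_allclose(s1.values, s2.values, rtol=1e-9)

    def test_zero_weight_rows_missing_not_zero(self, small_domain):
        pts = np.array([[30.0, 30.0], [40.0, 30.0]])
        pp = PointPattern(pts, small_domain, ["C", "x"], {"m": [np.nan, 0.5]})
        surf = wpcf(pp, "C", "m", target_grid=[0.5, 10.0], radial_grid=RadialGrid(0, 30, 10),
                    params=WeightingParams(0.1))
        assert np.isfinite(surf.values[0]).all()
        assert np.isnan(surf.values[1]).all()

    def test_missing_column_rejected(self, small_domain):
        pp = PointPattern(np.array([[30.0, 30.0]]), small_domain, ["C"], {"m": [0.5]})
        with pytest.raises(KeyError, match="unknown continuous mark"):
            wpcf(pp, "C", "nope")


class TestWPCFContinuous:
    def test_degenerate_second_column_reduces_to_wpcf(self, rng):
        """Column 1 constant at M1: slices equal the anchor-free wPCF in column 2."""
        dom = Domain(0, 200, 0, 200)
        pts = rng.uniform(0, 200, (24, 2))
        m1 = np.full(24, 0.5)
        m2 = rng.uniform(0, 1, 24)
        pp = PointPattern(pts, dom, ["P"] * 24, {"m1": m1, "m2": m2})
        grid = RadialGrid(0, 80, 20)
        t2 = np.array([0.3, 0.6])
        surf = wpcf_continuous(
            pp, "m1", "m2", targets_1=np.array([0.5]), targets_2=t2,
            radial_grid=grid, params_1=WeightingParams(0.1), params_2=WeightingParams(0.2),
        )
        # with w1 = 1 for every i, Eq. reduces to the categorical wPCF over all points
        ref = wpcf(pp, "P", "m2", target_grid=t2, radial_grid=grid,
                   params=WeightingParams(0.2))
        np.testing.assert_allclose(surf.values[0], ref.values, rtol=1e-9)

    def test_csr_marks_calibrate_to_one(self, unit_km_domain):
        rng = np.random.default_rng(3)
        pat = generate_csr(unit_km_domain, {"P": 600}, seed=3)
        m1 = rng.uniform(0, 1, 600)
        m2 = rng.uniform(0, 1, 600)
        pp = PointPattern(pat.coords, unit_km_domain, pat.categorical_marks,
                          {"m1": m1, "m2": m2})
        surf = wpcf_continuous(pp, "m1", "m2", radial_grid=RadialGrid(20, 200, 20),
                               n_targets=5)
        assert np.nanmean(surf.values) == pytest.approx(1.0, abs=0.1)

    def test_single_point_surface_all_missing(self, small_domain):
        pp = PointPattern(np.array([[50.0, 50.0]]), small_domain, ["P"], {"m1": [0.5], "m2": [0.5]})
        surf = wpcf_continuous(pp, "m1", "m2", targets_1=np.array([0.5]),
                               targets_2=np.array([0.5]), radial_grid=RadialGrid(0, 30, 10),
                               params_1=WeightingParams(0.1), params_2=WeightingParams(0.1))
        assert np.isnan(surf.values).all()
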