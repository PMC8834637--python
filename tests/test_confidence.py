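"""Joint confidence regions: threshold formula, contours, overlap."""

import numpy as np
import pytest
from scipy import stats

from storekin import FitConfig, NoiseSpec
from storekin.confidence import (
    JCRRegion,
    JCRSpec,
    _extract_region,
    jcr_region,
    jcr_threshold,
    regions_overlap,
    ssq_at,
)
from storekin.fitting import fit_one_step
from storekin.kinetics import ModelSpec
from storekin.simulate import dark_design, generate


class TestThreshold:
    def test_tabulated_f_quantile_example(self):
        # p=2, m=14, phi=0.10: F(2,12;0.90)=2.8068 from standard tables,
        # threshold = 1 + (2/12)*2.8068 = 1.4678
        assert jcr_threshold(1.0, 2, 14, 0.10) == pytest.approx(1.4678, abs=1e-4)

    def test_threshold_approaches_ssq_min_as_phi_to_one(self):
        assert jcr_threshold(2.5, 3, 56, 1 - 1e-12) == pytest.approx(2.5, rel=1e-6)

    def test_threshold_strictly_decreasing_in_m(self):
        values = [jcr_threshold(1.0, 2, m, 0.10) for m in range(10, 101)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_scales_linearly_with_ssq_min(self):
        assert jcr_threshold(3.0, 3, 56, 0.1) == pytest.approx(3 * jcr_threshold(1.0, 3, 56, 0.1))

    @pytest.mark.parametrize("p,m", [(3, 3), (3, 2), (0, 10)])
    def test_degenerate_dof_rejected(self, p, m):
        with pytest.raises(ValueError):
            jcr_threshold(1.0, p, m, 0.1)


class TestRegionExtraction:
    def test_contour_matches_analytic_ellipse(self):
        # Quadratic SSQ surface: the threshold contour is exactly an ellipse
        # with semi-axes a, b; marching squares must land within one cell.
        k0, e0, a, b = 5e-2, 30.0, 1e-2, 6.0
        ssq_fn = lambda k, e: 1.0 + ((k - k0) / a) ** 2 + ((e - e0) / b) ** 2
        threshold = 2.0  # unit quadratic excess -> radii exactly (a, b)
        kg, eg, _, inside, contours, clipped = _extract_region(
            ssq_fn, (k0, e0), (k0 - 3 * a, k0 + 3 * a), (e0 - 3 * b, e0 + 3 * b), threshold, 81
        )
        assert not clipped
        assert len(contours) == 1
        cell = np.hypot((kg[1] - kg[0]) / a, (eg[1] - eg[0]) / b)
        radii = np.hypot((contours[0][:, 0] - k0) / a, (contours[0][:, 1] - e0) / b)
        assert np.all(np.abs(radii - 1.0) < cell)

    def test_estimate_inside_its_own_region(self, noisy_zero_table, fast_cfg):
        fit = fit_one_step(noisy_zero_table, ModelSpec("zero"), fast_cfg)
        region = jcr_region(fit, noisy_zero_table)
        assert region.ssq_min <= region.threshold
        assert region.contains(*region.estimate)

    def test_far_corner_is_outside(self, noisy_zero_table, fast_cfg):
        fit = fit_one_step(noisy_zero_table, ModelSpec("zero"), fast_cfg)
        region = jcr_region(fit, noisy_zero_table)
        # grid corners have SSQ far above the threshold
        assert not region.inside[0, 0]
        assert not region.inside[-1, -1]
        assert not region.contains(region.kref_grid[0], region.ea_grid[0])

    def test_profiled_ssq_never_exceeds_fixed(self, noisy_zero_table, fast_cfg):
        fit = fit_one_step(noisy_zero_table, ModelSpec("zero"), fast_cfg)
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = fit.estimates.kref * rng.uniform(0.5, 1.5)
            e = fit.estimates.Ea * rng.uniform(0.5, 1.5)
            assert ssq_at(fit, noisy_zero_table, k, e, "profiled") <= ssq_at(
                fit, noisy_zero_table, k, e, "fixed_at_optimum"
            ) + 1e-12

    def test_region_threshold_agrees_with_formula(self, noisy_zero_table, fast_cfg):
        fit = fit_one_step(noisy_zero_table, ModelSpec("zero"), fast_cfg)
        region = jcr_region(fit, noisy_zero_table, JCRSpec(phi=0.10))
        assert region.threshold == pytest.approx(
            fit.ssq * (1 + fit.p / (fit.m - fit.p) * stats.f.ppf(0.90, fit.p, fit.m - fit.p)),
            rel=1e-12,
        )

    def test_resolution_floor_enforced(self):
        with pytest.raises(ValueError, match="25"):
            JCRSpec(grid_size=10)


def _square_region(x0, y0, half, units="ug/g/day"):
    c = np.array(
        [
            [x0 - half, y0 - half],
            [x0 + half, y0 - half],
            [x0 + half, y0 + half],
            [x0 - half, y0 + half],
            [x0 - half, y0 - half],
        ]
    )
    return JCRRegion(
        threshold=1.0,
        ssq_min=0.5,
        p=3,
        m=56,
        phi=0.1,
        kref_grid=np.array([x0]),
        ea_grid=np.array([y0]),
        inside=np.ones((1, 1), bool),
        contours=[c],
        estimate=(x0, y0),
        units=units,
    )


class TestOverlap:
    def test_region_overlaps_itself(self, noisy_zero_table, fast_cfg):
        fit = fit_one_step(noisy_zero_table, ModelSpec("zero"), fast_cfg)
        region = jcr_region(fit, noisy_zero_table)
        assert regions_overlap(region, region)

    def test_disjoint_squares_do_not_overlap(self):
        assert not regions_overlap(_square_region(0.0, 0.0, 1.0), _square_region(10.0, 10.0, 1.0))
        assert regions_overlap(_square_region(0.0, 0.0, 1.0), _square_region(1.5, 0.0, 1.0))

    def test_nested_regions_overlap(self):
        assert regions_overlap(_square_region(0.0, 0.0, 5.0), _square_region(0.5, 0.5, 0.5))

    def test_unit_mismatch_is_an_error(self):
        a = _square_region(0.0, 0.0, 1.0, units="ug/g/day")
        b = _square_region(0.0, 0.0, 1.0, units="1/Mlux_h")
        with pytest.raises(ValueError, match="incommensurable"):
            regions_overlap(a, b)

    def test_identically_generated_groups_usually_overlap(self, zero_truth):
        # Two independent synthetic studies from the same truth should give
        # overlapping 90% regions in nearly all replicates. Profiled regions
        # are used: the fixed-nuisance slice slightly understates the joint
        # uncertainty (see the coverage test), and between-group inference
        # should not inherit that understatement.
        model, truth = zero_truth
        cfg = FitConfig(n_starts=4)
        spec = JCRSpec(grid_size=41, nuisance_mode="profiled")
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            ta = generate(model, truth, dark_design(), NoiseSpec(sd=0.02, seed=seed), carotenoid="a")
            tb = generate(model, truth, dark_design(), NoiseSpec(sd=0.02, seed=seed), carotenoid="b")
            ra = jcr_region(fit_one_step(ta, model, cfg), ta, spec)
            rb = jcr_region(fit_one_step(tb, model, cfg), tb, spec)
            hits += regions_overlap(ra, rb)
        assert hits >= 0.95 * n_rep
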