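"""Single-feature tuning factors, product models, fitting and pooling."""

import numpy as np
import pytest
from scipy import stats

from conftest import (
    GRATING_PARAM_NAMES,
    HUE_PARAM_NAMES,
    grating_protocol_grids,
    hue_protocol_curves,
    relative_error,
)
from gammapatch import protocols as P
from gammapatch.exceptions import ValidationError
from gammapatch.separability import TuningMatrix, separability_index
from gammapatch.tuning_models import (
    GratingShape,
    GratingStimulus,
    HuePatchStimulus,
    HueShape,
    circular_median,
    con_tuning,
    cross_validate_grating,
    cross_validate_hue,
    fit_grating_shape,
    fit_hue_shape,
    grating_grid,
    grating_product,
    hue_grid,
    hue_product,
    hue_tuning,
    load_median_shapes,
    median_pool,
    ori_tuning,
    sat_tuning,
    scale,
    sf_tuning,
    size_tuning,
    val_tuning,
)


class TestSingleFeatureFactors:
    def test_sf_peak_value(self):
        assert sf_tuning(2**1.5, mu=1.5, sigma=0.8, A=2.0, B=0.5) == pytest.approx(2.5)

    def test_sf_symmetric_one_sigma_points(self):
        lo = sf_tuning(2 ** (1.5 - 0.8), 1.5, 0.8)
        hi = sf_tuning(2 ** (1.5 + 0.8), 1.5, 0.8)
        assert lo == pytest.approx(hi) == pytest.approx(np.exp(-0.5))

    def test_sf_table_value_against_density_oracle(self, median_shapes_m1):
        g, _ = median_shapes_m1
        expected = stats.norm.pdf(np.log2(4.0), g.mu, g.sigma) / stats.norm.pdf(
            g.mu, g.mu, g.sigma
        )
        assert sf_tuning(4.0, g.mu, g.sigma) == pytest.approx(expected, rel=1e-12)

    def test_ori_peak_and_periodicity(self):
        assert ori_tuning(30.0, alpha=30.0, kappa=2.0, A=3.0, B=1.0) == pytest.approx(4.0)
        thetas = np.array([0.0, 10.0, 77.0, 130.0])
        assert np.allclose(
            ori_tuning(thetas, 30.0, 2.0), ori_tuning(thetas + 180.0, 30.0, 2.0)
        )

    def test_ori_kappa_zero_is_flat(self):
        vals = ori_tuning(np.arange(0, 180, 10.0), alpha=45.0, kappa=0.0, A=2.0, B=1.0)
        assert np.allclose(vals, 3.0)

    def test_ori_matches_vonmises_density_oracle(self, median_shapes_m1):
        g, _ = median_shapes_m1
        theta = 60.0
        num = stats.vonmises.pdf(
            2 * np.deg2rad(theta), g.kappa, loc=2 * np.deg2rad(g.alpha)
        )
        den = stats.vonmises.pdf(0.0, g.kappa, loc=0.0)
        assert ori_tuning(theta, g.alpha, g.kappa) == pytest.approx(num / den, rel=1e-12)

    @pytest.mark.parametrize("fn", [size_tuning, con_tuning])
    def test_sigmoid_midpoint_and_monotonicity(self, fn):
        assert fn(2.0, 1.5, 2.0, A=2.0, B=0.5) == pytest.approx(1.5)  # A/2 + B
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        assert np.all(np.diff(fn(x, 1.5, 2.0)) > 0)

    def test_contrast_table_value_direct_formula(self):
        g2, _ = load_median_shapes("M2")
        expected = 1.0 / (
            1.0 + 10.0 ** (-g2.k * (np.log2(100.0) - np.log2(g2.c0)))
        )
        assert con_tuning(100.0, g2.k, g2.c0) == pytest.approx(expected, rel=1e-12)

    def test_hue_periodicity_and_reduction(self):
        hues = np.array([0.0, 33.0, 181.0, 300.0])
        full = hue_tuning(hues, 10.0, 2.0, 190.0, 1.5, 0.4)
        assert np.allclose(full, hue_tuning(hues + 360.0, 10.0, 2.0, 190.0, 1.5, 0.4))
        single = hue_tuning(hues, 10.0, 2.0, 190.0, 1.5, a_c=0.0)
        assert np.argmax(hue_tuning(np.arange(0, 360.0), 10.0, 2.0, 190.0, 1.5, 0.0)) == 10

    def test_hue_table_value_against_density_oracle(self, median_shapes_m1):
        _, h = median_shapes_m1

        def vm_unit(x_deg, c_deg, kappa):
            num = stats.vonmises.pdf(np.deg2rad(x_deg), kappa, loc=np.deg2rad(c_deg))
            return num / stats.vonmises.pdf(0.0, kappa, loc=0.0)

        expected = vm_unit(0.0, h.alpha_r, h.kappa_r) + h.a_c * vm_unit(
            0.0, h.alpha_c, h.kappa_c
        )
        assert hue_tuning(
            0.0, h.alpha_r, h.kappa_r, h.alpha_c, h.kappa_c, h.a_c
        ) == pytest.approx(expected, rel=1e-12)

    def test_sat_midpoint(self):
        assert sat_tuning(0.6, l=3.0, s0=0.6, A=2.0, B=0.1) == pytest.approx(1.1)

    def test_val_line_at_full_value(self, median_shapes_m1):
        _, h = median_shapes_m1
        assert val_tuning(100.0, h.g, h.o) == pytest.approx(0.4279)

    def test_val_clamped_below_domain_with_warning(self):
        with pytest.warns(UserWarning):
            low = val_tuning(10.0, 0.3, 0.35)
        assert low == pytest.approx(val_tuning(25.0, 0.3, 0.35))

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            sf_tuning(2.0, 1.0, -0.5)
        with pytest.raises(ValidationError):
            ori_tuning(10.0, 0.0, -1.0)
        with pytest.raises(ValidationError):
            size_tuning(-1.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            con_tuning(0.0, 1.0, 20.0)


class TestProductModels:
    def test_all_factors_at_ceiling(self):
        shape = GratingShape(mu=1.0, sigma=1.0, alpha=90.0, kappa=2.0,
                             m=2.0, sigma0=1.0, k=2.0, c0=10.0)
        stim = GratingStimulus(f=2.0, theta=90.0, r=1000.0, c=100.0)
        assert grating_product(stim, shape) == pytest.approx(1.0, abs=0.01)
        assert scale(grating_product(stim, shape), 3.0, 1.0) == pytest.approx(4.0, abs=0.05)

    def test_factor_at_zero_zeroes_product(self, recovery_shapes):
        g, _ = recovery_shapes
        stim = GratingStimulus(f=2.0, theta=90.0, r=5.0, c=1e-9)
        assert grating_product(stim, g) < 1e-6

    def test_unscaled_factors_bounded_unit(self, recovery_shapes):
        g, h = recovery_shapes
        rng = np.random.default_rng(0)
        for _ in range(50):
            stim = GratingStimulus(
                f=rng.uniform(0.2, 10), theta=rng.uniform(0, 180),
                r=rng.uniform(0.1, 30), c=rng.uniform(1, 100),
            )
            assert 0.0 <= grating_product(stim, g) <= 1.0

    def test_grating_grid_is_separable(self, median_shapes_m1):
        g, _ = median_shapes_m1
        grid = grating_grid(g, ("f", P.SF_VALUES), ("theta", P.ORI_8),
                            r=P.FULL_SCREEN_SIZE_DVA, c=100.0)
        assert abs(separability_index(grid).si - 1.0) < 1e-10

    def test_hue_grid_is_separable(self, median_shapes_m1):
        _, h = median_shapes_m1
        grid = hue_grid(h, ("H", P.HUE_6), ("S", P.SAT_VALUES), V=100.0,
                        R=P.FULL_SCREEN_SIZE_DVA)
        assert abs(separability_index(grid).si - 1.0) < 1e-10

    def test_zero_radius_patch_predicts_zero(self, median_shapes_m1):
        _, h = median_shapes_m1
        assert hue_product(HuePatchStimulus(0.0, 1.0, 100.0, 0.0), h) == 0.0

    def test_zero_saturation_floors_response(self, median_shapes_m1):
        _, h = median_shapes_m1
        strong = HueShape(**{**vars(h), "l": 20.0, "s0": 0.5})
        assert hue_product(HuePatchStimulus(0.0, 0.0, 100.0, 10.0), strong) < 1e-6

    def test_full_screen_red_is_hue_argmax(self, median_shapes_m1):
        _, h = median_shapes_m1
        sweep = np.arange(0.0, 360.0, 10.0)
        vals = [hue_product(HuePatchStimulus(H, 1.0, 100.0, 25.0), h) for H in sweep]
        best = sweep[np.argmax(vals)]
        # preferred hue is the fitted red-lobe center, within the sweep step
        assert min(abs(best - h.alpha_r), 360 - abs(best - h.alpha_r)) <= 30.0


class TestFitting:
    def test_grating_recovery_noiseless(self, recovery_shapes):
        g, _ = recovery_shapes
        fit = fit_grating_shape(*grating_protocol_grids(g))
        assert fit.ok
        for name in GRATING_PARAM_NAMES:
            period = 180.0 if name == "alpha" else None
            assert relative_error(getattr(g, name), getattr(fit.shape, name),
                                  period) < 0.01

    def test_hue_recovery_noiseless(self, recovery_shapes):
        _, h = recovery_shapes
        hue36, huesize, huesat, hueval = hue_protocol_curves(h)
        fit = fit_hue_shape(hue36, huesize, huesat, hueval)
        assert fit.ok
        for name in HUE_PARAM_NAMES:
            period = 360.0 if name in ("alpha_r", "alpha_c") else None
            assert relative_error(getattr(h, name), getattr(fit.shape, name),
                                  period) < 0.01

    def test_hue_center_inside_bound_recovered(self, recovery_shapes):
        _, h = recovery_shapes
        shifted = HueShape(**{**vars(h), "alpha_r": 70.0})
        fit = fit_hue_shape(*hue_protocol_curves(shifted))
        assert fit.shape is not None
        assert relative_error(70.0, fit.shape.alpha_r, 360.0) < 0.01

    def test_hue_center_outside_bound_is_pinned(self, recovery_shapes):
        # a true red-lobe center at 100 deg exceeds the +/-80 deg search
        # bound; the fit cannot reach it and stops at the bound
        _, h = recovery_shapes
        shifted = HueShape(**{**vars(h), "alpha_r": 100.0})
        fit = fit_hue_shape(*hue_protocol_curves(shifted))
        assert fit.shape is not None
        est = (fit.shape.alpha_r + 180) % 360 - 180
        assert est <= 80.0 + 1e-6

    def test_flat_input_flagged_not_raised(self):
        ones = TuningMatrix(np.ones((5, 8)), axis_a=P.SF_VALUES, axis_b=P.ORI_8)
        sz = TuningMatrix(np.ones((6, 8)), axis_a=P.SIZE_VALUES, axis_b=P.ORI_8)
        cn = TuningMatrix(np.ones((7, 4)), axis_a=P.CON_VALUES_M1, axis_b=P.ORI_4)
        fit = fit_grating_shape(ones, sz, cn)
        assert not fit.ok and fit.shape is None
        assert "flat" in fit.sf.message

    def test_fit_invariant_to_condition_order(self, recovery_shapes):
        g, _ = recovery_shapes
        sfori, sizeori, conori = grating_protocol_grids(g)
        perm = np.array([3, 1, 4, 0, 2])
        sfori_p = TuningMatrix(
            sfori.values[perm], axis_a=sfori.axis_a[perm], axis_b=sfori.axis_b
        )
        fit1 = fit_grating_shape(sfori, sizeori, conori)
        fit2 = fit_grating_shape(sfori_p, sizeori, conori)
        assert fit1.shape.mu == pytest.approx(fit2.shape.mu, abs=1e-6)
        assert fit1.shape.sigma == pytest.approx(fit2.shape.sigma, abs=1e-6)

    def test_design_point_counts_match_protocol_sizes(self, recovery_shapes):
        g, h = recovery_shapes
        fit = fit_grating_shape(*grating_protocol_grids(g))
        assert fit.sf.n_points == 40  # 5 SF x 8 orientations
        assert fit.ori.n_points == 40
        assert fit.size.n_points == 48  # 6 sizes x 8 orientations
        assert fit.con.n_points == 28  # 7 contrasts x 4 orientations
        hfit = fit_hue_shape(*hue_protocol_curves(h))
        assert hfit.hue.n_points == 48  # 36 hues + 6 max-sat + 6 max-val
        assert hfit.size.n_points == 7
        assert hfit.sat.n_points == 30  # 6 hues x 5 saturations
        assert hfit.val.n_points == 24  # 4 values x 6 hues


class TestCrossValidation:
    def test_zero_noise_gives_perfect_correlation(self, recovery_shapes):
        g, _ = recovery_shapes
        sfori, sizeori, conori = (m.values for m in grating_protocol_grids(g))
        tr = lambda v: np.repeat(v[..., None], 4, axis=-1)
        cv = cross_validate_grating(tr(sfori), tr(sizeori), tr(conori),
                                    sizeori_f=2.0, seed=0)
        for r in cv.mean_correlations.values():
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_hue_zero_noise_perfect(self, recovery_shapes):
        _, h = recovery_shapes
        hue36, huesize, huesat, hueval = hue_protocol_curves(h)
        tr = lambda v: np.repeat(np.asarray(v)[..., None], 4, axis=-1)
        cv = cross_validate_hue(
            tr(hue36), tr(huesize), tr(huesat.values), tr(hueval.values),
            val_values=np.array([25.0, 50.0, 75.0, 100.0]), seed=0,
        )
        for r in cv.mean_correlations.values():
            assert r == pytest.approx(1.0, abs=1e-8)


class TestMedianPool:
    def test_single_shape_is_identity(self, recovery_shapes):
        g, _ = recovery_shapes
        assert median_pool([g]) == g

    def test_elementwise_median(self, recovery_shapes):
        g, _ = recovery_shapes
        shapes = [GratingShape(**{**vars(g), "mu": mu}) for mu in (4.0, 5.0, 9.0)]
        assert median_pool(shapes).mu == 5.0

    def test_circular_median_wraps(self):
        assert circular_median([350.0, 0.0, 10.0], 360.0) == pytest.approx(0.0, abs=1e-9)

    def test_circular_median_orientation_period(self):
        assert circular_median([175.0, 0.0, 5.0], 180.0) == pytest.approx(0.0, abs=1e-9)

    def test_empty_list_raises(self):
        with pytest.raises(ValidationError):
            median_pool([])


def test_median_parameter_table_loads_both_subjects():
    for subject in ("M1", "M2"):
        g, h = load_median_shapes(subject)
        assert g.sigma > 0 and h.kappa_r >= 0
        # hue centers were tabulated in radians; degrees after conversion
        assert 0 <= h.alpha_r < 360 and 80 <= h.alpha_c <= 280
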