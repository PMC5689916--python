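"""TG-43 quantities: geometry function, Lambda, g(r), F(r,theta), fits."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from seedchar.tg43 import (
    TG43Dataset,
    anisotropy_function,
    average_dose_rate_constant,
    dose_rate_constant,
    fit_anisotropy_poly,
    fit_radial_poly,
    geometry_function,
    pmma_to_water_factor,
    radial_dose_function,
    reconstruct_dose_rate,
    reconstruct_dose_rate_array,
)
from seedchar.transport import TallyGrid

# published fifth-order fit of the radial dose function for this seed
PUBLISHED_G_COEFFS = (1.185, -0.175, -1.702e-2, 6.741e-3, -6.827e-4, 2.437e-5)

# published Monte Carlo anisotropy column at r = 0.7 cm (theta deg -> F)
PUBLISHED_F_07 = {
    0: 0.303, 10: 0.450, 20: 0.674, 30: 0.809, 40: 0.891,
    50: 0.949, 60: 1.005, 70: 0.991, 80: 0.994, 90: 1.000,
}


def line_source_g_oracle(r, theta_deg, length):
    """Numeric double-check: G = (1/L) integral dl / d(l)^2 over the line."""
    th = math.radians(theta_deg)

    def integrand(l):
        d2 = r * r + l * l - 2 * r * l * math.cos(th)
        return 1.0 / d2

    val, _ = quad(integrand, -length / 2, length / 2, epsabs=1e-14, epsrel=1e-12)
    return val / length


def synthetic_tally(radii, angles, dose, rel_err=None):
    theta = np.asarray(angles, dtype=float)
    mids = 0.5 * (theta[:-1] + theta[1:])
    edges = np.concatenate([[max(0.0, theta[0] - 5.0)], mids,
                            [min(180.0, theta[-1] + 5.0)]])
    return TallyGrid(
        radii_cm=np.asarray(radii, dtype=float),
        theta_deg=theta,
        theta_edges_deg=edges,
        shell_halfwidth_cm=0.05,
        medium="water",
        histories=1,
        rng_seed=0,
        dose=np.asarray(dose, dtype=float),
        rel_err=None if rel_err is None else np.asarray(rel_err, dtype=float),
    )


class TestGeometryFunction:
    def test_point_source_limit(self):
        assert geometry_function(2.0, 90.0, 0.0) == pytest.approx(0.25, abs=1e-15)

    def test_reference_point_value(self):
        # beta = 2 atan(L/2r) at theta = 90: frozen from the numeric oracle
        g = geometry_function(1.0, 90.0, 0.325)
        assert g == pytest.approx(0.9913348, abs=1e-6)
        assert g == pytest.approx(line_source_g_oracle(1.0, 90.0, 0.325), rel=1e-9)

    def test_long_axis_limit(self):
        # 1/(r^2 - L^2/4) closed form
        assert geometry_function(1.0, 0.0, 0.325) == pytest.approx(
            1.0 / (1.0 - 0.325**2 / 4.0), rel=1e-12
        )
        assert geometry_function(1.0, 180.0, 0.325) == pytest.approx(
            1.0 / (1.0 - 0.325**2 / 4.0), rel=1e-12
        )

    def test_inside_source_extent_raises(self):
        with pytest.raises(ValueError):
            geometry_function(0.1, 0.0, 0.325)

    def test_matches_numeric_oracle_at_random_points(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            r = rng.uniform(0.3, 10.0)
            th = rng.uniform(5.0, 175.0)
            assert geometry_function(r, th, 0.325) == pytest.approx(
                line_source_g_oracle(r, th, 0.325), rel=1e-6
            )

    def test_point_source_limit_uniform_in_theta(self):
        # G * r^2 -> 1 as L/r -> 0, uniformly in angle
        r = 1.0
        for th in np.arange(1.0, 180.0, 12.5):
            assert geometry_function(r, th, 1e-4) * r * r == pytest.approx(1.0, abs=1e-8)


class TestDoseRateConstant:
    def test_unit_ratio(self):
        assert dose_rate_constant(1.0, 1.0) == 1.0

    def test_normalisation_invariance(self):
        assert dose_rate_constant(2.0 * 0.3, 2.0 * 0.31) == pytest.approx(
            dose_rate_constant(0.3, 0.31)
        )

    def test_invalid_sk(self):
        with pytest.raises(ValueError):
            dose_rate_constant(1.0, 0.0)

    def test_consensus_average(self):
        assert average_dose_rate_constant(0.975, 0.943) == pytest.approx(0.959)
        assert average_dose_rate_constant(1.0, 0.9) == pytest.approx(0.95)
        assert average_dose_rate_constant(0.7, 0.7) == 0.7


class TestRadialDoseFunction:
    def test_pure_geometry_gives_unity(self):
        radii = np.array([0.5, 1.0, 2.0, 3.0, 5.0])
        g_vals = geometry_function(radii, 90.0, 0.325)
        tally = synthetic_tally(radii, [90.0], g_vals[:, None])
        g = radial_dose_function(tally, 0.325)
        assert np.allclose(g["g"], 1.0, atol=1e-12)

    def test_normalised_at_r0(self, water_tally):
        g = radial_dose_function(water_tally, 0.325)
        assert float(g.set_index("r_cm")["g"].loc[1.0]) == 1.0

    def test_missing_reference_radius_raises(self):
        tally = synthetic_tally([2.0, 3.0], [90.0], [[1.0], [0.5]])
        with pytest.raises(ValueError):
            radial_dose_function(tally, 0.325)


class TestRadialPolyFit:
    def test_round_trip_of_published_coefficients(self):
        radii = np.concatenate([[0.5, 0.7], np.arange(1.0, 10.01, 0.5)])
        g = np.polynomial.polynomial.polyval(radii, PUBLISHED_G_COEFFS)
        coeffs, resid = fit_radial_poly(pd.DataFrame({"r_cm": radii, "g": g}))
        assert np.allclose(coeffs, PUBLISHED_G_COEFFS, atol=1e-9)
        assert np.max(np.abs(resid)) < 1e-9

    def test_published_fit_value_at_r0(self):
        value = np.polynomial.polynomial.polyval(1.0, PUBLISHED_G_COEFFS)
        assert value == pytest.approx(0.999, abs=1e-3)

    def test_constant_input(self):
        radii = np.linspace(0.5, 10, 12)
        coeffs, _ = fit_radial_poly(pd.DataFrame({"r_cm": radii, "g": 1.0}))
        assert coeffs[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(coeffs[1:], 0.0, atol=1e-12)

    def test_too_few_radii(self):
        with pytest.raises(ValueError):
            fit_radial_poly(pd.DataFrame({"r_cm": [1, 2, 3], "g": [1, 0.8, 0.6]}))


class TestAnisotropyFunction:
    def test_isotropic_point_source_gives_unity(self):
        radii = np.array([1.0, 2.0])
        angles = np.arange(10.0, 171.0, 20.0)
        gg = geometry_function(radii[:, None], angles[None, :], 0.325)
        tally = synthetic_tally(radii, angles, gg)  # D proportional to G
        f = anisotropy_function(tally, 0.325)
        assert np.allclose(f.to_numpy(), 1.0, atol=1e-12)

    def test_unity_at_90_degrees(self, water_tally):
        f = anisotropy_function(water_tally, 0.325)
        assert np.all(f[90.0].to_numpy() == 1.0)

    def test_missing_90_raises(self):
        tally = synthetic_tally([1.0], [30.0, 60.0], [[1.0, 1.0]])
        with pytest.raises(ValueError):
            anisotropy_function(tally, 0.325)


class TestAnisotropyPolyFit:
    def test_constant_column(self):
        theta = np.arange(0.0, 91.0, 10.0)
        coeffs, _ = fit_anisotropy_poly(np.ones_like(theta), theta)
        assert coeffs[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(coeffs[1:], 0.0, atol=1e-10)

    def test_quintic_round_trip(self):
        theta = np.arange(0.0, 91.0, 10.0)
        true = np.array([0.3, 0.9, -1.2, 1.4, -0.7, 0.12])
        vals = np.polynomial.polynomial.polyval(np.radians(theta), true)
        coeffs, resid = fit_anisotropy_poly(vals, theta)
        assert np.allclose(coeffs, true, atol=1e-9)
        assert np.max(np.abs(resid)) < 1e-9

    def test_published_column_intercept(self):
        """Fit of the published r = 0.7 cm column: p0 near F(0.7, 0) = 0.303."""
        col = pd.Series(PUBLISHED_F_07)
        coeffs, _ = fit_anisotropy_poly(col.to_numpy(dtype=float),
                                        col.index.to_numpy(dtype=float))
        assert coeffs[0] == pytest.approx(0.303, abs=0.02)

    def test_missing_angles_skipped(self):
        theta = np.arange(0.0, 91.0, 10.0)
        vals = np.polynomial.polynomial.polyval(np.radians(theta), [1, 0.1, 0, 0, 0, 0])
        vals[2] = np.nan
        coeffs, _ = fit_anisotropy_poly(vals, theta)
        assert coeffs[0] == pytest.approx(1.0, abs=1e-9)


class TestPmmaToWater:
    def test_identical_media_unity(self):
        t = synthetic_tally([1.0, 2.0], [90.0], [[1.0], [0.3]], [[0.01], [0.01]])
        p = pmma_to_water_factor(t, t)
        assert np.allclose(p["p_phant"], 1.0)

    def test_error_propagation(self):
        t1 = synthetic_tally([1.0], [90.0], [[1.0]], [[0.03]])
        t2 = synthetic_tally([1.0], [90.0], [[0.8]], [[0.04]])
        p = pmma_to_water_factor(t1, t2)
        assert p["rel_err"].iloc[0] == pytest.approx(math.hypot(0.03, 0.04), rel=1e-12)

    def test_grid_mismatch_rejected(self):
        t1 = synthetic_tally([1.0], [90.0], [[1.0]])
        t2 = synthetic_tally([2.0], [90.0], [[1.0]])
        with pytest.raises(ValueError):
            pmma_to_water_factor(t1, t2)

    def test_direction_set_by_attenuation_data(self, xs):
        """The water/PMMA dose ratio follows the vendored coefficients: the
        mu_en ratio puts it well above 1, and water's larger linear
        attenuation at 27-31 keV makes it fall with distance."""
        from seedchar.transport import dose_rate_table

        tw = dose_rate_table(None, "water", [1.0, 5.0], [90.0],
                             histories=200_000, rng_seed=31)
        tp = dose_rate_table(None, "pmma", [1.0, 5.0], [90.0],
                             histories=200_000, rng_seed=32)
        p = pmma_to_water_factor(tw, tp).set_index("r_cm")["p_phant"]
        assert xs.mu_en("water", 28.0) / xs.mu_en("pmma", 28.0) > 1.3
        assert xs.total("water", 28.0) * 1.0 > xs.total("pmma", 28.0) * 1.18
        assert p.loc[1.0] > 1.2
        assert p.loc[5.0] < p.loc[1.0]


class TestReconstruction:
    def test_reference_point_returns_sk_lambda(self, mc_dataset):
        rate = reconstruct_dose_rate(mc_dataset, 0.5, 1.0, 90.0)
        assert rate == pytest.approx(0.5 * mc_dataset.lambda_ * mc_dataset.g_of_r(1.0),
                                     rel=1e-9)
        assert mc_dataset.g_of_r(1.0) == pytest.approx(1.0, abs=0.01)

    def test_round_trip_reproduces_tally(self, mc_dataset, water_tally, sk_run):
        """Reconstruction at tabulated nodes matches the source tally within 1%."""
        sk, _ = sk_run
        for r in (1.0, 2.0, 5.0):
            for th in (30.0, 60.0, 90.0):
                rate = reconstruct_dose_rate(mc_dataset, sk, r, th)
                assert rate == pytest.approx(water_tally.value(r, th), rel=0.01)

    def test_transverse_monotone_decrease(self, mc_dataset):
        rates = [reconstruct_dose_rate(mc_dataset, 1.0, r, 90.0)
                 for r in np.arange(1.0, 7.01, 0.5)]
        assert np.all(np.diff(rates) < 0)

    def test_extrapolation_guard(self, mc_dataset):
        with pytest.raises(ValueError):
            reconstruct_dose_rate(mc_dataset, 1.0, 12.0, 90.0)
        # explicit opt-in allows it
        assert reconstruct_dose_rate(mc_dataset, 1.0, 12.0, 90.0,
                                     allow_extrapolation=True) > 0

    def test_vectorised_matches_scalar(self, mc_dataset):
        rng = np.random.default_rng(23)
        r = rng.uniform(0.6, 9.5, 20)
        th = rng.uniform(0.0, 355.0, 20)
        vec = reconstruct_dose_rate_array(mc_dataset, 0.7, r, th)
        for i in range(20):
            assert vec[i] == pytest.approx(
                reconstruct_dose_rate(mc_dataset, 0.7, r[i], th[i],
                                      allow_extrapolation=True), rel=1e-9
            )


class TestDatasetPersistence:
    def test_save_load_round_trip(self, mc_dataset, tmp_path):
        mc_dataset.save(tmp_path / "ds")
        back = TG43Dataset.load(tmp_path / "ds")
        assert back.lambda_ == pytest.approx(mc_dataset.lambda_, rel=1e-12)
        assert np.allclose(back.g_table["g"], mc_dataset.g_table["g"])
        assert np.allclose(back.f_table.to_numpy(), mc_dataset.f_table.to_numpy())
        assert back.g_coeffs is not None

    def test_validation_rejects_bad_datasets(self, mc_dataset):
        bad_f = mc_dataset.f_table.copy()
        bad_f[90.0] = 0.9
        with pytest.raises(ValueError):
            TG43Dataset(
                lambda_=mc_dataset.lambda_,
                active_length_cm=0.325,
                g_table=mc_dataset.g_table,
                f_table=bad_f,
            )
        with pytest.raises(ValueError):
            TG43Dataset(
                lambda_=-1.0,
                active_length_cm=0.325,
                g_table=mc_dataset.g_table,
                f_table=mc_dataset.f_table,
            )
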