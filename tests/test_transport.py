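"""Monte Carlo transport: emission, free paths, scattering, tallies."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from seedchar.materials import default_table
from seedchar.transport import (
    I125_SPECTRUM,
    PhantomSpec,
    PhotonSpectrum,
    PhotonState,
    TallyGrid,
    _run_kernel,
    air_kerma_strength,
    dose_rate_table,
    sample_emission,
    score_kerma,
    transport_photon,
)

MEAN_LINE_ENERGY = 28.383  # probability-weighted mean of the five lines


def _isotropic_state(rng, energy=27.5):
    mu = 1 - 2 * rng.random()
    phi = 2 * math.pi * rng.random()
    s = math.sqrt(1 - mu * mu)
    return PhotonState(
        np.zeros(3), np.array([s * math.cos(phi), s * math.sin(phi), mu]), energy
    )


class TestSpectrum:
    def test_default_lines(self):
        assert sum(I125_SPECTRUM.probabilities) == pytest.approx(1.0, abs=1e-12)
        assert I125_SPECTRUM.mean_energy_kev == pytest.approx(MEAN_LINE_ENERGY, abs=5e-4)

    def test_invalid_spectra_raise(self):
        with pytest.raises(ValueError):
            PhotonSpectrum((), ())
        with pytest.raises(ValueError):
            PhotonSpectrum((27.5, 31.0), (0.5, 0.4))  # does not sum to 1


class TestEmission:
    def test_single_line_energy(self, gms):
        rng = np.random.default_rng(3)
        mono = PhotonSpectrum((30.0,), (1.0,))
        for _ in range(50):
            assert sample_emission(gms, mono, rng).energy_kev == 30.0

    def test_line_frequencies_match_abundances(self, gms):
        rng = np.random.default_rng(4)
        n = 100_000
        energies = np.array(
            [sample_emission(gms, I125_SPECTRUM, rng).energy_kev for _ in range(n)]
        )
        observed = [np.sum(energies == e) for e in I125_SPECTRUM.energies_kev]
        expected = [p * n for p in I125_SPECTRUM.probabilities]
        _, p_value = stats.chisquare(observed, expected)
        assert p_value > 0.001
        # sampled mean energy within 3 sigma of the analytic mean
        se = energies.std() / math.sqrt(n)
        assert abs(energies.mean() - MEAN_LINE_ENERGY) < 3 * se

    def test_positions_on_coating_and_isotropic_directions(self, gms):
        rng = np.random.default_rng(5)
        states = [sample_emission(gms, I125_SPECTRUM, rng) for _ in range(4000)]
        pos = np.array([s.position for s in states])
        dirs = np.array([s.direction for s in states])
        rho = np.hypot(pos[:, 0], pos[:, 1])
        on_side = np.isclose(rho, 0.5 * (gms.marker_radius + gms.coat_outer_radius))
        on_end = np.abs(pos[:, 2]) > gms.marker_half_length
        assert np.all(on_side | on_end)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        assert np.abs(dirs.mean(axis=0)).max() < 4 / math.sqrt(len(dirs))


class TestPhotonTransport:
    def test_vacuum_photon_travels_straight_and_escapes(self, gms, xs):
        rng = np.random.default_rng(6)
        state = PhotonState(np.array([0.0, 0.2, 0.0]), np.array([0.0, 1.0, 0.0]), 27.5)
        segs, fate = transport_photon(state, gms, PhantomSpec("vacuum", 15.0), xs, rng)
        assert fate == "escaped"
        assert segs[-1][3] == 27.5  # unchanged energy
        end = segs[-1][1]
        assert np.linalg.norm(end) == pytest.approx(15.0, abs=1e-5)
        assert end[0] == pytest.approx(0.0, abs=1e-9)  # no deflection

    def test_narrow_beam_attenuation(self, xs):
        """Unscattered fraction through 1 cm of water equals exp(-mu t)."""
        rng = np.random.default_rng(8)
        n = 20_000
        t = 1.0
        survived = 0
        for _ in range(n):
            state = PhotonState(np.zeros(3), np.array([1.0, 0.0, 0.0]), 27.5)
            segs, _ = transport_photon(state, None, PhantomSpec("water", 15.0), xs, rng)
            first = np.linalg.norm(np.asarray(segs[0][1]) - np.asarray(segs[0][0]))
            survived += first >= t
        p_expected = math.exp(-xs.total("water", 27.5) * 1.0 * t)
        sigma = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(survived / n - p_expected) < 3 * sigma

    def test_compton_mean_cosine_matches_klein_nishina(self):
        """Sampled scatter cosines at 27.5 keV vs numeric KN integration."""
        from seedchar.transport import _sample_kn_py

        k = 27.5 / 510.99895
        c = np.linspace(-1, 1, 20001)
        p = 1.0 / (1.0 + k * (1.0 - c))
        dcs = 0.5 * p * p * (p + 1.0 / p - (1.0 - c * c))
        mean_expected = np.trapezoid(c * dcs, c) / np.trapezoid(dcs, c)

        rng = np.random.default_rng(9)
        n = 100_000
        sampled = np.array([_sample_kn_py(27.5, rng)[0] for _ in range(n)])
        se = sampled.std() / math.sqrt(n)
        assert abs(sampled.mean() - mean_expected) < 3 * se

    def test_dead_photon_rejected(self, xs):
        state = PhotonState(np.zeros(3), np.array([1.0, 0, 0]), 27.5, alive=False)
        with pytest.raises(ValueError):
            transport_photon(state, None, PhantomSpec("water"), xs)


class TestScoreKerma:
    def test_no_tracks_gives_zero(self, xs):
        tally = TallyGrid(
            np.array([1.0]), np.array([90.0]), np.array([80.0, 100.0]),
            0.05, "water", 1, 0,
        )
        tally = score_kerma([], tally, xs)
        assert np.all(tally.dose == 0)

    def test_zero_volume_cell_rejected(self):
        with pytest.raises(ValueError):
            TallyGrid(
                np.array([1.0]), np.array([90.0]), np.array([90.0, 90.0]),
                0.05, "water", 1, 0,
            ).cell_volumes()

    def test_point_source_inverse_square_and_closed_form(self, xs):
        """Vacuum point source: kerma * r^2 constant and equal to E mu_en/4 pi."""
        mono = PhotonSpectrum((30.0,), (1.0,))
        radii = np.array([2.0, 4.0, 6.0, 8.0])
        tally = _run_kernel(
            None, "vacuum", "water", radii, 0.05, np.array([90.0]),
            np.array([80.0, 100.0]), 200_000, 10, mono, 15.0, xs,
        )
        expected = 30.0 * xs.mu_en("water", 30.0) / (4 * math.pi)
        for i, r in enumerate(radii):
            val = tally.dose[i, 0] * r * r
            sigma = val * tally.rel_err[i, 0]
            assert abs(val - expected) < 3 * max(sigma, 1e-12) + 1e-3 * expected


class TestAirKermaStrength:
    def test_bare_point_source_closed_form(self, xs):
        """S_k per photon for a bare line source: E (mu_en/rho)_air / 4 pi."""
        mono = PhotonSpectrum((30.0,), (1.0,))
        sk, err = air_kerma_strength(None, mono, histories=200_000, rng_seed=12)
        expected = 30.0 * xs.mu_en("air", 30.0) / (4 * math.pi)
        assert sk == pytest.approx(expected, rel=max(3 * err, 0.01))

    def test_capsule_attenuates(self, sk_run, xs):
        sk_seed, _ = sk_run
        expected_bare = sum(
            e * p * xs.mu_en("air", e) / (4 * math.pi)
            for e, p in zip(I125_SPECTRUM.energies_kev, I125_SPECTRUM.probabilities)
        )
        assert sk_seed < expected_bare

    def test_history_floor(self, gms):
        with pytest.raises(ValueError):
            air_kerma_strength(gms, histories=100)

    def test_error_scaling_with_histories(self, gms):
        _, e1 = air_kerma_strength(gms, histories=50_000, rng_seed=21)
        _, e2 = air_kerma_strength(gms, histories=200_000, rng_seed=22)
        # quadrupling the histories should halve the standard error
        assert e1 / e2 == pytest.approx(2.0, rel=0.35)


class TestDoseRateTable:
    def test_reproducible_bit_for_bit(self, gms):
        kw = dict(radii_cm=[1.0, 2.0], angles_deg=[60.0, 90.0, 120.0],
                  histories=50_000, rng_seed=99)
        t1 = dose_rate_table(gms, "water", **kw)
        t2 = dose_rate_table(gms, "water", **kw)
        assert np.array_equal(t1.dose, t2.dose)
        assert np.array_equal(t1.rel_err, t2.rel_err)

    def test_radius_beyond_phantom_rejected(self, gms):
        with pytest.raises(ValueError):
            dose_rate_table(gms, "water", [16.0], [90.0], histories=10_000)

    def test_invalid_medium_rejected(self, gms):
        with pytest.raises(ValueError):
            dose_rate_table(gms, "gel", [1.0], [90.0], histories=10_000)

    def test_transverse_dose_monotone_beyond_1cm(self, water_tally):
        profile = water_tally.transverse()
        d = profile[profile["r_cm"] >= 1.0]["dose_per_history"].to_numpy()
        assert np.all(np.diff(d) < 0)

    def test_mirror_symmetry(self, water_tally):
        """theta vs 180 - theta doses agree within 3 sigma (symmetric seed)."""
        for r in (1.0, 3.0):
            for th in (40.0, 60.0):
                d1 = water_tally.value(r, th)
                d2 = water_tally.value(r, 180.0 - th)
                s1 = d1 * water_tally.rel_err_at(r, th)
                s2 = d2 * water_tally.rel_err_at(r, 180.0 - th)
                assert abs(d1 - d2) < 3 * math.hypot(s1, s2)

    def test_far_cell_statistics(self, water_tally):
        """Transverse far-cell precision stays within the 2.5% design target."""
        assert water_tally.rel_err_at(10.0, 90.0) < 0.025


class TestConsistency:
    def test_python_route_agrees_with_kernel(self, xs):
        """Independent per-photon route vs batch kernel: transverse dose at
        1 cm from a point source in water, within 3 sigma."""
        rng = np.random.default_rng(42)
        histories = []
        for _ in range(25_000):
            segs, _ = transport_photon(
                _isotropic_state(rng), None, PhantomSpec("water", 15.0), xs, rng
            )
            histories.append(segs)
        tally_py = TallyGrid(
            np.array([1.0]), np.array([90.0]), np.array([80.0, 100.0]),
            0.05, "water", 1, 0,
        )
        tally_py = score_kerma(histories, tally_py, xs)

        mono = PhotonSpectrum((27.5,), (1.0,))
        tally_k = _run_kernel(
            None, "water", "water", np.array([1.0]), 0.05, np.array([90.0]),
            np.array([80.0, 100.0]), 400_000, 77, mono, 15.0, xs,
        )
        d_py, d_k = tally_py.value(1.0), tally_k.value(1.0)
        sigma = math.hypot(
            d_py * tally_py.rel_err_at(1.0), d_k * tally_k.rel_err_at(1.0)
        )
        assert abs(d_py - d_k) < 3 * sigma

    def test_energy_bookkeeping(self, xs):
        """Kerma integral + escaped + cutoff energy accounts for the emitted
        energy on a closed phantom, within the estimator's channel-mix bias."""
        radii = np.arange(0.25, 14.8, 0.5)
        angles = np.arange(10.0, 180.0, 20.0)
        tally = _run_kernel(
            None, "water", "water", radii, 0.25, angles,
            np.arange(0.0, 180.01, 20.0), 100_000, 7, I125_SPECTRUM, 15.0, xs,
        )
        kerma_kev = float(np.sum(tally.dose * tally.cell_volumes())) * tally.histories
        audit = tally.energy_audit
        balance = (kerma_kev + audit["escaped_kev"] + audit["cutoff_kev"])
        assert balance / audit["emitted_kev"] == pytest.approx(1.0, abs=0.05)

    def test_audit_is_exact_for_analog_bookkeeping(self, water_tally):
        a = water_tally.energy_audit
        total = a["absorbed_kev"] + a["escaped_kev"] + a["cutoff_kev"]
        assert total == pytest.approx(a["emitted_kev"], rel=1e-9)
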