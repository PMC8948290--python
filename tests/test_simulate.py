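"""Simulator physics: Debye model, Fresnel optics, echo series, phantoms."""

from __future__ import annotations

import cmath

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzburn.simulate import (
    BiopsyDisk,
    BurnSite,
    DebyeParams,
    PhantomSpec,
    ScanConfig,
    WindowSpec,
    debye_permittivity,
    fresnel_reflection,
    load_scan,
    refractive_index,
    sample_response_spectrum,
    save_scan,
    severity_to_hydration,
    synth_reference_pulse,
    synth_scan,
    tissue_permittivity,
)


# ---------------------------------------------------------------------------
# double-Debye permittivity
# ---------------------------------------------------------------------------


class TestDebyePermittivity:
    def test_static_and_infinite_frequency_limits(self, debye):
        eps0 = debye_permittivity(debye, np.array([0.0]))[0]
        assert eps0 == pytest.approx(debye.eps_static, abs=1e-12)
        eps_hi = debye_permittivity(debye, np.array([1e9]))[0]
        assert eps_hi.real == pytest.approx(debye.eps_inf, rel=1e-6)

    def test_matches_independent_closed_form_at_half_thz(self, debye):
        # oracle: direct complex arithmetic with python scalars
        w = 2.0 * cmath.pi * 0.5e12
        expected = (
            debye.eps_inf
            + (debye.eps_static - debye.eps_mid) / (1 - 1j * w * debye.tau1)
            + (debye.eps_mid - debye.eps_inf) / (1 - 1j * w * debye.tau2)
        )
        got = debye_permittivity(debye, np.array([0.5]))[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_loss_is_non_negative(self, debye):
        eps = debye_permittivity(debye, np.linspace(0, 3, 301))
        assert np.all(eps.imag >= -1e-15)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(eps_static=2.0, eps_mid=3.6),  # eps_s < eps_2
            dict(eps_inf=-1.0),
            dict(tau1=0.1e-12, tau2=10e-12),  # tau1 < tau2
            dict(tau2=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DebyeParams(**kwargs)

    def test_negative_frequency_rejected(self, debye):
        with pytest.raises(ValueError):
            debye_permittivity(debye, np.array([-0.1]))


# ---------------------------------------------------------------------------
# refractive index and Fresnel reflection
# ---------------------------------------------------------------------------


class TestOptics:
    def test_refractive_index_simple_cases(self):
        assert refractive_index(4 + 0j) == pytest.approx(2.0)
        assert refractive_index(1 + 0j) == pytest.approx(1.0)

    def test_refractive_index_principal_branch_polar_oracle(self):
        eps = 3 + 0.5j
        r, phi = abs(eps), cmath.phase(eps)
        expected = cmath.sqrt(r) * cmath.exp(1j * phi / 2)
        assert refractive_index(eps) == pytest.approx(expected, rel=1e-12)

    def test_zero_permittivity_rejected(self):
        with pytest.raises(ValueError):
            refractive_index(0.0)

    def test_fresnel_matched_interface_and_closed_form(self):
        assert fresnel_reflection(1.5, 1.5) == pytest.approx(0.0)
        assert fresnel_reflection(1.0, 2.0) == pytest.approx(-1.0 / 3.0)

    def test_fresnel_sign_flips_between_air_and_skin_backing(self):
        r_air = fresnel_reflection(1.95, 1.0)
        r_skin = fresnel_reflection(1.95, 2.4)
        assert r_air.real > 0 > r_skin.real

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n1=st.floats(1.0, 5.0),
        n2=st.floats(1.0, 5.0),
        k2=st.floats(0.0, 3.0),
    )
    def test_fresnel_passivity(self, n1, n2, k2):
        """|r| <= 1 for any interface between passive media."""
        r = fresnel_reflection(n1 + 0j, n2 + 1j * k2)
        assert abs(r) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# window-backed sample response
# ---------------------------------------------------------------------------


class TestSampleResponse:
    def test_two_term_series_matches_hand_summation(self):
        """One-echo response on a coarse 8-point grid vs an explicitly
        summed two-term series (thin window keeps the echo in-record)."""
        window = WindowSpec(refractive_index=1.95, thickness=1e-4, n_echoes=1)
        freq = np.linspace(0.0, 1.75, 8)
        eps = np.full(8, 2.9 + 0.4j)
        got = sample_response_spectrum(window, eps, freq)

        n_w = 1.95
        n_m = np.sqrt(np.conj(eps))
        r = (n_w - n_m) / (n_w + n_m)
        r_int = (n_w - 1) / (n_w + 1)
        tprod = 4 * n_w / (1 + n_w) ** 2
        T = 2 * n_w * 1e-4 * 1e3 / 0.299792458
        expected = tprod * (r + r * r * r_int * np.exp(-2j * np.pi * freq * T))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_echo_sign_pattern_flips_with_backing_medium(self, window):
        freq = np.linspace(0, 2, 64)
        h_air = sample_response_spectrum(window, np.ones(64, complex), freq)
        h_skin = sample_response_spectrum(window, np.full(64, 5.0 + 0j), freq)
        # primary reflection (DC term) has opposite sign
        assert h_air[0].real * h_skin[0].real < 0

    def test_thick_window_reduces_to_primary_reflection(self):
        """Echoes delayed beyond the record implied by the grid vanish."""
        freq = np.fft.rfftfreq(2048, 0.05)  # 102.4 ps record
        eps = np.full(freq.size, 3.0 + 0.3j)
        thick = WindowSpec(thickness=30e-3, n_echoes=2)  # ~390 ps round trip
        h = sample_response_spectrum(thick, eps, freq)
        n_m = refractive_index(np.conj(eps))
        primary = (
            4 * 1.95 / (1 + 1.95) ** 2 * fresnel_reflection(1.95, n_m)
        )
        np.testing.assert_allclose(h, primary, rtol=1e-12)

    def test_echo_amplitudes_decay_geometrically(self, window, debye):
        freq = np.fft.rfftfreq(4096, 0.05)
        eps = tissue_permittivity(debye, freq, 0.2)
        h = sample_response_spectrum(window, eps, freq)
        pulse = synth_reference_pulse(ScanConfig())
        wf = np.fft.irfft(np.fft.rfft(pulse.amplitude) * h)
        t = pulse.t
        T = window.round_trip_ps
        peaks = []
        for m in range(3):
            gate = (t > 50 + m * T - 5) & (t < 50 + m * T + 5)
            peaks.append(np.abs(wf[gate]).max())
        assert peaks[0] > peaks[1] > peaks[2]


# ---------------------------------------------------------------------------
# incident pulse
# ---------------------------------------------------------------------------


class TestReferencePulse:
    def test_bandwidth_peak_position_and_zero_dc(self):
        cfg = ScanConfig()
        wf = synth_reference_pulse(cfg)
        assert wf.t[np.argmax(wf.amplitude)] == pytest.approx(cfg.pulse_delay_ps)
        spec = np.abs(np.fft.rfft(wf.amplitude))
        freq = cfg.freq_axis()

        def amp_at(f):
            return spec[np.argmin(np.abs(freq - f))]

        assert amp_at(0.3) >= 10 * amp_at(3.0)
        assert abs(np.trapezoid(wf.amplitude, wf.t)) < 1e-9 * np.abs(wf.amplitude).max()

    def test_deterministic(self):
        cfg = ScanConfig()
        a = synth_reference_pulse(cfg).amplitude
        b = synth_reference_pulse(cfg).amplitude
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# severity-to-hydration map
# ---------------------------------------------------------------------------


class TestSeverityMap:
    def test_healthy_baseline_and_midpoint(self):
        assert severity_to_hydration(0.0) == 0.0
        assert severity_to_hydration(50.0, max_delta=0.4) == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d1=st.floats(0, 100), d2=st.floats(0, 100))
    def test_monotone(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert severity_to_hydration(lo) <= severity_to_hydration(hi)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            severity_to_hydration(101.0)


# ---------------------------------------------------------------------------
# scan assembly
# ---------------------------------------------------------------------------


class TestSynthScan:
    def test_noise_free_uniform_phantom_gives_identical_pixels(self, noiseless_cube):
        flat = noiseless_cube.waveforms.reshape(9, -1)
        np.testing.assert_array_equal(flat, np.broadcast_to(flat[0], flat.shape))

    def test_same_seed_gives_bit_identical_cubes(self, window, debye):
        cfg = ScanConfig(nx=3, ny=3, seed=11)
        ph = PhantomSpec(burn_sites=(BurnSite((1.5, 1.5), 1.0, 30.0),))
        a = synth_scan(ph, cfg, window, debye)
        b = synth_scan(ph, cfg, window, debye)
        np.testing.assert_array_equal(a.waveforms, b.waveforms)
        np.testing.assert_array_equal(a.reference.amplitude, b.reference.amplitude)

    def test_biopsy_mask_matches_rasterized_disk_area(self, window, debye):
        cfg = ScanConfig(nx=27, ny=27, noise_rms=0.0)
        ph = PhantomSpec(biopsy_disks=(BiopsyDisk((13.5, 13.5), 4.0),))
        cube = synth_scan(ph, cfg, window, debye)
        xg, yg = np.meshgrid(
            (np.arange(27) + 0.5), (np.arange(27) + 0.5)
        )
        disk = (xg - 13.5) ** 2 + (yg - 13.5) ** 2 <= 2.0**2
        np.testing.assert_array_equal(cube.truth_biopsy_mask, disk)

    def test_ft_site_reflects_more_than_spt_site(self, window, debye):
        """In-band reflectivity ordering between severity grades,
        matching the spectral-amplitude ordering seen in vivo."""
        from thzburn.features import BandSpec, band_area
        from thzburn.preprocess import deconvolve_scan

        cfg = ScanConfig(nx=9, ny=3, seed=5)
        ph = PhantomSpec(
            burn_sites=(
                BurnSite((1.5, 1.5), 1.2, 20.0),  # SPT
                BurnSite((7.5, 1.5), 1.2, 95.0),  # FT
            )
        )
        cube = synth_scan(ph, cfg, window, debye)
        spectra = deconvolve_scan(cube)
        spt = band_area(spectra.trace(1, 1))
        ft = band_area(spectra.trace(1, 7))
        assert ft > spt

    def test_band_reflectivity_monotone_in_d_noise_off(self, window, debye):
        from thzburn.features import band_area
        from thzburn.preprocess import deconvolve_scan

        cfg = ScanConfig(nx=1, ny=1, noise_rms=0.0, scatter_jitter=0.0)
        areas = []
        for d in (0.0, 25.0, 50.0, 75.0, 100.0):
            ph = PhantomSpec(burn_sites=(BurnSite((0.5, 0.5), 1.0, d),))
            spectra = deconvolve_scan(synth_scan(ph, cfg, window, debye))
            areas.append(band_area(spectra.trace(0, 0)))
        assert np.all(np.diff(areas) > 0)

    def test_pre_pulse_noise_variance_scales_with_averages(self, window, debye):
        """Sample variance before the pulse tracks noise_rms^2/n_averages
        (Monte-Carlo over 200 seeds)."""
        ph = PhantomSpec(burn_sites=(BurnSite((0.5, 0.5), 1.0, 50.0),))

        def make(n_avg, seed, noise):
            cfg = ScanConfig(
                nx=1,
                ny=1,
                time_window_ps=51.2,
                pulse_delay_ps=30.0,
                n_averages=n_avg,
                noise_rms=noise,
                seed=seed,
                scatter_jitter=0.0,
            )
            return synth_scan(ph, cfg, window, debye)

        clean = make(1, 0, 0.0).waveforms[0, 0]
        est = {}
        for n_avg in (1, 20):
            samples = []
            for seed in range(200):
                cube = make(n_avg, seed, 0.01)
                pre = cube.t < 20.0
                samples.append(np.var((cube.waveforms[0, 0] - clean)[pre]))
            est[n_avg] = np.mean(samples)
        expected = {n: 0.01**2 / n for n in est}
        for n in est:
            assert est[n] == pytest.approx(expected[n], rel=0.15)
        assert est[1] / est[20] == pytest.approx(20.0, rel=0.2)

    def test_burn_site_outside_fov_rejected(self, window, debye):
        cfg = ScanConfig(nx=3, ny=3)
        ph = PhantomSpec(burn_sites=(BurnSite((10.0, 1.0), 1.0, 50.0),))
        with pytest.raises(ValueError):
            synth_scan(ph, cfg, window, debye)

    def test_clipped_biopsy_disk_warns(self, window, debye, caplog):
        cfg = ScanConfig(nx=5, ny=5, noise_rms=0.0)
        ph = PhantomSpec(biopsy_disks=(BiopsyDisk((4.5, 2.5), 4.0),))
        with caplog.at_level("WARNING"):
            cube = synth_scan(ph, cfg, window, debye)
        assert any("clipping" in r.message for r in caplog.records)
        assert cube.truth_biopsy_mask.any()


class TestValidation:
    def test_window_spec_invariants(self):
        with pytest.raises(ValueError):
            WindowSpec(n_echoes=0)
        with pytest.raises(ValueError):
            WindowSpec(refractive_index=0.9)

    def test_scan_config_nyquist(self):
        with pytest.raises(ValueError):
            ScanConfig(dt_ps=0.5)  # Nyquist 1 THz < 2 THz

    def test_burn_percentage_bounds(self):
        with pytest.raises(ValueError):
            BurnSite((1, 1), 1.0, 150.0)


class TestHdf5RoundTrip:
    def test_scan_container_round_trips(self, noisy_cube, tmp_path):
        path = tmp_path / "scan.h5"
        save_scan(noisy_cube, path)
        back = load_scan(path)
        np.testing.assert_array_equal(back.waveforms, noisy_cube.waveforms)
        np.testing.assert_array_equal(
            back.reference.amplitude, noisy_cube.reference.amplitude
        )
        np.testing.assert_array_equal(
            back.truth_biopsy_mask, noisy_cube.truth_biopsy_mask
        )
        assert back.config == noisy_cube.config
        assert back.window == noisy_cube.window
        assert back.debye == noisy_cube.debye
        assert list(back.truth_sites["d"]) == list(noisy_cube.truth_sites["d"])
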