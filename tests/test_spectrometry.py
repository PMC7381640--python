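"""Spectrum conditioning, response-matrix construction and unfolding."""

import numpy as np
import pytest
from scipy.stats import norm

from radsurvey.constants import compton_edge_mev
from radsurvey.dosimetry import dose_from_soil
from radsurvey.forward import DetectorModel, line_expected_channels
from radsurvey.spectrometry import (
    CalibrationError,
    ResponseMatrix,
    activities_from_flux,
    build_response_matrix,
    calibrate_energy,
    dose_from_flux,
    rebin_spectrum,
    smooth_spectrum,
    subtract_cosmic,
    two_point_calibration,
    unfold,
)
from radsurvey.synthetic import generate_sites, simulate_nai_spectrum
from radsurvey.types import ActivityTriplet, PulseHeightSpectrum

from conftest import single_region_config


def _with_true_calibration(spectrum, detector):
    return PulseHeightSpectrum(
        spectrum.counts, spectrum.live_time, detector.offset_kev, detector.gain_kev
    )


def _noise_free_site_spectrum(activity, live_time=600.0, cosmic=0.01):
    config = single_region_config((35, 57, 551), (0, 0, 0), cosmic_cps_per_channel=cosmic)
    base = generate_sites(config, 1)[0]
    site = type(base)(
        base.site_id, base.region, base.lat, base.lon, activity,
        dose_from_soil(activity),
    )
    return simulate_nai_spectrum(site, live_time, config, noise=False), config


class TestSmoothing:
    def test_mean_filter_spreads_isolated_count(self):
        spec = PulseHeightSpectrum(np.array([0.0, 9.0, 0.0]), 1.0)
        out = smooth_spectrum(spec, 1)
        assert out.counts == pytest.approx([3.0, 3.0, 3.0])

    def test_constant_spectrum_unchanged(self):
        spec = PulseHeightSpectrum(np.full(64, 5.0), 1.0)
        assert smooth_spectrum(spec, 3).counts == pytest.approx(np.full(64, 5.0))

    def test_zero_half_width_is_identity(self):
        spec = PulseHeightSpectrum(np.arange(16, dtype=float), 1.0)
        assert smooth_spectrum(spec, 0).counts == pytest.approx(spec.counts)

    def test_interior_peak_counts_conserved(self, rng):
        counts = np.zeros(512)
        x = np.arange(512)
        counts += 1000 * np.exp(-0.5 * ((x - 256) / 10.0) ** 2)
        counts = rng.poisson(counts).astype(float)
        out = smooth_spectrum(PulseHeightSpectrum(counts, 1.0), 3)
        assert out.counts.sum() == pytest.approx(counts.sum(), rel=1e-3)

    def test_smoothed_maximum_tracks_true_peak(self, rng):
        # oracle: dense quadratic fit to the noise-free peak shape
        x = np.arange(512, dtype=float)
        true_center = 301.0
        expected = 500 * np.exp(-0.5 * ((x - true_center) / 8.0) ** 2) + 20
        noisy = rng.poisson(expected).astype(float)
        smoothed = smooth_spectrum(PulseHeightSpectrum(noisy, 1.0), 3)
        found = int(np.argmax(smoothed.counts))
        window = slice(int(true_center) - 6, int(true_center) + 7)
        coeffs = np.polyfit(x[window], expected[window], 2)
        oracle_center = -coeffs[1] / (2 * coeffs[0])
        assert abs(found - oracle_center) <= 1.0 + 1e-9

    def test_rejects_oversized_window(self):
        spec = PulseHeightSpectrum(np.zeros(16), 1.0)
        with pytest.raises(ValueError):
            smooth_spectrum(spec, 9)


class TestEnergyCalibration:
    def test_two_point_solution_is_exact(self):
        offset, gain = two_point_calibration(457.5, 817.2, 1464.0, 2615.0)
        assert offset + gain * 457.5 == pytest.approx(1464.0, abs=1e-9)
        assert offset + gain * 817.2 == pytest.approx(2615.0, abs=1e-9)

    def test_recovers_generator_gain(self, rng):
        spec, config = _noise_free_site_spectrum(ActivityTriplet(35, 57, 551))
        noisy = PulseHeightSpectrum(
            rng.poisson(spec.counts).astype(float), spec.live_time
        )
        offset, gain = calibrate_energy(noisy)
        assert gain == pytest.approx(config.detector.gain_kev, rel=5e-3)

    def test_tracks_perturbed_gain(self, rng):
        det = DetectorModel(gain_kev=3.2 * 1.05)
        config = single_region_config((35, 57, 551), (0, 0, 0), detector=det)
        site = generate_sites(config, 1)[0]
        spec = simulate_nai_spectrum(site, 600, config, noise=False)
        noisy = PulseHeightSpectrum(rng.poisson(spec.counts).astype(float), 600)
        _, gain = calibrate_energy(noisy)
        assert gain / 3.2 == pytest.approx(1.05, rel=5e-3)

    def test_missing_peak_is_named(self):
        spec, _ = _noise_free_site_spectrum(ActivityTriplet(0, 0, 500.0))
        with pytest.raises(CalibrationError, match="Tl-208"):
            calibrate_energy(spec)


class TestCosmicSubtraction:
    def test_flat_floor_removed_entirely(self, detector):
        spec = PulseHeightSpectrum(
            np.full(detector.n_channels, 12.0), 60.0,
            detector.offset_kev, detector.gain_kev,
        )
        terrestrial, rate = subtract_cosmic(spec)
        assert np.allclose(terrestrial.counts, 0.0)
        assert rate == pytest.approx(12.0 / 60.0)

    def test_empty_window_leaves_spectrum_unchanged(self, detector):
        counts = np.zeros(detector.n_channels)
        counts[100:200] = 50.0
        spec = PulseHeightSpectrum(counts, 30.0, detector.offset_kev, detector.gain_kev)
        terrestrial, rate = subtract_cosmic(spec)
        assert rate == 0.0
        assert terrestrial.counts == pytest.approx(counts)

    def test_recovers_generator_floor(self, rng, detector):
        spec, config = _noise_free_site_spectrum(
            ActivityTriplet(35, 57, 551), live_time=600.0, cosmic=0.2
        )
        noisy = _with_true_calibration(
            PulseHeightSpectrum(rng.poisson(spec.counts).astype(float), 600.0),
            config.detector,
        )
        _, rate = subtract_cosmic(noisy)
        # Poisson error of the window mean: sqrt(rate / (live * n_channels))
        n_win = np.sum(
            (noisy.energies_mev() >= 3.0) & (noisy.energies_mev() < 3.2)
        )
        sigma = np.sqrt(0.2 / (600.0 * n_win))
        assert abs(rate - 0.2) < 4 * sigma

    def test_requires_calibration(self, detector):
        spec = PulseHeightSpectrum(np.zeros(detector.n_channels), 30.0)
        with pytest.raises(ValueError):
            subtract_cosmic(spec)


class TestResponseMatrix:
    def test_perfect_resolution_no_continuum_is_diagonal(self):
        det = DetectorModel(resolution_fwhm_662=0.0, continuum_fraction=0.0)
        resp = build_response_matrix(det)
        off_diag = resp.matrix - np.diag(np.diag(resp.matrix))
        assert np.abs(off_diag).max() == 0.0
        assert np.all(np.diag(resp.matrix) > 0)

    def test_column_sums_match_quadrature_oracle(self, detector, response):
        # oracle: Gaussian mass over the channel range plus continuum mass
        reps = response.binning.representative_energies()
        edges = detector.channel_edges_mev()
        for j, e in enumerate(reps):
            eff = detector.efficiency(e)
            sigma = detector.sigma_mev(e)
            peak_mass = norm.cdf(edges[-1], e, sigma) - norm.cdf(edges[0], e, sigma)
            centers = detector.channel_energies_mev()
            n_cont = np.sum(centers < compton_edge_mev(e))
            cont_mass = detector.continuum_fraction if n_cont > 0 else 0.0
            expected = eff * (peak_mass + cont_mass)
            # channels above the last bin edge are outside the binning
            in_bins = centers < response.binning.edges_mev[-1]
            rates = line_expected_channels(detector, float(e), 1.0)
            assert response.matrix[:, j].sum() == pytest.approx(
                rates[in_bins].sum(), rel=1e-12
            )
            assert rates.sum() == pytest.approx(expected, rel=1e-6)

    def test_continuum_scatters_only_downward(self):
        det = DetectorModel(resolution_fwhm_662=0.0, continuum_fraction=0.3)
        resp = build_response_matrix(det)
        # rows are pulse-height bins: downscatter fills rows below the
        # incident bin's energy, i.e. the upper triangle; upscatter (lower
        # triangle) must be absent
        assert np.abs(np.tril(resp.matrix, k=-1)).max() == 0.0
        assert np.triu(resp.matrix, k=1).sum() > 0

    def test_rejects_binning_beyond_detector_range(self):
        det = DetectorModel(n_channels=512, gain_kev=3.2)  # tops out at 1.64 MeV
        with pytest.raises(ValueError):
            build_response_matrix(det)


class TestUnfolding:
    def test_identity_response_returns_counts(self, response):
        k = response.binning.n_bins
        identity = ResponseMatrix(
            np.eye(k), response.binning,
            response.flux_per_activity, response.dose_per_flux,
        )
        c = np.abs(np.sin(np.arange(k))) * 10
        flux, resid = unfold(c, identity)
        assert flux == pytest.approx(c, abs=1e-10)
        assert resid < 1e-10

    def test_zero_spectrum_gives_zero_flux(self, response):
        flux, resid = unfold(np.zeros(response.binning.n_bins), response)
        assert np.all(flux == 0)
        assert resid == 0

    def test_forward_flux_recovered_exactly(self, response, rng):
        k = response.binning.n_bins
        truth = rng.uniform(0, 50, size=k)
        c = response.matrix @ truth
        flux, resid = unfold(c, response)
        assert flux == pytest.approx(truth, rel=1e-8, abs=1e-8)
        assert resid < 1e-8

    def test_pure_k40_line_flux_recovered(self, detector, response):
        spec, config = _noise_free_site_spectrum(
            ActivityTriplet(0, 0, 500.0), cosmic=0.0
        )
        calibrated = _with_true_calibration(spec, config.detector)
        binned = rebin_spectrum(calibrated, response.binning)
        flux, _ = unfold(binned, response)
        k_bin = response.binning.flagged["K40"]
        assert flux[k_bin] == pytest.approx(500.0 * 0.1067, rel=1e-2)


class TestActivitiesAndDose:
    def test_zero_flux_zero_everything(self, response):
        zero = np.zeros(response.binning.n_bins)
        a = activities_from_flux(zero, response)
        assert (a.a_u, a.a_th, a.a_k) == (0.0, 0.0, 0.0)
        assert dose_from_flux(zero, response) == 0.0

    def test_linearity_in_flux(self, response, rng):
        flux = rng.uniform(0, 5, size=response.binning.n_bins)
        a1 = activities_from_flux(flux, response)
        a2 = activities_from_flux(2 * flux, response)
        assert a2.as_array() == pytest.approx(2 * a1.as_array(), rel=1e-9)
        assert dose_from_flux(2 * flux, response) == pytest.approx(
            2 * dose_from_flux(flux, response), rel=1e-12
        )

    def test_direct_measurement_triplet_recovered(self, response):
        truth = ActivityTriplet(50.0, 43.0, 486.0)
        spec, config = _noise_free_site_spectrum(truth)
        calibrated = _with_true_calibration(spec, config.detector)
        terrestrial, _ = subtract_cosmic(calibrated)
        binned = rebin_spectrum(terrestrial, response.binning)
        flux, _ = unfold(binned, response)
        a = activities_from_flux(flux, response)
        assert a.as_array() == pytest.approx(truth.as_array(), rel=2e-2)

    def test_unfolded_dose_matches_soil_formula(self, response):
        truth = ActivityTriplet(35.0, 57.0, 551.0)
        spec, config = _noise_free_site_spectrum(truth)
        calibrated = _with_true_calibration(spec, config.detector)
        terrestrial, _ = subtract_cosmic(calibrated)
        binned = rebin_spectrum(terrestrial, response.binning)
        flux, _ = unfold(binned, response)
        assert dose_from_flux(flux, response) == pytest.approx(
            dose_from_soil(truth), rel=3e-2
        )

    @pytest.mark.parametrize("scale", [0.1, 1.0, 10.0, 100.0])
    def test_full_round_trip_across_three_decades(self, response, scale):
        truth = ActivityTriplet(35.0 * scale, 57.0 * scale, 551.0 * scale)
        spec, config = _noise_free_site_spectrum(truth)
        offset, gain = calibrate_energy(spec)
        calibrated = PulseHeightSpectrum(spec.counts, spec.live_time, offset, gain)
        terrestrial, _ = subtract_cosmic(calibrated)
        binned = rebin_spectrum(terrestrial, response.binning)
        flux, _ = unfold(binned, response)
        a = activities_from_flux(flux, response)
        assert a.as_array() == pytest.approx(truth.as_array(), rel=1e-2)

    def test_peak_bin_dose_below_full_dose(self, response, rng):
        flux = rng.uniform(1, 10, size=response.binning.n_bins)
        assert dose_from_flux(flux, response, bins="peaks") < dose_from_flux(
            flux, response, bins="all"
        )
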