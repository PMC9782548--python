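"""Spectra, linear-combination fitting, CRLB and SNR statistics."""

import numpy as np
import pytest

import hankelmrs as hm
from hankelmrs.quantify import (
    NOT_DETECTED,
    BasisSet,
    CollinearBasisError,
    FitResult,
    Spectrum,
    compute_crlb,
    concentration_ratios,
    estimate_snr,
    fisher_information,
    fit_linear_combination,
    to_spectrum,
    window_indices,
)


class TestToSpectrum:
    def test_constant_fid_peaks_at_reference_ppm(self, toy_acq):
        fid = hm.FIDSignal(np.ones(toy_acq.n_points, complex), toy_acq)
        spec = to_spectrum(fid)
        assert spec.ppm_axis[np.argmax(np.abs(spec.values))] == pytest.approx(
            toy_acq.ref_ppm, abs=1e-9
        )

    def test_line_position_within_one_grid_step(self):
        acq = hm.P31_ACQ
        table = hm.PeakTable((hm.ResonanceLine("Pi", 4.8, 1.0, 20.0),), "P31")
        spec = to_spectrum(hm.synthesize_fid(table, acq))
        step = acq.ppm_span / acq.n_points
        peak_ppm = spec.ppm_axis[np.argmax(np.abs(spec.values))]
        assert abs(peak_ppm - 4.8) <= step

    def test_parseval_energy_equality(self, toy_truth):
        spec = to_spectrum(toy_truth)
        e_time = np.sum(np.abs(toy_truth.samples) ** 2)
        e_freq = np.sum(np.abs(spec.values) ** 2) / toy_truth.acq.n_points
        assert abs(e_time - e_freq) <= 1e-10 * e_time

    def test_ppm_axis_decreases_left_to_right(self, toy_truth):
        spec = to_spectrum(toy_truth)
        assert np.all(np.diff(spec.ppm_axis) < 0)


class TestWindowIndices:
    def test_full_axis_window_selects_everything(self, toy_truth):
        spec = to_spectrum(toy_truth)
        idx = window_indices(spec, spec.ppm_axis.min(), spec.ppm_axis.max())
        assert idx.size == toy_truth.acq.n_points

    def test_p31_default_window_is_strictly_inside_the_axis(self):
        """16025.64 Hz / 161.98 MHz ~ 98.9 ppm span, so [-19.5, 10] is interior."""
        spec = to_spectrum(hm.synthesize_fid(hm.default_peak_table("P31"), hm.P31_ACQ))
        idx = window_indices(spec, -19.5, 10.0)
        assert 0 < idx[0] and idx[-1] < spec.ppm_axis.size - 1
        assert spec.ppm_axis.max() > 49 and spec.ppm_axis.min() < -49

    def test_degenerate_window_returns_single_bin(self, toy_truth):
        spec = to_spectrum(toy_truth)
        target = float(spec.ppm_axis[40])
        idx = window_indices(spec, target, target)
        assert idx.size == 1 and idx[0] == 40

    def test_disjoint_window_rejected(self, toy_truth):
        spec = to_spectrum(toy_truth)
        with pytest.raises(ValueError, match="overlap"):
            window_indices(spec, 500.0, 600.0)


class TestFitLinearCombination:
    def test_recovers_known_amplitudes_on_exact_model(
        self, toy_table, toy_acq, toy_basis, toy_window
    ):
        fid = hm.synthesize_fid(toy_table, toy_acq)
        fit = fit_linear_combination(fid, toy_basis, toy_window)
        truth = [toy_table.total_amplitude(m) for m in fit.metabolites]
        assert np.allclose(fit.amplitudes, truth, rtol=1e-3)

    def test_recovers_injected_zero_order_phase(
        self, toy_table, toy_acq, toy_basis, toy_window
    ):
        fid = hm.synthesize_fid(toy_table, toy_acq)
        phased = fid.with_samples(fid.samples * np.exp(1j * np.deg2rad(30.0)))
        fit = fit_linear_combination(phased, toy_basis, toy_window)
        truth = [toy_table.total_amplitude(m) for m in fit.metabolites]
        assert fit.phase0_deg == pytest.approx(30.0, abs=1.0)
        assert np.allclose(fit.amplitudes, truth, rtol=1e-2)

    def test_duplicate_basis_entries_raise_collinearity_error(self, toy_acq):
        table = hm.PeakTable(
            (
                hm.ResonanceLine("A", -3.0, 1.0, 8.0),
                hm.ResonanceLine("Twin", -3.0, 1.0, 8.0),
            ),
            "P31",
        )
        basis = BasisSet.from_peak_table(table, toy_acq)
        fid = hm.synthesize_fid(table, toy_acq)
        with pytest.raises(CollinearBasisError, match="Twin"):
            fit_linear_combination(fid, basis, (-8.0, 8.0))

    def test_amplitudes_are_nonnegative_under_noise(
        self, toy_table, toy_acq, toy_basis, toy_window
    ):
        truth = hm.synthesize_fid(toy_table, toy_acq)
        for seed in range(5):
            noisy = hm.add_noise(truth, 0.2, seed)
            fit = fit_linear_combination(noisy, toy_basis, toy_window)
            assert np.all(fit.amplitudes >= 0)


class TestCrlb:
    @pytest.fixture()
    def toy_fit(self, toy_table, toy_acq, toy_basis, toy_window):
        fid = hm.synthesize_fid(toy_table, toy_acq)
        return fid, fit_linear_combination(fid, toy_basis, toy_window)

    def test_amplitude_fisher_diagonal_matches_hand_coded_sum(self, toy_fit, toy_basis):
        """One-parameter closed form: F_aa = sum_window |B(nu)|^2 / sigma^2."""
        _, fit = toy_fit
        sigma = 0.3
        F, names = fisher_information(fit, toy_basis, sigma)
        t = toy_basis.acq.time_axis
        env = np.exp((2j * np.pi * fit.shift_hz - np.pi * fit.extra_damping_hz) * t)
        for m_idx in range(3):
            col = np.fft.fftshift(np.fft.fft(toy_basis.fids[:, m_idx] * env))[::-1]
            col = col[fit.window_idx]
            hand = float(np.sum(np.abs(col) ** 2)) / sigma**2
            assert F[m_idx, m_idx] == pytest.approx(hand, rel=1e-10)
        # the pure amplitude-only bound 100*sigma/(a*||B||) from the 1x1 inverse
        a = fit.amplitudes[0]
        col = np.fft.fftshift(np.fft.fft(toy_basis.fids[:, 0] * env))[::-1][fit.window_idx]
        assert 100.0 * np.sqrt(1.0 / F[0, 0]) / a == pytest.approx(
            100.0 * sigma / (a * np.linalg.norm(col)), rel=1e-10
        )

    def test_crlb_scales_exactly_linearly_with_sigma(self, toy_fit, toy_basis):
        fid, fit = toy_fit
        c1 = compute_crlb(fit, fid, toy_basis, sigma=0.1).copy()
        c2 = compute_crlb(fit, fid, toy_basis, sigma=0.2).copy()
        assert np.allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_absent_metabolite_gets_sentinel(self, toy_acq, toy_window):
        """Ground truth lacks C; the fit returns amplitude ~0 and %SD = 999."""
        full = hm.PeakTable(
            (
                hm.ResonanceLine("A", -3.0, 1.0, 8.0),
                hm.ResonanceLine("B", 0.0, 0.8, 8.0),
                hm.ResonanceLine("C", 4.0, 0.0001, 8.0),
            ),
            "P31",
        )
        truth_table = hm.PeakTable(full.lines[:2], "P31")
        basis = BasisSet.from_peak_table(full, toy_acq)
        fid = hm.synthesize_fid(truth_table, toy_acq)
        fit = fit_linear_combination(fid, basis, toy_window)
        crlb = compute_crlb(fit, fid, basis, sigma=0.1)
        assert crlb[list(fit.metabolites).index("C")] == NOT_DETECTED
        assert np.all(crlb[:2] < NOT_DETECTED)

    def test_monte_carlo_amplitude_sd_matches_predicted_crlb(
        self, toy_table, toy_acq, toy_basis, toy_window
    ):
        """Empirical SD over seeded replicates within [0.8, 1.25] x CRLB at high SNR."""
        truth = hm.synthesize_fid(toy_table, toy_acq)
        sigma_time = 0.02
        # the Fisher matrix lives in the windowed frequency domain, where the
        # per-channel noise SD is sigma_time * sqrt(N) under the plain FFT
        sigma = sigma_time * np.sqrt(toy_acq.n_points)
        amps, preds = [], []
        for seed in range(200):
            noisy = hm.add_noise(truth, sigma_time, 5000 + seed)
            fit = fit_linear_combination(noisy, toy_basis, toy_window)
            compute_crlb(fit, noisy, toy_basis, sigma=sigma)
            amps.append(fit.amplitudes.copy())
            preds.append(fit.crlb_pct * fit.amplitudes / 100.0)
        amps = np.array(amps)
        pred_sd = np.mean(preds, axis=0)
        emp_sd = np.std(amps, axis=0, ddof=1)
        for m_idx in range(3):
            assert 0.8 * pred_sd[m_idx] <= emp_sd[m_idx] <= 1.25 * pred_sd[m_idx]

    def test_information_nesting_preserves_fisher_submatrix(
        self, toy_table, toy_acq, toy_window
    ):
        """Adding an independent metabolite leaves the shared Fisher block intact
        and can only increase (never decrease) the shared CRLBs."""
        sub_basis = BasisSet.from_peak_table(
            hm.PeakTable(toy_table.lines[:2], "P31"), toy_acq
        )
        full_basis = BasisSet.from_peak_table(toy_table, toy_acq)
        fid = hm.synthesize_fid(hm.PeakTable(toy_table.lines[:2], "P31"), toy_acq)
        fit_sub = fit_linear_combination(fid, sub_basis, toy_window)
        fit_full = fit_linear_combination(fid, full_basis, toy_window)
        F_sub, _ = fisher_information(fit_sub, sub_basis, sigma=0.1)
        F_full, _ = fisher_information(fit_full, full_basis, sigma=0.1)
        assert np.allclose(F_full[:2, :2], F_sub[:2, :2], rtol=1e-8)


class TestEstimateSnr:
    def _manual_fit(self, spec, idx, baseline, residual):
        ppm_w = spec.ppm_axis[idx]
        return FitResult(
            metabolites=("X",),
            amplitudes=np.array([1.0]),
            phase0_deg=0.0,
            phase1_deg_per_ppm=0.0,
            shift_hz=0.0,
            extra_damping_hz=0.0,
            baseline_coeffs=np.zeros(1, complex),
            baseline=baseline,
            residual=residual,
            window_ppm=(float(ppm_w.min()), float(ppm_w.max())),
            window_idx=idx,
            ppm_window=ppm_w,
            phase_center_ppm=float(ppm_w.mean()),
            sigma_est=float(np.sqrt(np.mean(np.abs(residual) ** 2) / 2)),
        )

    def test_printed_definition_arithmetic(self, toy_acq):
        """Peak minus baseline 10, residual RMS 0.5 -> SNR = 10."""
        n = toy_acq.n_points
        values = np.full(n, 2.0 + 0j)
        values[50] = 12.0  # peak height above the flat baseline: 10
        ppm = np.linspace(8, -8, n)
        spec = Spectrum(values, ppm, toy_acq)
        idx = np.arange(n)
        baseline = np.full(n, 2.0 + 0j)
        residual = np.full(n, 0.5 + 0j)  # real-channel RMS 0.5
        fit = self._manual_fit(spec, idx, baseline, residual)
        assert estimate_snr(spec, fit, fit.window_ppm) == pytest.approx(10.0)

    def test_noiseless_input_yields_infinity_sentinel(
        self, toy_table, toy_acq, toy_basis, toy_window
    ):
        fid = hm.synthesize_fid(toy_table, toy_acq)
        fit = fit_linear_combination(fid, toy_basis, toy_window)
        fit.residual = np.zeros_like(fit.residual)
        assert estimate_snr(to_spectrum(fid), fit, toy_window) == np.inf

    def test_snr_invariant_under_positive_scaling(
        self, toy_table, toy_acq, toy_basis, toy_window
    ):
        truth = hm.synthesize_fid(toy_table, toy_acq)
        noisy = hm.add_noise(truth, 0.1, 3)
        fit = fit_linear_combination(noisy, toy_basis, toy_window)
        snr = estimate_snr(to_spectrum(noisy), fit, toy_window)
        scaled = noisy.with_samples(noisy.samples * 3.5)
        fit2 = fit_linear_combination(scaled, toy_basis, toy_window)
        snr2 = estimate_snr(to_spectrum(scaled), fit2, toy_window)
        assert snr2 == pytest.approx(snr, rel=1e-3)

    def test_halving_sigma_roughly_doubles_snr(
        self, toy_table, toy_acq, toy_basis, toy_window
    ):
        truth = hm.synthesize_fid(toy_table, toy_acq)

        def mean_snr(sigma):
            vals = []
            for k in range(20):
                noisy = hm.add_noise(truth, sigma, 300 + k)
                fit = fit_linear_combination(noisy, toy_basis, toy_window)
                vals.append(estimate_snr(to_spectrum(noisy), fit, toy_window))
            return np.mean(vals)

        assert mean_snr(0.02) / mean_snr(0.04) == pytest.approx(2.0, rel=0.15)


class TestConcentrationRatios:
    def test_reference_maps_to_one(self, toy_table, toy_acq, toy_basis, toy_window):
        fid = hm.synthesize_fid(toy_table, toy_acq)
        fit = fit_linear_combination(fid, toy_basis, toy_window)
        ratios = concentration_ratios(fit, "A")
        assert ratios["A"] == pytest.approx(1.0)
        assert ratios["B"] == pytest.approx(0.8, rel=1e-2)

    def test_ratios_are_scale_invariant(self, toy_table, toy_acq, toy_basis, toy_window):
        fid = hm.synthesize_fid(toy_table, toy_acq)
        fit = fit_linear_combination(fid, toy_basis, toy_window)
        r1 = concentration_ratios(fit, "A")
        fit.amplitudes = fit.amplitudes * 4.2
        r2 = concentration_ratios(fit, "A")
        for m in r1:
            assert r2[m] == pytest.approx(r1[m], rel=1e-12)

    def test_simple_two_metabolite_arithmetic(self):
        fit = FitResult(
            metabolites=("A", "B"),
            amplitudes=np.array([2.0, 1.0]),
            phase0_deg=0, phase1_deg_per_ppm=0, shift_hz=0, extra_damping_hz=0,
            baseline_coeffs=np.zeros(1, complex), baseline=np.zeros(1, complex),
            residual=np.zeros(1, complex), window_ppm=(0, 1),
            window_idx=np.array([0]), ppm_window=np.array([0.5]),
            phase_center_ppm=0.5, sigma_est=0.0,
        )
        assert concentration_ratios(fit, "A") == {"A": 1.0, "B": 0.5}

    def test_zero_reference_rejected(self):
        fit = FitResult(
            metabolites=("A",), amplitudes=np.array([0.0]),
            phase0_deg=0, phase1_deg_per_ppm=0, shift_hz=0, extra_damping_hz=0,
            baseline_coeffs=np.zeros(1, complex), baseline=np.zeros(1, complex),
            residual=np.zeros(1, complex), window_ppm=(0, 1),
            window_idx=np.array([0]), ppm_window=np.array([0.5]),
            phase_center_ppm=0.5, sigma_est=0.0,
        )
        with pytest.raises(ValueError, match="reference"):
            concentration_ratios(fit, "A")
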