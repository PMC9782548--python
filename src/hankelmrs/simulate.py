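"""Synthetic single-voxel MRS acquisitions.

Generates ground-truth and noisy FIDs with the statistical structure of
in vivo mouse-brain acquisitions at 9.4 T: a 13-metabolite ``31P``
whole-brain protocol (4096 complex points, 16,025.64 Hz bandwidth) and a
16-metabolite ``1H`` striatum protocol (2048 points, 4401.41 Hz), plus a
"stroke-like" variant of the latter with globally attenuated metabolites
and elevated lactate.

The signal model is the standard sum of damped complex exponentials

    s[n] = sum_k  a_k * exp(i*phi_k) * exp(2*pi*i*f_k*n*dt) * exp(-pi*(lw_k + g)*n*dt)

where ``f_k`` is the offset in Hz of line ``k`` from the carrier,
``lw_k`` its Lorentzian full width at half maximum in Hz and ``g`` an
optional global extra damping.  Chemical shifts and linewidths use
standard literature values; amplitudes are in arbitrary
concentration-proportional units and are freely configurable — the
pipeline's evaluation depends on line count and separation, not on the
exact shifts.
"""

from __future__ import annotations

import numpy as np

from .signals import AcquisitionParams, FIDSignal, Nucleus, PeakTable, ResonanceLine

__all__ = [
    "P31_ACQ",
    "H1_ACQ",
    "default_acquisition",
    "default_peak_table",
    "stroke_peak_table",
    "synthesize_fid",
    "add_noise",
    "calibrate_sigma_for_snr",
    "SnrCalibrationError",
]

#: Whole-brain 31P protocol sampling grid (9.4 T, ISIS localization).
P31_ACQ = AcquisitionParams(
    n_points=4096,
    spectral_width=16025.64,
    spectrometer_freq=161.98,
    nucleus=Nucleus.P31,
    ref_ppm=0.0,
)

#: Striatum 1H protocol sampling grid (9.4 T, PRESS localization).
H1_ACQ = AcquisitionParams(
    n_points=2048,
    spectral_width=4401.41,
    spectrometer_freq=400.13,
    nucleus=Nucleus.H1,
    ref_ppm=4.7,
)


def default_acquisition(nucleus: Nucleus | str) -> AcquisitionParams:
    """Default sampling grid for a nucleus (the protocols above)."""
    nucleus = Nucleus.coerce(nucleus)
    return P31_ACQ if nucleus is Nucleus.P31 else H1_ACQ


# 31P: all-singlet table.  PCr is the 0-ppm chemical-shift reference; the
# remaining shifts are standard brain values.  Amplitudes are
# concentration ratios to PCr (loosely guided by in vivo whole-brain
# reports); 20 Hz linewidths are typical for whole-brain voxels at 9.4 T.
_P31_LINES = [
    # metabolite, shift_ppm, amplitude, lw_hz
    ("PCr", 0.00, 1.00, 20.0),
    ("a-ATP", -7.55, 0.74, 20.0),
    ("b-ATP", -16.30, 0.24, 20.0),
    ("g-ATP", -2.50, 0.55, 20.0),
    ("Pi", 4.80, 0.26, 20.0),
    ("NADH", -8.60, 0.14, 20.0),
    ("NAD+", -8.20, 0.11, 20.0),
    ("PE", 6.80, 0.32, 20.0),
    ("PC", 6.20, 0.07, 20.0),
    ("GPE", 3.50, 0.05, 20.0),
    ("GPC", 2.90, 0.15, 20.0),
    ("MP", 7.50, 0.02, 20.0),
    ("DPG", 5.40, 0.07, 20.0),
]

# 1H: multiplets modelled as fixed sub-line groups (metabolite name shared,
# sub-line amplitudes are stoichiometric weights times the metabolite
# amplitude).  Shifts are standard brain values; amplitudes follow typical
# striatal concentrations in mM-like arbitrary units; 10 Hz linewidths.
_H1_LINES = [
    ("Ala", [(1.462, 0.5), (1.480, 0.5)], 1.82),
    ("Asp", [(2.65, 0.5), (2.80, 0.5)], 1.33),
    ("Cr", [(3.027, 0.6), (3.913, 0.4)], 3.94),
    ("PCr", [(3.029, 0.6), (3.930, 0.4)], 5.14),
    ("GABA", [(1.89, 0.34), (2.28, 0.33), (3.01, 0.33)], 2.91),
    ("Glc", [(3.23, 0.3), (3.40, 0.4), (3.70, 0.3)], 1.28),
    ("Gln", [(2.12, 0.4), (2.44, 0.4), (3.75, 0.2)], 3.57),
    ("Glu", [(2.06, 0.4), (2.34, 0.4), (3.74, 0.2)], 9.58),
    ("GPC", [(3.212, 0.6), (3.66, 0.4)], 0.71),
    ("PCh", [(3.208, 0.6), (3.58, 0.4)], 1.19),
    ("GSH", [(2.15, 0.25), (2.53, 0.25), (2.93, 0.25), (3.77, 0.25)], 2.38),
    ("Ins", [(3.27, 0.3), (3.52, 0.4), (3.61, 0.3)], 5.53),
    ("Lac", [(1.30, 0.5), (1.33, 0.5)], 2.71),
    ("NAA", [(2.008, 0.8), (2.49, 0.2)], 6.74),
    ("NAAG", [(2.042, 0.8), (2.72, 0.2)], 1.54),
    ("Tau", [(3.25, 0.5), (3.42, 0.5)], 8.08),
]

_H1_LW_HZ = 10.0


def default_peak_table(nucleus: Nucleus | str) -> PeakTable:
    """Built-in ground-truth peak table for a nucleus.

    The 31P table holds the 13 phosphorus metabolites resolved in brain
    spectra (PCr, the three ATP resonances, Pi, NADH, NAD+, PE, PC, GPE,
    GPC, MP, DPG) with PCr at 0.0 ppm as chemical-shift reference.  The
    1H table holds the 16 standard neurochemical-profile metabolites
    (Ala, Asp, Cr, PCr, GABA, Glc, Gln, Glu, GPC, PCh, GSH, Ins, Lac,
    NAA, NAAG, Tau), multiplets included, within 0.2-4.0 ppm.
    """
    nucleus = Nucleus.coerce(nucleus)
    if nucleus is Nucleus.P31:
        lines = [
            ResonanceLine(name, shift, amp, lw)
            for name, shift, amp, lw in _P31_LINES
        ]
    else:
        lines = [
            ResonanceLine(name, shift, amp * w, _H1_LW_HZ)
            for name, subs, amp in _H1_LINES
            for shift, w in subs
        ]
    return PeakTable(tuple(lines), nucleus)


def stroke_peak_table(
    attenuation: float = 0.15, lac_factor: float = 3.0
) -> PeakTable:
    """Stroke-like 1H ground truth: global signal loss plus elevated lactate.

    All metabolite amplitudes are scaled by ``attenuation`` (default 0.15,
    which reproduces a raw SNR of about 10 at the noise level calibrated
    for the normal striatum spectra) and lactate is additionally scaled by
    ``lac_factor`` (default 3), the canonical ischemia signature.
    """
    return default_peak_table(Nucleus.H1).scaled(
        global_factor=attenuation, per_metabolite={"Lac": lac_factor}
    )


def synthesize_fid(
    table: PeakTable,
    acq: AcquisitionParams,
    global_damping_hz: float = 0.0,
    line_phases_deg: np.ndarray | None = None,
) -> FIDSignal:
    """Noiseless FID of a peak table on an acquisition grid.

    Each line contributes a damped complex exponential at its offset from
    the carrier; ``global_damping_hz`` adds a uniform extra Lorentzian
    width.  ``line_phases_deg`` optionally overrides the per-line phases.
    Deterministic given its inputs; provenance is ``ground_truth``.
    """
    if global_damping_hz < 0:
        raise ValueError("global_damping_hz must be >= 0")
    phases = (
        np.asarray(line_phases_deg, dtype=float)
        if line_phases_deg is not None
        else np.array([ln.phase_deg for ln in table.lines])
    )
    if phases.shape != (len(table.lines),):
        raise ValueError("line_phases_deg must have one entry per line")

    half_bw = acq.spectral_width / 2.0
    t = acq.time_axis
    samples = np.zeros(acq.n_points, dtype=np.complex128)
    for ln, phi in zip(table.lines, phases):
        f = float(acq.hz_offset(ln.shift_ppm))
        if not (-half_bw <= f <= half_bw):
            raise ValueError(
                f"line {ln.metabolite!r} at {ln.shift_ppm} ppm maps to "
                f"{f:.1f} Hz, outside the acquired bandwidth "
                f"[{-half_bw:.1f}, {half_bw:.1f}] Hz"
            )
        samples += (
            ln.amplitude
            * np.exp(1j * np.deg2rad(phi))
            * np.exp(2j * np.pi * f * t)
            * np.exp(-np.pi * (ln.lw_hz + global_damping_hz) * t)
        )
    return FIDSignal(samples, acq, provenance="ground_truth")


def add_noise(fid: FIDSignal, sigma: float, rng_seed: int) -> FIDSignal:
    """Add iid Gaussian noise of SD ``sigma`` per real/imaginary channel.

    Reproducible for a fixed ``rng_seed``; ``sigma = 0`` returns the
    input samples unchanged (provenance becomes ``raw``).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal((fid.acq.n_points, 2)) * sigma
    samples = fid.samples + noise[:, 0] + 1j * noise[:, 1]
    return FIDSignal(samples, fid.acq, provenance="raw")


class SnrCalibrationError(RuntimeError):
    """Raised when the noise-level search fails to bracket the target SNR."""


def _mean_snr(truth, basis, window, sigma, n_probe, seed0):
    from .quantify import estimate_snr, fit_linear_combination, to_spectrum

    vals = []
    for j in range(n_probe):
        noisy = add_noise(truth, sigma, seed0 + j)
        fit = fit_linear_combination(noisy, basis, window)
        vals.append(estimate_snr(to_spectrum(noisy), fit, window))
    return float(np.mean(vals))


def calibrate_sigma_for_snr(
    table: PeakTable,
    acq: AcquisitionParams,
    target_snr: float,
    n_probe: int = 8,
    rng_seed: int = 0,
    rel_tol: float = 0.1,
    max_iter: int = 40,
) -> float:
    """Noise SD whose mean measured spectral SNR hits a target.

    The SNR statistic is the one reported by the quantification stage
    (window maximum minus baseline over twice the RMS residual), averaged
    over ``n_probe`` noisy realizations.  Because SNR is essentially
    proportional to ``1/sigma`` for a fixed signal, the search starts from
    the analytic white-noise estimate, rescales once, then bisects in log
    space until the probe mean is within ``rel_tol`` of ``target_snr``.
    """
    from .quantify import DEFAULT_WINDOWS, BasisSet

    if not target_snr > 0:
        raise ValueError("target_snr must be > 0")
    if n_probe < 1:
        raise ValueError("n_probe must be >= 1")

    window = DEFAULT_WINDOWS[acq.nucleus]
    basis = BasisSet.from_peak_table(table, acq)
    truth = synthesize_fid(table, acq)

    # White-noise estimate: spectral peak over twice the real-channel
    # residual RMS (~ sigma * sqrt(N)) equals the target.
    peak = float(np.abs(np.fft.fft(truth.samples)).max())
    sigma = peak / (2.0 * target_snr * np.sqrt(acq.n_points))
    if sigma < np.finfo(float).tiny or target_snr > 1e5:
        return max(sigma, 0.0)

    snr = _mean_snr(truth, basis, window, sigma, n_probe, rng_seed)
    if abs(snr - target_snr) <= rel_tol * target_snr:
        return sigma
    sigma *= snr / target_snr  # proportional correction

    lo = hi = None  # lo: sigma giving snr > target; hi: sigma giving snr < target
    for _ in range(max_iter):
        snr = _mean_snr(truth, basis, window, sigma, n_probe, rng_seed)
        if abs(snr - target_snr) <= rel_tol * target_snr:
            return sigma
        if snr > target_snr:
            lo = sigma
        else:
            hi = sigma
        if lo is None:
            sigma = hi / 2.0
        elif hi is None:
            sigma = lo * 2.0
        else:
            sigma = float(np.sqrt(lo * hi))
    raise SnrCalibrationError(
        f"could not reach SNR {target_snr} within {max_iter} bisection steps "
        f"(last mean SNR {snr:.3g} at sigma {sigma:.3g})"
    )
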