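"""Spectral transformation, linear-combination fitting, CRLB and SNR.

The fitter is a simplified linear-combination model in the frequency
domain over a restricted analysis window (-19.5 to 10 ppm for 31P, 0.2
to 4.0 ppm for 1H):

    S(nu) = exp(i*(phi0 + phi1*(ppm - c))) * sum_m a_m B_m(nu; df, g)
            + baseline(nu)

with non-negative metabolite amplitudes ``a_m``, global zero/first-order
phases, a global frequency shift ``df`` (Hz), a global extra Lorentzian
damping ``g`` (Hz), and a complex polynomial baseline.  Real and
imaginary channels are fitted jointly; the nonlinear nuisance parameters
are refined by bounded local optimization with the amplitudes and
baseline projected out at each step (variable projection with NNLS).

Uncertainty is reported as Cramer-Rao lower bounds in percent (%SD):
100 * sqrt((F^-1)_mm) / a_m with Fisher information
F = Re(J^H J) / sigma^2 over all model parameters on the window.
Metabolites with vanishing amplitude (or a singular Fisher matrix) get
the conventional "not detected" sentinel 999.

SNR follows the LCModel convention: the maximum of the phased real
spectrum minus the fitted baseline over the analysis window, divided by
twice the RMS of the real-channel fit residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .signals import AcquisitionParams, FIDSignal, Nucleus, PeakTable
from .simulate import synthesize_fid

__all__ = [
    "Spectrum",
    "BasisSet",
    "FitResult",
    "DEFAULT_WINDOWS",
    "NOT_DETECTED",
    "to_spectrum",
    "window_indices",
    "fit_linear_combination",
    "fisher_information",
    "compute_crlb",
    "estimate_snr",
    "concentration_ratios",
    "quantify_fid",
    "CollinearBasisError",
]

#: Analysis windows in ppm (lo, hi) per nucleus.
DEFAULT_WINDOWS = {Nucleus.P31: (-19.5, 10.0), Nucleus.H1: (0.2, 4.0)}

#: Conventional "not detected" %SD sentinel.
NOT_DETECTED = 999.0


@dataclass(frozen=True)
class Spectrum:
    """Frequency-domain view of a FID; ppm axis decreases left to right."""

    values: np.ndarray
    ppm_axis: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.complex128))
        object.__setattr__(self, "ppm_axis", np.asarray(self.ppm_axis, dtype=float))
        if self.values.shape != self.ppm_axis.shape:
            raise ValueError("values and ppm_axis must have the same length")


def _spectrum_values(samples: np.ndarray) -> np.ndarray:
    """FFT with the module convention: ppm (frequency) decreasing left to right."""
    return np.fft.fftshift(np.fft.fft(samples))[::-1]


def to_spectrum(fid: FIDSignal) -> Spectrum:
    """Discrete Fourier transform of a FID.

    A decaying exponential at offset ``f`` Hz yields (after zero-order
    phasing) an absorption-mode Lorentzian peaked at the corresponding
    ppm position.  Plain (unnormalized) FFT, so Parseval reads
    ``sum |s[n]|^2 == sum |S[k]|^2 / N``.
    """
    acq = fid.acq
    freqs = np.fft.fftshift(np.fft.fftfreq(acq.n_points, d=acq.dwell_time))[::-1]
    ppm = acq.ref_ppm + freqs / acq.spectrometer_freq
    return Spectrum(_spectrum_values(fid.samples), ppm, acq)


def window_indices(spectrum: Spectrum, lo_ppm: float, hi_ppm: float) -> np.ndarray:
    """Contiguous indices covering ``[lo_ppm, hi_ppm]`` (boundary bins included)."""
    if not lo_ppm <= hi_ppm:
        raise ValueError(f"need lo_ppm <= hi_ppm, got ({lo_ppm}, {hi_ppm})")
    ppm = spectrum.ppm_axis
    if hi_ppm < ppm.min() or lo_ppm > ppm.max():
        raise ValueError(
            f"window [{lo_ppm}, {hi_ppm}] ppm does not overlap the axis "
            f"[{ppm.min():.2f}, {ppm.max():.2f}] ppm"
        )
    mask = (ppm >= lo_ppm) & (ppm <= hi_ppm)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        # degenerate window between grid points: nearest bin
        idx = np.array([int(np.argmin(np.abs(ppm - 0.5 * (lo_ppm + hi_ppm))))])
    return idx


@dataclass(frozen=True)
class BasisSet:
    """Per-metabolite noiseless unit-amplitude FIDs on an acquisition grid.

    Multiplet sub-lines of a metabolite are merged into one basis entry
    with stoichiometric weights, so fitted amplitudes are per-metabolite
    totals.
    """

    metabolites: tuple[str, ...]
    fids: np.ndarray  # (n_points, n_metabolites) complex
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        fids = np.asarray(self.fids, dtype=np.complex128)
        object.__setattr__(self, "fids", fids)
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        if fids.shape != (self.acq.n_points, len(self.metabolites)):
            raise ValueError("fids must be (n_points, n_metabolites)")

    @classmethod
    def from_peak_table(cls, table: PeakTable, acq: AcquisitionParams) -> "BasisSet":
        names = table.metabolites
        cols = []
        for name in names:
            lines = table.lines_of(name)
            total = sum(ln.amplitude for ln in lines)
            sub = PeakTable(
                tuple(
                    type(ln)(
                        metabolite=ln.metabolite,
                        shift_ppm=ln.shift_ppm,
                        amplitude=(ln.amplitude / total) if total > 0 else 1.0 / len(lines),
                        lw_hz=ln.lw_hz,
                        phase_deg=ln.phase_deg,
                    )
                    for ln in lines
                ),
                table.nucleus,
            )
            cols.append(synthesize_fid(sub, acq).samples)
        return cls(tuple(names), np.stack(cols, axis=1), acq)

    def index_of(self, metabolite: str) -> int:
        try:
            return self.metabolites.index(metabolite)
        except ValueError:
            raise KeyError(f"metabolite {metabolite!r} not in basis") from None


@dataclass
class FitResult:
    """Linear-combination fit output on an analysis window."""

    metabolites: tuple[str, ...]
    amplitudes: np.ndarray
    phase0_deg: float
    phase1_deg_per_ppm: float
    shift_hz: float
    extra_damping_hz: float
    baseline_coeffs: np.ndarray  # complex Legendre coefficients on the window
    baseline: np.ndarray  # complex baseline evaluated on the window
    residual: np.ndarray  # complex (data - model) on the window
    window_ppm: tuple[float, float]
    window_idx: np.ndarray
    ppm_window: np.ndarray
    phase_center_ppm: float
    sigma_est: float  # RMS of the stacked real/imag residual channels
    crlb_pct: np.ndarray | None = None
    snr: float | None = None

    def phase_factor(self) -> np.ndarray:
        """exp(i*phi(nu)) on the window."""
        phi = np.deg2rad(
            self.phase0_deg
            + self.phase1_deg_per_ppm * (self.ppm_window - self.phase_center_ppm)
        )
        return np.exp(1j * phi)

    def amplitude_of(self, metabolite: str) -> float:
        return float(self.amplitudes[self.metabolites.index(metabolite)])

    def crlb_of(self, metabolite: str) -> float:
        if self.crlb_pct is None:
            raise ValueError("CRLBs not computed yet")
        return float(self.crlb_pct[self.metabolites.index(metabolite)])

    def as_frame(self):
        """Flat per-metabolite table: amplitude, crlb_pct."""
        import pandas as pd

        return pd.DataFrame(
            {
                "metabolite": list(self.metabolites),
                "amplitude": self.amplitudes,
                "crlb_pct": (
                    self.crlb_pct
                    if self.crlb_pct is not None
                    else np.full(len(self.metabolites), np.nan)
                ),
            }
        )


class CollinearBasisError(ValueError):
    """Raised when basis entries are (numerically) linearly dependent."""


def _basis_spectra(
    basis: BasisSet, shift_hz: float, damp_hz: float, idx: np.ndarray
) -> np.ndarray:
    """Windowed frequency-domain basis with global shift/damping applied."""
    t = basis.acq.time_axis
    env = np.exp((2j * np.pi * shift_hz - np.pi * damp_hz) * t)
    spec = np.fft.fftshift(np.fft.fft(basis.fids * env[:, None], axis=0), axes=0)[::-1]
    return spec[idx, :]


def _legendre_design(n: int, degree: int) -> np.ndarray:
    """Legendre polynomial columns on n evenly indexed window points."""
    x = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    return np.polynomial.legendre.legvander(x, degree)


def _solve_linear(
    Bw: np.ndarray, phase: np.ndarray, poly: np.ndarray, data: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative amplitudes + free complex baseline by NNLS on split columns."""
    M = Bw.shape[1]
    cols = phase[:, None] * Bw
    nb = poly.shape[1]
    nw = data.size
    # real stacking: rows = [Re; Im]
    A = np.empty((2 * nw, M + 4 * nb))
    A[:nw, :M] = cols.real
    A[nw:, :M] = cols.imag
    # baseline: c_re*p and c_im*i*p, each split into +/- for NNLS
    A[:nw, M : M + nb] = poly
    A[nw:, M : M + nb] = 0.0
    A[:, M + nb : M + 2 * nb] = -A[:, M : M + nb]
    A[:nw, M + 2 * nb : M + 3 * nb] = 0.0
    A[nw:, M + 2 * nb : M + 3 * nb] = poly
    A[:, M + 3 * nb :] = -A[:, M + 2 * nb : M + 3 * nb]
    b = np.concatenate([data.real, data.imag])
    coef, _ = scipy.optimize.nnls(A, b)
    amps = coef[:M]
    c_re = coef[M : M + nb] - coef[M + nb : M + 2 * nb]
    c_im = coef[M + 2 * nb : M + 3 * nb] - coef[M + 3 * nb :]
    return amps, c_re + 1j * c_im


def fit_linear_combination(
    fid: FIDSignal,
    basis: BasisSet,
    window: tuple[float, float] | None = None,
    baseline_degree: int = 2,
    collinearity_tol: float = 0.9999,
    shift_bound_hz: float = 20.0,
    damp_bound_hz: float = 50.0,
    max_nfev: int = 80,
) -> FitResult:
    """Fit the linear-combination model to a FID over an analysis window.

    Amplitudes are constrained non-negative; phase0/phase1, a global
    frequency shift and a global extra damping are refined by bounded
    least squares starting from zero.  Deterministic for fixed inputs.

    Raises
    ------
    CollinearBasisError
        If two basis entries are numerically identical on the window.
    """
    if basis.acq.n_points != fid.acq.n_points:
        raise ValueError("basis and FID are on different grids")
    if window is None:
        window = DEFAULT_WINDOWS[fid.acq.nucleus]
    spectrum = to_spectrum(fid)
    idx = window_indices(spectrum, *window)
    data = spectrum.values[idx]
    ppm_w = spectrum.ppm_axis[idx]
    center = float(ppm_w.mean())
    poly = _legendre_design(idx.size, baseline_degree)

    B0 = _basis_spectra(basis, 0.0, 0.0, idx)
    norms = np.linalg.norm(B0, axis=0)
    if np.any(norms == 0):
        dead = [m for m, nz in zip(basis.metabolites, norms) if nz == 0]
        raise CollinearBasisError(f"basis entries vanish on the window: {dead}")
    G = np.abs((B0.conj().T @ B0) / np.outer(norms, norms))
    np.fill_diagonal(G, 0.0)
    bad = np.argwhere(G > collinearity_tol)
    if bad.size:
        pairs = sorted(
            {
                tuple(sorted((basis.metabolites[i], basis.metabolites[j])))
                for i, j in bad
            }
        )
        raise CollinearBasisError(
            f"collinear basis entries on the window: {pairs}"
        )

    def residual(x: np.ndarray) -> np.ndarray:
        phi0, phi1, shift, damp = x
        Bw = _basis_spectra(basis, shift, damp, idx)
        phase = np.exp(
            1j * np.deg2rad(phi0 + phi1 * (ppm_w - center))
        )
        amps, cb = _solve_linear(Bw, phase, poly, data)
        model = phase * (Bw @ amps) + poly @ cb
        res = data - model
        return np.concatenate([res.real, res.imag])

    scale = np.linalg.norm(data) / np.sqrt(data.size) or 1.0
    sol = scipy.optimize.least_squares(
        residual,
        x0=np.zeros(4),
        bounds=(
            [-180.0, -45.0, -shift_bound_hz, 0.0],
            [180.0, 45.0, shift_bound_hz, damp_bound_hz],
        ),
        method="trf",
        diff_step=[1e-2, 1e-2, 1e-3, 1e-3],
        max_nfev=max_nfev,
        x_scale=[10.0, 1.0, 1.0, 1.0],
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
    )
    phi0, phi1, shift, damp = sol.x
    Bw = _basis_spectra(basis, shift, damp, idx)
    phase = np.exp(1j * np.deg2rad(phi0 + phi1 * (ppm_w - center)))
    amps, cb = _solve_linear(Bw, phase, poly, data)
    baseline = poly @ cb
    model = phase * (Bw @ amps) + baseline
    res = data - model
    stacked = np.concatenate([res.real, res.imag])
    return FitResult(
        metabolites=basis.metabolites,
        amplitudes=amps,
        phase0_deg=float(phi0),
        phase1_deg_per_ppm=float(phi1),
        shift_hz=float(shift),
        extra_damping_hz=float(damp),
        baseline_coeffs=cb,
        baseline=baseline,
        residual=res,
        window_ppm=(float(window[0]), float(window[1])),
        window_idx=idx,
        ppm_window=ppm_w,
        phase_center_ppm=center,
        sigma_est=float(np.sqrt(np.mean(stacked**2))),
    )


def fisher_information(
    fit: FitResult, basis: BasisSet, sigma: float
) -> tuple[np.ndarray, list[str]]:
    """Fisher information over all model parameters on the fit window.

    F_jk = Re( sum_window conj(dS/dtheta_j) * dS/dtheta_k ) / sigma^2,
    with the real/imaginary channels each carrying noise SD ``sigma``.
    Returns the matrix and the parameter names (amplitudes first).
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    idx = fit.window_idx
    ppm_w = fit.ppm_window
    t = basis.acq.time_axis
    env = np.exp(
        (2j * np.pi * fit.shift_hz - np.pi * fit.extra_damping_hz) * t
    )
    phase = fit.phase_factor()

    def win_fft(cols: np.ndarray) -> np.ndarray:
        return np.fft.fftshift(np.fft.fft(cols, axis=0), axes=0)[::-1][idx, :]

    Bw = win_fft(basis.fids * env[:, None])
    dB_shift = win_fft(basis.fids * (2j * np.pi * t * env)[:, None])
    dB_damp = win_fft(basis.fids * (-np.pi * t * env)[:, None])

    signal = Bw @ fit.amplitudes
    deg = np.pi / 180.0
    nb = fit.baseline_coeffs.size
    poly = _legendre_design(idx.size, nb - 1)

    cols = [phase[:, None] * Bw]  # d/da_m
    cols.append((1j * deg * phase * signal)[:, None])  # d/dphi0
    cols.append(
        (1j * deg * (ppm_w - fit.phase_center_ppm) * phase * signal)[:, None]
    )  # d/dphi1
    cols.append((phase * (dB_shift @ fit.amplitudes))[:, None])  # d/dshift
    cols.append((phase * (dB_damp @ fit.amplitudes))[:, None])  # d/ddamp
    cols.append(poly.astype(complex))  # d/dc_re
    cols.append(1j * poly)  # d/dc_im
    J = np.concatenate(cols, axis=1)
    F = np.real(J.conj().T @ J) / sigma**2
    names = (
        [f"amp:{m}" for m in fit.metabolites]
        + ["phase0", "phase1", "shift", "damping"]
        + [f"base_re:{k}" for k in range(nb)]
        + [f"base_im:{k}" for k in range(nb)]
    )
    return F, names


def compute_crlb(
    fit: FitResult,
    fid: FIDSignal,
    basis: BasisSet,
    sigma: float,
    amplitude_rtol: float = 1e-8,
) -> np.ndarray:
    """Per-metabolite CRLB %SD; sentinel 999 for undetected metabolites.

    ``sigma`` is the noise SD per real channel of the windowed spectrum
    (by default estimated from the fit residual RMS, matching the SNR
    denominator's spirit).  Values are 100*sqrt((F^-1)_mm)/a_m, capped at
    the sentinel; amplitudes at machine scale (relative to the largest)
    and metabolites hit by a singular Fisher matrix get 999.
    """
    F, _ = fisher_information(fit, basis, sigma)
    M = len(fit.metabolites)
    amax = float(fit.amplitudes.max()) if fit.amplitudes.size else 0.0
    detected = fit.amplitudes > amplitude_rtol * max(amax, np.finfo(float).tiny)
    try:
        cov = np.linalg.inv(F)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular Fisher matrix; using pseudo-inverse, affected "
            "metabolites reported as not detected (999)",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = np.linalg.pinv(F)
    var = np.diag(cov)[:M]
    crlb = np.full(M, NOT_DETECTED)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = detected & np.isfinite(var) & (var > 0)
        crlb[ok] = 100.0 * np.sqrt(var[ok]) / fit.amplitudes[ok]
    crlb = np.minimum(crlb, NOT_DETECTED)
    fit.crlb_pct = crlb
    return crlb


def estimate_snr(
    spectrum: Spectrum, fit: FitResult, window: tuple[float, float] | None = None
) -> float:
    """LCModel-convention SNR on the analysis window.

    Maximum of the phased real spectrum minus the fitted baseline over
    the window, divided by twice the RMS of the phased real-channel fit
    residual.  A zero residual (noiseless, fit-consistent input) yields
    the +infinity sentinel.
    """
    if window is None:
        window = fit.window_ppm
    idx = window_indices(spectrum, *window)
    if idx.size != fit.window_idx.size or not np.array_equal(idx, fit.window_idx):
        raise ValueError("SNR window does not match the fit window")
    phase = fit.phase_factor()
    data = spectrum.values[idx]
    height = float(np.max(np.real(np.conj(phase) * (data - fit.baseline))))
    rms = float(np.sqrt(np.mean(np.real(np.conj(phase) * fit.residual) ** 2)))
    if rms <= 1e-9 * abs(height):
        # residual at machine scale: noiseless, fit-consistent input
        fit.snr = np.inf
        return np.inf
    snr = height / (2.0 * rms)
    fit.snr = snr
    return snr


def concentration_ratios(fit: FitResult, reference: str) -> dict[str, float]:
    """Amplitudes normalized to a reference metabolite (ratio map, ref -> 1.0)."""
    a_ref = fit.amplitude_of(reference)
    if a_ref <= 0:
        raise ValueError(f"reference {reference!r} has non-positive amplitude")
    return {m: float(a / a_ref) for m, a in zip(fit.metabolites, fit.amplitudes)}


def quantify_fid(
    fid: FIDSignal,
    basis: BasisSet,
    window: tuple[float, float] | None = None,
    baseline_degree: int = 2,
    sigma: float | None = None,
) -> FitResult:
    """Fit + CRLB + SNR in one call.

    ``sigma`` defaults to the RMS of the fit residual; pass an explicit
    value (e.g. from a signal-free region) to override.
    """
    fit = fit_linear_combination(fid, basis, window, baseline_degree)
    sig = fit.sigma_est if sigma is None else sigma
    if sig > 0:
        compute_crlb(fit, fid, basis, sig)
    else:
        fit.crlb_pct = np.full(len(fit.metabolites), NOT_DETECTED)
    estimate_snr(to_spectrum(fid), fit, fit.window_ppm)
    return fit
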