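# Methods

## Signal model and simulator

Every synthetic FID is a finite sum of damped complex exponentials
sampled at dwell time Δt = 1/SW:

    s[n] = Σ_k a_k · e^{iφ_k} · e^{2πi f_k nΔt} · e^{−π (λ_k + g) nΔt}

with f_k = (δ_k − δ_ref)·f₀ the offset in Hz of chemical shift δ_k
(ppm) from the carrier, λ_k the Lorentzian FWHM in Hz, and g an
optional global extra damping. Noise is iid circular Gaussian, SD σ per
real/imaginary channel per sample.

Two built-in protocols fix the study conditions:

- **³¹P whole brain** — 4096 complex points, 16,025.64 Hz bandwidth,
  161.98 MHz, carrier at 0 ppm (PCr-referenced). 13 singlet resonances
  (PCr, α/β/γ-ATP, Pi, NADH, NAD⁺, PE, PC, GPE, GPC, MP, DPG) with
  standard literature shifts, 20 Hz linewidths (typical of a whole-brain
  voxel at 9.4 T), and amplitudes expressed as concentration ratios to
  PCr. Noise is calibrated so the measured raw spectral SNR is ≈ 5.
- **¹H striatum** — 2048 points, 4401.41 Hz, 400.13 MHz, carrier at
  4.7 ppm (water). 16 metabolites (Ala, Asp, Cr, PCr, GABA, Glc, Gln,
  Glu, GPC, PCh, GSH, Ins, Lac, NAA, NAAG, Tau); multiplets are modelled
  as fixed sub-line groups (39 Lorentzian sub-lines in total) with
  stoichiometric weights, 10 Hz linewidths, mM-scale amplitude ratios
  typical of striatum. Raw SNR operating point ≈ 71.
- **¹H stroke-like** — the striatum table with all amplitudes × 0.15 and
  Lac × 3, evaluated at the noise level calibrated for the normal ¹H
  protocol; this lands the raw SNR at ≈ 10 and makes lactate the
  dominant ischemia signature.

Shifts and linewidths are defaults, not claims: peak tables are plain
CSV and fully overridable; the evaluation properties depend on line
count and separation, not exact positions. Amplitude ratios were chosen
once as realistic values and are configurable.

What the simulator does **not** emulate: pulse-sequence physics (ISIS /
PRESS / water suppression), J-coupling evolution (multiplets are fixed
patterns, not quantum-simulated), macromolecule and lipid baselines,
eddy-current or non-Lorentzian lineshape distortions, frequency drift.
Passing tests therefore demonstrate correctness of the algorithmic chain
under the stated signal model, not performance on in vivo data, where
fit residuals are dominated by model mismatch rather than white noise.

## Denoiser

Pipeline: optional exponential line broadening (lb_hz; adds exactly
lb Hz to every Lorentzian FWHM) → Hankel embedding H[i,j] = s[i+j] of
shape W × (N−W+1) with W = ⌊N/2⌋ by default → truncated SVD at rank r →
reconstruction. Single pass; no Cadzow (truncate/re-Hankelize)
iteration.

- **Rank**: r equals the number of metabolites in the basis (13 for
  ³¹P, 16 for ¹H) by convention. For multiplet-rich ¹H signals the true
  exponential-model rank (number of sub-lines, 39 here) exceeds 16, so
  rank-16 truncation removes real signal; see Limitations.
- **Reconstruction**: the default reads the first row (samples 0…N−W)
  and the last column skipping its first entry (samples N−W+1…N−1); the
  shared corner entry is used once, the only length-preserving reading
  of first-row-plus-last-column concatenation. `antidiagonal_mean` (the
  least-squares projection onto Hankel structure, the standard
  Cadzow-style alternative) is provided for sensitivity analysis; for an
  exactly-Hankel matrix both are exact inverses of the embedding.
- **SVD**: LAPACK for small matrices; for min(shape) ≥ 256 and
  r ≤ min(shape)/8, a Lanczos partial SVD (`scipy.sparse.linalg.svds`)
  with a fixed all-ones start vector, so results are deterministic.
  Degenerate singular values are kept in sorted order; the truncated
  matrix is unique in Frobenius norm regardless of tie-breaking.
- Pre-broadening is never applied automatically; the CLI warns when the
  estimated noise singular level σ_t(√W + √(N−W+1)) exceeds a
  configurable fraction (default 0.5) of σ₁, the regime where 5–15 Hz
  of line broadening is advisable for ³¹P.

## Fitter, CRLB, SNR

The frequency-domain model on the analysis window (³¹P: −19.5–10 ppm;
¹H: 0.2–4.0 ppm) is

    S(ν) = e^{i(φ₀ + φ₁·(ppm−c))} Σ_m a_m B_m(ν; δf, γ) + Σ_j c_j P_j(ν)

with a_m ≥ 0 the per-metabolite amplitudes, B_m unit-amplitude basis
spectra (FFT of the peak-table sub-lines, shifted by δf Hz and damped by
γ Hz globally), and a complex Legendre baseline (degree 2 by default,
the smallest model that makes "maximum minus baseline" well defined).
Real and imaginary channels are fitted jointly. Nonlinear parameters
(φ₀, φ₁ ∈ ±180° / ±45°·ppm⁻¹, δf ∈ ±20 Hz, γ ∈ [0, 50] Hz) start at
zero and are refined by bounded trust-region least squares with the
linear part solved exactly at each step (variable projection; NNLS with
baseline coefficients sign-split). Phases are fitted, not assumed, so
phase-correction failures are observable. A collinearity check
(normalized Gram > 0.9999) rejects duplicate basis entries by name
before fitting.

**CRLB**: Fisher information F = Re(JᴴJ)/σ² over all parameters
(amplitudes, φ₀, φ₁, δf, γ, baseline), with analytic derivatives.
σ is the per-channel noise SD *of the windowed spectrum* (for
white time-domain noise of SD σ_t under the plain FFT this is σ_t·√N);
the default estimate is the RMS of the stacked fit residual, matching
the SNR denominator's spirit, and an explicit σ (e.g. from a signal-free
region) can be passed instead. %SD_m = 100·√((F⁻¹)_mm)/a_m, capped at
the conventional sentinel 999; amplitudes at machine scale relative to
the largest, or a singular Fisher matrix, also yield 999.

**SNR** = (max over the window of the phased real spectrum minus the
fitted baseline) / (2 × RMS of the phased real-channel residual). A
residual below 10⁻⁹ of the peak height (machine-scale, i.e. noiseless
fit-consistent input) reports +∞.

## Evaluation design

Replicates replace subjects: each adds an independent seeded noise
realization to the same ground truth, the *same* noisy FID is fitted
raw and after denoising, and metrics are compared pairwise (two-sided
paired t-test, α = 0.05). Sentinel (999) or non-finite values drop the
pair for that metric only (pairwise, per-metric deletion). Percent
differences are always recomputed from the table's own means. Zero or
degenerate difference variance renders p as NaN. No multiple-testing
correction is applied across metabolite rows, matching standard
reporting practice for such tables. Per-replicate seeds derive from the
master seed by fixed arithmetic and are recorded.

**Null calibration**: a literal identity denoiser on the same noisy FID
gives identically zero differences (the fitter is deterministic), so
the type-I error of the chain is checked with the second arm drawn as an
independent noise realization without denoising
(`denoiser="identity", paired_noise=False`); the paired p-values are
then uniform under the null, and the measured significance rate at
α = 0.05 stays within [0.01, 0.10] over 200 seeded experiments.

## Problem sizes used by the test suite

Chosen to keep the default `pytest` run to a few minutes on one CPU:
the denoising-efficacy check runs the full 4096-point ³¹P grid with 50
replicates; CRLB calibration (200 replicates) and type-I control (200
experiments × 4 replicates) use a 3-singlet, 256-point toy protocol
whose fits are milliseconds; statistical power at the ³¹P operating
point is demonstrated by the n = 50 efficacy run rather than by
repeating full-grid experiments.

## Numerical choices

- FFT convention: plain unnormalized FFT, fftshifted, axis reversed so
  ppm decreases left to right; Parseval holds as Σ|s|² = Σ|S|²/N.
- Odd N: W = ⌊N/2⌋, matrix W × (N−W+1).
- SNR calibration: σ is found by probing the measured mean SNR over a
  few seeded realizations, starting from the white-noise closed form
  peak/(2·SNR·√N) with one proportional correction, then log-space
  bisection to within 10% of the target.
- NNLS guarantees a_m ≥ 0 exactly; at a truth of zero amplitude the
  active constraint produces exact zeros on noiseless data.
- All RNG uses `numpy.random.default_rng` with integer seeds below 2³¹.

## Known limitations

- At the ¹H operating point the rank-16 truncation of a 39-sub-line
  signal discards genuine signal components; with noise as small as raw
  SNR ≈ 71 implies, the truncation loss exceeds the noise removed and
  the measured SNR (and some CRLBs) can *worsen* after denoising. The
  package reports this honestly; it is the synthetic counterpart of the
  information loss known for linear-predictability denoising of
  single-voxel ¹H data, whereas sparse ³¹P spectra (true rank = basis
  size) show severalfold SNR gains and uniformly smaller CRLBs.
- Concentration scaling is arbitrary-unit; only ratios (e.g. /PCr) and
  relative changes are meaningful. No water-reference scaling is
  modelled.
- The concat reconstruction takes the denoised FID's late samples from a
  single matrix column, so unlike anti-diagonal averaging it does not
  average the truncation residue; both modes are exposed.
- LCModel itself (spline baselines, lineshape priors, control
  parameters) is not emulated; raw and denoised arms always use the same
  fitter, so paired comparisons remain internally consistent.
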