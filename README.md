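# hankelmrs

Hankel low-rank denoising and quantification for single-voxel magnetic
resonance spectroscopy (MRS) time-domain signals, with a complete
in-silico evaluation chain.

Preclinical single-voxel MRS — e.g. ³¹P and ¹H spectra from small
mouse-brain voxels at 9.4 T — suffers from low signal-to-noise ratio
(SNR), and averaging longer is often impossible (scan time, anesthesia,
disease models). This package implements the post-processing
alternative: **linear-predictability (Hankel) low-rank denoising** of
the free induction decay (FID), together with everything needed to
evaluate it quantitatively on synthetic data that mimic the in vivo
acquisitions: a damped-exponential simulator, a linear-combination
spectral fitter with Cramér–Rao lower bounds (CRLB), the
LCModel-convention SNR statistic, and seeded raw-vs-denoised Monte-Carlo
comparison tables with paired t-tests.

## The method

A noiseless FID that is a sum of *r* damped complex exponentials

```
s[n] = Σ_k a_k e^{iφ_k} e^{2πi f_k n Δt} e^{−π λ_k n Δt}
```

is linearly predictable: the Hankel matrix `H[i, j] = s[i + j]` (shape
`W × (N−W+1)`, default `W = N/2`) has rank exactly *r*, while white
noise spreads over all singular values. The denoiser is therefore:

1. optional exponential line broadening (`e^{−π·lb·t}`, 5–15 Hz helps
   very noisy ³¹P data);
2. Hankel embedding of the FID;
3. truncated SVD at rank *r* — by Eckart–Young the Frobenius-optimal
   rank-*r* approximation; *r* is conventionally the number of
   metabolite resonances (13 for the ³¹P basis, 16 for ¹H);
4. reconstruction of the N-point FID from the truncated matrix, either
   by concatenating its first row and last column (default) or by
   anti-diagonal averaging.

Quantification fits `S(ν) = e^{i(φ₀+φ₁ν)} Σ_m a_m B_m(ν; δf, γ) +
baseline(ν)` over the analysis window (−19.5–10 ppm for ³¹P, 0.2–4.0 ppm
for ¹H) with non-negative amplitudes; per-metabolite uncertainty is the
CRLB `%SD = 100·√((F⁻¹)_mm)/a_m` from the full Fisher information, with
999 the conventional "not detected" sentinel, and
`SNR = (window max − baseline) / (2·RMS residual)`.

## Worked example

```sh
python examples/denoise_fid.py
```

```
rank r = 13, Hankel window W = 2048, pre-broadening = 5.0 Hz
SNR  raw      :     5.15
SNR  denoised :    24.11  (4.7x)
time-domain MSE vs truth: raw 0.3144 -> denoised 0.0063
```

A whole-brain ³¹P FID (4096 points, 16,025.64 Hz bandwidth, 13
resonances) with noise calibrated to raw SNR ≈ 5 gains a ~4.7× SNR
improvement from rank-13 truncation, and the denoised FID is ~50×
closer to the noiseless ground truth in mean squared error — the gain
is real signal recovery, not smoothing. The other scripts in
`examples/` show simulation (`simulate_spectrum.py`), CRLB tables before
and after denoising (`quantify_crlb.py`), and the replicated comparison
experiment (`compare_raw_vs_denoised.py`), e.g.:

```
 metric  n_pairs  mean_raw   sd_raw  mean_denoised  sd_denoised   pct_diff      p_value  significant
    snr        8  5.380744 0.232687      24.256714     3.556737 350.805943 1.205933e-06         True
crlb:PCr       8  4.598974 0.155155       0.863046     0.102593 -81.233952 1.885539e-10         True
```

A thin CLI mirrors the library (`hankelmrs simulate | denoise | fit |
evaluate`), operating on a plain-text columnar FID format that
round-trips bit-exactly.

## Layout

- `src/hankelmrs/signals.py` — acquisition metadata, FID and peak-table
  containers
- `src/hankelmrs/simulate.py` — synthetic ³¹P/¹H ground truth, noise,
  SNR calibration
- `src/hankelmrs/denoise.py` — apodization, Hankel embedding, truncated
  SVD, reconstruction
- `src/hankelmrs/quantify.py` — spectra, linear-combination fit, CRLB,
  SNR
- `src/hankelmrs/evaluate.py` — replicated experiments, paired t-tests,
  comparison tables
- `src/hankelmrs/io.py`, `cli.py` — file formats, configs, command line
- `docs/methods.md` — model assumptions, parameter choices, limitations
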