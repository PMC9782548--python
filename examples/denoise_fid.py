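"""Low-rank denoise a noisy 31P FID and measure the SNR gain.

The Hankel matrix of a 13-resonance FID has rank 13; truncating its SVD
at r = 13 (after 5 Hz exponential pre-broadening, as is useful for very
noisy phosphorus data) suppresses the noise spread across the remaining
singular values.
"""

import numpy as np

import hankelmrs as hm

table = hm.default_peak_table("P31")
acq = hm.P31_ACQ
truth = hm.synthesize_fid(table, acq)
sigma = hm.calibrate_sigma_for_snr(table, acq, target_snr=5.0, n_probe=4, rng_seed=0)
noisy = hm.add_noise(truth, sigma, rng_seed=7)

params = hm.DenoiseParams(r=13, lb_hz=5.0)  # W defaults to N/2 = 2048
denoised = hm.lowrank_denoise(noisy, params)

basis = hm.BasisSet.from_peak_table(table, acq)
fit_raw = hm.quantify_fid(noisy, basis)
fit_den = hm.quantify_fid(denoised, basis)

mse_raw = np.mean(np.abs(noisy.samples - truth.samples) ** 2)
mse_den = np.mean(np.abs(denoised.samples - truth.samples) ** 2)

print(f"rank r = {params.r}, Hankel window W = {acq.n_points // 2}, "
      f"pre-broadening = {params.lb_hz} Hz")
print(f"SNR  raw      : {fit_raw.snr:8.2f}")
print(f"SNR  denoised : {fit_den.snr:8.2f}  ({fit_den.snr / fit_raw.snr:.1f}x)")
print(f"time-domain MSE vs truth: raw {mse_raw:.4f} -> denoised {mse_den:.4f}")

# SNR is the LCModel convention (window maximum minus baseline over twice
# the RMS fit residual); the MSE line confirms the denoised FID is closer
# to the noiseless ground truth, not merely smoother.
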