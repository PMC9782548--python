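"""Fit a 31P spectrum and report amplitudes with CRLB uncertainties.

The linear-combination fitter estimates non-negative metabolite
amplitudes plus global phase, frequency-shift and damping nuisances over
the -19.5 to 10 ppm analysis window; uncertainty is the Cramer-Rao
lower bound in percent (%SD), with 999 marking "not detected".
"""

import hankelmrs as hm

table = hm.default_peak_table("P31")
acq = hm.P31_ACQ
truth = hm.synthesize_fid(table, acq)
sigma = hm.calibrate_sigma_for_snr(table, acq, target_snr=5.0, n_probe=4, rng_seed=0)
noisy = hm.add_noise(truth, sigma, rng_seed=3)
denoised = hm.lowrank_denoise(noisy, hm.DenoiseParams(r=13, lb_hz=5.0))

basis = hm.BasisSet.from_peak_table(table, acq)
fit_raw = hm.quantify_fid(noisy, basis)
fit_den = hm.quantify_fid(denoised, basis)
ratios = hm.concentration_ratios(fit_den, "PCr")

print(f"{'metabolite':<8} {'true':>6} {'raw %SD':>9} {'den %SD':>9} {'ratio/PCr':>10}")
for m in fit_raw.metabolites:
    print(f"{m:<8} {table.total_amplitude(m):>6.2f} "
          f"{fit_raw.crlb_of(m):>9.2f} {fit_den.crlb_of(m):>9.2f} "
          f"{ratios[m]:>10.2f}")
print(f"\nfitted phase0: raw {fit_raw.phase0_deg:+.1f} deg, "
      f"denoised {fit_den.phase0_deg:+.1f} deg")

# Denoising sharply shrinks the CRLBs of the well-detected metabolites;
# the weakest resonances (amplitudes a few percent of PCr) can stay at or
# fall to the 999 "not detected" sentinel at this noise level.  The /PCr
# column is the conventional phosphorus concentration reporting unit,
# with the reference itself at exactly 1.00.
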