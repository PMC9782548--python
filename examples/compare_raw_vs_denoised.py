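"""Seeded Monte-Carlo comparison of raw vs denoised quantification.

Runs a small replicated experiment at the whole-brain 31P operating
point (raw SNR ~5, rank 13) and prints the comparison table: mean +/- SD
per condition, percent difference, and the paired t-test p-value per
metric. Replicates stand in for subjects.
"""

from hankelmrs import DenoiseParams
from hankelmrs.evaluate import p31_experiment, run_experiment, summarize

config = p31_experiment(denoise=DenoiseParams(r=13, lb_hz=5.0))
records = run_experiment(config, n_replicates=8, master_seed=2024)
table = summarize(records)

rows = table.df[table.df["metric"].isin(["snr", "crlb:PCr", "crlb:b-ATP", "conc:Pi"])]
print(rows.to_string(index=False))

# "snr" should show a severalfold increase with p << 0.05; the CRLB rows
# shrink (lower uncertainty after denoising); "conc:Pi" is the Pi/PCr
# concentration ratio, which should stay near its ground-truth value of
# 0.26 in both arms.
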