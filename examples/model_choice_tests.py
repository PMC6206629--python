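"""Decide between a shared and per-genome mismatch probability.

Simulates one dataset where two genomes truly differ (0.005 vs 0.015
errors per base), fits both models, and runs the burden and variance
component tests of the shared-probability null.  Small p-values mean the
per-genome model (TADIP) is needed; large ones mean the single shared
probability (TAMER) is adequate.
"""

from tadip import (
    burden_test,
    fit_em,
    null_p0,
    simulate_dataset,
    tadip_recommended,
    varying_two_error_config,
    vct_test,
)

cfg = varying_two_error_config(n_reads=1000, seed=7)
table, _ = simulate_dataset(cfg)

alt = fit_em(table, mode="per_genome_p")
p0, E = null_p0(table)
print("per-genome estimates p_hat:", [f"{p:.4f}" for p in alt.params.p])
print(f"shared-probability null p0 = {p0:.4f}")
print("effective aligned bases E:", [f"{e:.0f}" for e in E])

b = burden_test(alt.params.p, p0, E)
v = vct_test(alt.params.p, p0, E)
print(f"burden test: statistic = {b.statistic:.2f}, p = {b.p_value:.3g}")
print(f"variance component test: statistic = {v.statistic:.3g}, "
      f"p = {v.p_value:.3g}")
print("recommendation:",
      "per-genome probabilities (TADIP)" if tadip_recommended(b, v)
      else "shared probability (TAMER) adequate")
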