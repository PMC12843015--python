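"""Simulated exact statistics by multinomial resampling.

With 60 patients per arm the delta-method normal approximation deserves a
check.  Conditioning on the 180 patients, the observed table induces a
multinomial over the six cells (probabilities a_ij/180); resampling whole
tables gives the finite-sample distribution of the log RR-difference, its
empirical variances/covariance, the statistic recomputed from those moments,
a right-tail exact p-value, and the shape (skewness, excess kurtosis) of the
standardized statistic.  A histogram with a standard-normal overlay is
written next to this script's working directory.

Uses 10^6 replicates to stay quick; pass a larger n_reps for tighter moments.
"""

from corrisk import export_histogram, make_table, render_report, run_exact

table = make_table([54, 6, 48, 12, 36, 24])
result = run_exact(table, n_reps=1_000_000, seed=180, keep_sample=1_000_000)
print(render_report({"exact": result}))

export_histogram(result, "zeta_histogram.png", bins=80)
print(
    "Wrote zeta_histogram.png (+ .csv bin counts).\n"
    f"The simulated distribution is right-skewed (skewness "
    f"{result.skewness:.4f}), so the exact right-tail p "
    f"({result.p_exact:.5f}) is a little more significant than the "
    "normal-theory two-sided p (0.01994) — not a universal ordering, "
    "just this table's."
)
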