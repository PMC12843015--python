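"""Exhaustive enumeration as an exact check on the Monte-Carlo machinery.

For small tables the full multinomial support — every composition of n
patients into the six cells, C(n+5,5) outcomes — can be enumerated and each
outcome weighted by its exact probability.  On the worked example scaled
down by six (n=30) this gives the exact moments the simulation estimates,
plus the probability mass of degenerate outcomes (zero event counts) the
simulation discards.
"""

from corrisk import enumerate_exact, make_table, run_exact

table = make_table([9, 1, 8, 2, 6, 4])  # the 180-patient trial divided by 6

exact = enumerate_exact(table)
sim = run_exact(table, n_reps=1_000_000, seed=30)

print(f"support outcomes: {exact.support_size}")
print(f"degenerate probability mass: {exact.mass_degenerate:.5f}")
print(f"{'quantity':<18}{'enumeration':>14}{'simulation':>14}")
for name_exact, name_sim in [
    ("var_log_rr1", "var_log_rr1_sim"),
    ("var_log_rr2", "var_log_rr2_sim"),
    ("cov_log", "cov_log_sim"),
    ("zeta", "zeta_sim"),
    ("p_exact", "p_exact"),
    ("skewness", "skewness"),
    ("excess_kurtosis", "excess_kurtosis"),
]:
    print(
        f"{name_exact:<18}{getattr(exact, name_exact):>14.5f}"
        f"{getattr(sim, name_sim):>14.5f}"
    )
print(
    "\nEvery simulated column should sit within Monte-Carlo error of the\n"
    "enumerated one; at n=30 the delta-method variances would be far less\n"
    "accurate, which is exactly when the exact route earns its keep."
)
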