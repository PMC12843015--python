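"""Simulated exact statistics for the correlated relative-risk test.

The delta-method variances behind the closed-form zeta statistic are
first-order approximations; with ~60 patients per arm their accuracy, and the
normality of the statistic, deserve a check.  Conditioning on the total
sample size ``n``, the observed table induces a multinomial distribution over
the six cells with probabilities ``a_ij / n``.  Drawing full 3x2 tables from
that multinomial gives the finite-sample ("simulated exact") distribution of
the log relative-risk difference:

* empirical variances and covariance of the per-replicate log RRs, to
  compare against their delta-method counterparts;
* the statistic recomputed with those simulated moments (``zeta_sim``);
* the standardized distribution of the per-replicate log-difference —
  each replicate's ``log RR1 - log RR2`` centered and scaled by the
  empirical mean and standard deviation of that quantity across replicates —
  whose sample skewness and excess kurtosis quantify the departure from
  normality, and whose right-tail area at ``zeta_sim`` is the exact p-value
  for interaction.

Replicates on which a log relative risk is undefined (a zero event count in
any arm) are discarded and counted; at the scale of a 60-per-arm trial with
common events this loses a negligible fraction of draws, and ``n_used`` makes
the loss visible.

For small ``n`` the full multinomial support can be enumerated instead,
giving the same moments exactly; :func:`enumerate_exact` is the oracle the
Monte-Carlo path is tested against.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import stats

from .contingency import ThreeByTwoTable
from .errors import DegenerateTableError
from .ratio_comparison import compare_rr

__all__ = [
    "ExactSimulationResult",
    "EnumerationResult",
    "DEFAULT_SEED",
    "GENERATOR_NAME",
    "cell_probabilities",
    "simulate_tables",
    "run_exact",
    "enumerate_exact",
    "export_histogram",
]

#: Default seed for the exact simulation; fixed so shipped example reports
#: are reproducible byte for byte.
DEFAULT_SEED = 180

#: The random-number generator algorithm; fixed by name so seeds stay
#: portable across releases.
GENERATOR_NAME = "numpy-PCG64"

_BATCH = 1_000_000  # replicates per simulation batch; keeps peak memory flat


@dataclass(frozen=True)
class ExactSimulationResult:
    """Outcome of a Monte-Carlo exact run; see :func:`run_exact`."""

    n_reps: int
    n_used: int
    var_log_rr1_sim: float
    var_log_rr2_sim: float
    cov_log_sim: float
    zeta_sim: float
    zeta_delta: float
    p_exact: float
    skewness: float
    excess_kurtosis: float
    seed: int
    threshold: str
    low_yield: bool
    statistic_sample: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_dict(self, display_sigfigs: int | None = None) -> dict:
        from .report import round_sig

        out = {
            "generator": GENERATOR_NAME,
            "seed": self.seed,
            "n_reps": self.n_reps,
            "n_used": self.n_used,
            "threshold": self.threshold,
            "low_yield": self.low_yield,
            "var_log_rr1_sim": self.var_log_rr1_sim,
            "var_log_rr2_sim": self.var_log_rr2_sim,
            "cov_log_sim": self.cov_log_sim,
            "zeta_sim": self.zeta_sim,
            "zeta_delta": self.zeta_delta,
            "p_exact": self.p_exact,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
        }
        if display_sigfigs is not None:
            out["display"] = {
                k: round_sig(v, display_sigfigs)
                for k, v in out.items()
                if isinstance(v, float)
            }
        return out

    def to_json(self, display_sigfigs: int | None = 5, **kwargs) -> str:
        return json.dumps(self.to_dict(display_sigfigs), **kwargs)


@dataclass(frozen=True)
class EnumerationResult:
    """Exact moments over the full multinomial support (small-n oracle).

    All moments are population moments of the distribution of the
    log relative risks conditional on non-degenerate outcomes; the excluded
    probability mass is reported in ``mass_degenerate``.
    """

    support_size: int
    total_probability: float
    mass_degenerate: float
    var_log_rr1: float
    var_log_rr2: float
    cov_log: float
    zeta: float
    p_exact: float
    skewness: float
    excess_kurtosis: float


def cell_probabilities(table: ThreeByTwoTable) -> np.ndarray:
    """Multinomial cell probabilities ``p_ij = a_ij / n`` in row-major order.

    Sums to 1 up to floating-point rounding (exactly 1 in rational
    arithmetic).
    """
    n = table.n
    if n <= 0:
        raise DegenerateTableError("table has no observations")
    return table.counts.ravel() / n


def _batch_sizes(n_reps: int, batch: int = _BATCH) -> Iterator[int]:
    remaining = n_reps
    while remaining > 0:
        yield min(batch, remaining)
        remaining -= min(batch, remaining)


def simulate_tables(table: ThreeByTwoTable, n_reps: int, seed: int) -> Iterator[np.ndarray]:
    """Yield ``n_reps`` multinomial replicate tables, each a 3x2 int array.

    Every replicate redistributes all ``n`` patients over the six cells
    according to ``cell_probabilities(table)`` — row totals vary across
    replicates by design, since the single multinomial is conditioned only on
    ``n``.  The stream is deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    probs = cell_probabilities(table)
    n = table.n
    rng = np.random.default_rng(seed)
    for size in _batch_sizes(n_reps):
        draws = rng.multinomial(n, probs, size=size)
        for row in draws:
            yield row.reshape(3, 2)


def run_exact(
    table: ThreeByTwoTable,
    n_reps: int = 10_000_000,
    seed: int = DEFAULT_SEED,
    threshold: str = "simulated_moment",
    keep_sample: int = 0,
    max_sample: int = 1_000_000,
) -> ExactSimulationResult:
    """Monte-Carlo exact statistics for the correlated relative-risk test.

    Parameters
    ----------
    table
        The observed table; must be non-degenerate under
        :func:`~corrisk.ratio_comparison.compare_rr`.
    n_reps
        Number of multinomial replicates.
    seed
        Seed for the ``numpy`` PCG64 generator.
    threshold
        Which observed statistic the right-tail area is measured at:
        ``"simulated_moment"`` (default) thresholds at ``zeta_sim``, the
        statistic recomputed from the simulated variances/covariance;
        ``"delta_method"`` thresholds at the closed-form delta-method zeta.
    keep_sample
        If positive, retain up to ``min(keep_sample, max_sample)`` of the
        standardized replicate statistics (for plotting).

    Notes
    -----
    ``p_exact`` is the plain proportion of standardized replicate statistics
    at or above the threshold, so it can be exactly 0 for extreme inputs.
    Replicates are drawn and reduced in fixed-size batches; only one scalar
    per replicate is held across batches.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if threshold not in {"simulated_moment", "delta_method"}:
        raise ValueError(f"unknown threshold {threshold!r}")
    baseline = compare_rr(table)  # raises on degenerate input tables
    probs = cell_probabilities(table)
    n = table.n
    rng = np.random.default_rng(seed)

    diffs = np.empty(n_reps)  # per-replicate log RR1 - log RR2
    s1 = s2 = s11 = s22 = s12 = 0.0
    used = 0
    for size in _batch_sizes(n_reps):
        draws = rng.multinomial(n, probs, size=size)
        a11, a12, a21, a22, a31, a32 = draws.T
        r1, r2, r3 = a11 + a12, a21 + a22, a31 + a32
        ok = (a11 > 0) & (a21 > 0) & (a31 > 0)
        a11, a21, a31, r1, r2, r3 = (x[ok] for x in (a11, a21, a31, r1, r2, r3))
        log_pi0 = np.log(a11 / r1)
        l1 = log_pi0 - np.log(a31 / r3)
        l2 = log_pi0 - np.log(a21 / r2)
        k = l1.size
        diffs[used : used + k] = l1 - l2
        used += k
        s1 += l1.sum()
        s2 += l2.sum()
        s11 += (l1 * l1).sum()
        s22 += (l2 * l2).sum()
        s12 += (l1 * l2).sum()

    if used < 2:
        raise DegenerateTableError(
            "all (or all but one) simulated replicates were degenerate; "
            "the simulated moments are undefined"
        )
    diffs = diffs[:used]
    m1, m2 = s1 / used, s2 / used
    var1 = (s11 - used * m1 * m1) / (used - 1)
    var2 = (s22 - used * m2 * m2) / (used - 1)
    cov = (s12 - used * m1 * m2) / (used - 1)

    mean_d = diffs.mean()
    sd_d = diffs.std(ddof=1)
    if sd_d == 0:
        raise DegenerateTableError("simulated log-difference has zero variance")
    zeta_sim = baseline.log_diff / sd_d
    standardized = (diffs - mean_d) / sd_d
    cut = zeta_sim if threshold == "simulated_moment" else baseline.zeta
    p_exact = float(np.count_nonzero(standardized >= cut)) / used

    low_yield = used / n_reps < 0.5
    if low_yield:
        warnings.warn(
            f"only {used}/{n_reps} replicates were non-degenerate; "
            "simulated moments may be unreliable",
            stacklevel=2,
        )

    sample = None
    if keep_sample > 0:
        sample = standardized[: min(keep_sample, max_sample)].copy()

    return ExactSimulationResult(
        n_reps=n_reps,
        n_used=used,
        var_log_rr1_sim=float(var1),
        var_log_rr2_sim=float(var2),
        cov_log_sim=float(cov),
        zeta_sim=float(zeta_sim),
        zeta_delta=float(baseline.zeta),
        p_exact=p_exact,
        skewness=float(stats.skew(standardized, bias=False)),
        excess_kurtosis=float(stats.kurtosis(standardized, fisher=True, bias=False)),
        seed=seed,
        threshold=threshold,
        low_yield=low_yield,
        statistic_sample=sample,
    )


def _full_support(n: int) -> np.ndarray:
    """All compositions of ``n`` into six non-negative cells (stars and bars)."""
    bars = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n + 5), 5)),
        dtype=np.int64,
    ).reshape(-1, 5)
    edges = np.concatenate(
        [
            np.zeros((len(bars), 1), dtype=np.int64),
            bars + 1,
            np.full((len(bars), 1), n + 6, dtype=np.int64),
        ],
        axis=1,
    )
    return np.diff(edges, axis=1) - 1


def enumerate_exact(table: ThreeByTwoTable, max_n: int = 40) -> EnumerationResult:
    """Exact moments of the simulated-exact distribution by full enumeration.

    Iterates every composition of ``n`` patients into the six cells, weights
    each outcome by its multinomial probability, and computes the same
    quantities as :func:`run_exact` by exact weighted sums.  The support has
    ``C(n+5, 5)`` outcomes, so this is restricted to small tables; it exists
    as the independent oracle for the Monte-Carlo path.

    Raises
    ------
    ValueError
        If ``table.n > max_n``; use :func:`run_exact` for large tables.
    """
    n = table.n
    if n > max_n:
        raise ValueError(
            f"table total n={n} exceeds max_n={max_n}; the support has "
            f"C(n+5,5) outcomes — use run_exact for tables this large"
        )
    baseline = compare_rr(table)
    probs = cell_probabilities(table)
    support = _full_support(n)
    weights = stats.multinomial.pmf(support, n=n, p=probs)

    a11, a12, a21, a22, a31, a32 = support.T
    ok = (a11 > 0) & (a21 > 0) & (a31 > 0)
    mass_degenerate = float(weights[~ok].sum())
    w = weights[ok]
    total = w.sum()
    if total <= 0:
        raise DegenerateTableError("every outcome in the support is degenerate")
    w = w / total
    a11, a21, a31 = a11[ok], a21[ok], a31[ok]
    r1, r2, r3 = (a11 + a12[ok]), (a21 + a22[ok]), (a31 + a32[ok])
    log_pi0 = np.log(a11 / r1)
    l1 = log_pi0 - np.log(a31 / r3)
    l2 = log_pi0 - np.log(a21 / r2)

    m1 = float(w @ l1)
    m2 = float(w @ l2)
    var1 = float(w @ (l1 - m1) ** 2)
    var2 = float(w @ (l2 - m2) ** 2)
    cov = float(w @ ((l1 - m1) * (l2 - m2)))

    d = l1 - l2
    mean_d = float(w @ d)
    var_d = float(w @ (d - mean_d) ** 2)
    sd_d = math.sqrt(var_d)
    if sd_d == 0:
        raise DegenerateTableError(
            "the log-difference is constant over the non-degenerate support"
        )
    z = (d - mean_d) / sd_d
    zeta = baseline.log_diff / sd_d
    return EnumerationResult(
        support_size=len(support),
        total_probability=float(weights.sum()),
        mass_degenerate=mass_degenerate,
        var_log_rr1=var1,
        var_log_rr2=var2,
        cov_log=cov,
        zeta=zeta,
        p_exact=float(w[z >= zeta].sum()),
        skewness=float(w @ z**3),
        excess_kurtosis=float(w @ z**4) - 3.0,
    )


def export_histogram(
    result: ExactSimulationResult, path: str | Path, bins: int = 60
) -> None:
    """Plot the standardized replicate statistics with a N(0,1) overlay.

    Writes the figure to ``path`` (PNG/SVG by extension) and the binned
    counts to the same path with a ``.csv`` suffix, columns
    ``bin_left,bin_right,count``.  Requires the run to have retained a
    statistic sample (``keep_sample > 0`` in :func:`run_exact`).
    """
    if result.statistic_sample is None or len(result.statistic_sample) == 0:
        raise ValueError(
            "no statistic sample retained; rerun run_exact with keep_sample > 0"
        )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sample = np.asarray(result.statistic_sample)
    counts, edges = np.histogram(sample, bins=bins)

    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(sample, bins=edges, density=True, color="#7a9fc2", edgecolor="white")
    grid = np.linspace(edges[0], edges[-1], 400)
    ax.plot(grid, stats.norm.pdf(grid), "k-", lw=1.5, label="standard normal")
    ax.axvline(result.zeta_sim, color="firebrick", ls="--", lw=1, label="observed zeta")
    ax.set_xlabel("standardized log RR-difference")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write("bin_left,bin_right,count\n")
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{left!r},{right!r},{int(count)}\n")
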