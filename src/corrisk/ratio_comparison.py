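"""Closed-form comparison of two correlated relative risks (or odds ratios).

Two treatments T1, T2 are each compared with the same referent-control arm
T0, giving two relative risks

    RR1 = pi0 / pi2     (T0 vs T2, the new treatment)
    RR2 = pi0 / pi1     (T0 vs T1, the standard treatment)

with ``pi_i`` the per-arm unfavorable-event probability.  Because both ratios
share the referent numerator, log RR1 and log RR2 are positively correlated;
the test for a differential treatment effect works on the log-difference
scale,

    zeta = (log RR1 - log RR2) / sqrt(Var1 + Var2 - 2 Cov),

where the variances and the covariance come from the first-order delta
method:

    Var(log RRk) = 1/a11 - 1/a1+ + 1/ak1 - 1/ak+
    Cov(log RR1, log RR2) = 1/a11 - 1/a1+        (the shared-arm component)

Under the null of equal relative risks, zeta is asymptotically standard
normal, and the two-sided tail probability is the single p-value for
interaction — no multiplicity adjustment is needed in this three-arm design.
The odds-ratio analogue replaces the risks by odds and uses the classic
Woolf cell-reciprocal variances.

Zero event counts make a log relative risk infinite; they raise
:class:`~corrisk.errors.DegenerateTableError` rather than being patched by a
continuity correction, so printed results are exactly reproducible from the
raw counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

from scipy import stats

from .contingency import ThreeByTwoTable
from .errors import DegenerateTableError, DegenerateVarianceError
from .report import round_sig

__all__ = [
    "RiskComparisonResult",
    "OddsComparisonResult",
    "rr_estimates",
    "var_log_rr",
    "cov_log_rr",
    "zeta_statistic",
    "p_interaction",
    "compare_rr",
    "or_estimates",
    "compare_or",
]


@dataclass(frozen=True)
class RiskComparisonResult:
    """Correlated relative-risk comparison on the log-difference scale.

    Attributes
    ----------
    rr1, rr2
        Relative risks ``pi0/pi2`` and ``pi0/pi1`` (referent over treatment).
    log_diff
        ``log(rr1) - log(rr2)``, natural logarithms.
    var_log_rr1, var_log_rr2, cov_log
        Delta-method variances of the log relative risks and their
        covariance (the shared referent-arm component).
    se_log_diff
        ``sqrt(var_log_rr1 + var_log_rr2 - 2 cov_log)``.
    zeta
        Standardized statistic ``log_diff / se_log_diff``.
    p_interaction
        Two-sided normal p-value ``2 (1 - Phi(|zeta|))``.
    rld_percent
        Relative risk-reduction on the log-difference scale,
        ``(rr1/rr2 - 1) x 100``; positive when the new treatment (T2)
        reduces risk more than the standard one (T1).
    """

    rr1: float
    rr2: float
    log_diff: float
    var_log_rr1: float
    var_log_rr2: float
    cov_log: float
    se_log_diff: float
    zeta: float
    p_interaction: float
    rld_percent: float

    def to_dict(self, display_sigfigs: int = 5) -> dict:
        """Full-precision fields plus a ``display`` block rounded to
        ``display_sigfigs`` significant digits."""
        full = asdict(self)
        full["display"] = {k: round_sig(v, display_sigfigs) for k, v in asdict(self).items()}
        return full

    def to_json(self, display_sigfigs: int = 5, **kwargs) -> str:
        return json.dumps(self.to_dict(display_sigfigs), **kwargs)


@dataclass(frozen=True)
class OddsComparisonResult:
    """Correlated odds-ratio comparison; see :class:`RiskComparisonResult`.

    ``ror_reduction_percent`` is ``(or1/or2 - 1) x 100``, the odds-ratio
    analogue of the relative risk-reduction.
    """

    or1: float
    or2: float
    log_diff: float
    var_log_or1: float
    var_log_or2: float
    cov_log: float
    se_log_diff: float
    zeta: float
    p_interaction: float
    ror_reduction_percent: float

    def to_dict(self, display_sigfigs: int = 5) -> dict:
        full = asdict(self)
        full["display"] = {k: round_sig(v, display_sigfigs) for k, v in asdict(self).items()}
        return full

    def to_json(self, display_sigfigs: int = 5, **kwargs) -> str:
        return json.dumps(self.to_dict(display_sigfigs), **kwargs)


def _require_events(table: ThreeByTwoTable) -> None:
    for i, events in enumerate(table.event_counts):
        if events == 0:
            raise DegenerateTableError(
                f"zero event count in arm {table.arm_labels[i]!r}: "
                "log relative risk is undefined"
            )


def rr_estimates(table: ThreeByTwoTable) -> tuple[float, float]:
    """Point estimates ``(rr1, rr2)`` of the two correlated relative risks.

    ``rr1 = (a11/a1+) / (a31/a3+)`` compares the referent with treatment T2;
    ``rr2 = (a11/a1+) / (a21/a2+)`` compares it with T1.
    """
    _require_events(table)
    pi0, pi1, pi2 = table.risks
    return pi0 / pi2, pi0 / pi1


def var_log_rr(a11: int, a1p: int, ak1: int, akp: int) -> float:
    """Delta-method variance of ``log RRk``: ``1/a11 - 1/a1+ + 1/ak1 - 1/ak+``.

    ``(a11, a1p)`` are the referent arm's event count and size, ``(ak1, akp)``
    the treatment arm's.
    """
    if a11 <= 0 or ak1 <= 0:
        raise DegenerateTableError("zero event count: Var(log RR) is undefined")
    # grouped so the referent component equals cov_log_rr to the last bit
    return (1 / a11 - 1 / a1p) + (1 / ak1 - 1 / akp)


def cov_log_rr(a11: int, a1p: int) -> float:
    """Delta-method covariance of the two log relative risks.

    Equals ``1/a11 - 1/a1+`` — the variance component contributed by the
    shared referent arm, i.e. the first two terms of either
    :func:`var_log_rr`.
    """
    if a11 <= 0:
        raise DegenerateTableError("zero event count in referent arm")
    return 1 / a11 - 1 / a1p


def zeta_statistic(log_diff: float, var1: float, var2: float, cov: float) -> float:
    """Standardized log-difference ``(log_diff - 0) / sqrt(var1 + var2 - 2 cov)``.

    The null expectation of the log-difference is zero (equal relative
    risks), so no centering term appears.
    """
    denom = var1 + var2 - 2 * cov
    if denom <= 0:
        raise DegenerateVarianceError(
            f"variance of the log-difference is not positive ({denom!r})"
        )
    return log_diff / math.sqrt(denom)


def p_interaction(zeta: float) -> float:
    """Two-sided normal p-value ``2 (1 - Phi(|zeta|))``, in (0, 1].

    The absolute value keeps the p-value invariant under swapping the two
    treatment arms (which only flips the sign of zeta).
    """
    if not math.isfinite(zeta):
        raise ValueError(f"zeta must be finite, got {zeta!r}")
    return float(min(1.0, 2.0 * stats.norm.sf(abs(zeta))))


def compare_rr(table: ThreeByTwoTable) -> RiskComparisonResult:
    """Full correlated relative-risk comparison for a validated table.

    >>> from corrisk import make_table, compare_rr
    >>> res = compare_rr(make_table([54, 6, 48, 12, 36, 24]))
    >>> round(res.zeta, 4), round(res.rld_percent, 3)
    (2.3275, 33.333)
    """
    rr1, rr2 = rr_estimates(table)
    a11 = int(table.counts[0, 0])
    a1p, a2p, a3p = (int(x) for x in table.row_totals)
    a21, a31 = int(table.counts[1, 0]), int(table.counts[2, 0])
    var1 = var_log_rr(a11, a1p, a31, a3p)
    var2 = var_log_rr(a11, a1p, a21, a2p)
    cov = cov_log_rr(a11, a1p)
    log_diff = math.log(rr1) - math.log(rr2)
    zeta = zeta_statistic(log_diff, var1, var2, cov)
    return RiskComparisonResult(
        rr1=rr1,
        rr2=rr2,
        log_diff=log_diff,
        var_log_rr1=var1,
        var_log_rr2=var2,
        cov_log=cov,
        se_log_diff=math.sqrt(var1 + var2 - 2 * cov),
        zeta=zeta,
        p_interaction=p_interaction(zeta),
        rld_percent=(rr1 / rr2 - 1.0) * 100.0,
    )


def or_estimates(table: ThreeByTwoTable) -> tuple[float, float]:
    """Point estimates ``(or1, or2)`` of the two correlated odds ratios.

    ``or1 = (a11/a12) / (a31/a32)``; ``or2 = (a11/a12) / (a21/a22)``.
    All six cells must be positive.
    """
    c = table.counts
    for i in range(3):
        for j in range(2):
            if c[i, j] == 0:
                raise DegenerateTableError(
                    f"zero cell for arm {table.arm_labels[i]!r}, outcome "
                    f"{table.outcome_labels[j]!r}: odds ratio is undefined"
                )
    odds = c[:, 0] / c[:, 1]
    return float(odds[0] / odds[2]), float(odds[0] / odds[1])


def compare_or(table: ThreeByTwoTable) -> OddsComparisonResult:
    """Full correlated odds-ratio comparison for a validated table.

    Variances are the Woolf cell-reciprocal sums
    ``Var(log ORk) = 1/a11 + 1/a12 + 1/ak1 + 1/ak2`` and the covariance is
    the shared referent-arm component ``1/a11 + 1/a12``.
    """
    or1, or2 = or_estimates(table)
    a11, a12 = (int(x) for x in table.counts[0])
    a21, a22 = (int(x) for x in table.counts[1])
    a31, a32 = (int(x) for x in table.counts[2])
    cov = 1 / a11 + 1 / a12
    var1 = cov + (1 / a31 + 1 / a32)
    var2 = cov + (1 / a21 + 1 / a22)
    log_diff = math.log(or1) - math.log(or2)
    zeta = zeta_statistic(log_diff, var1, var2, cov)
    return OddsComparisonResult(
        or1=or1,
        or2=or2,
        log_diff=log_diff,
        var_log_or1=var1,
        var_log_or2=var2,
        cov_log=cov,
        se_log_diff=math.sqrt(var1 + var2 - 2 * cov),
        zeta=zeta,
        p_interaction=p_interaction(zeta),
        ror_reduction_percent=(or1 / or2 - 1.0) * 100.0,
    )
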