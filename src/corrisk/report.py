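"""Rendering of analysis results as text or JSON.

Display values are rounded to a number of *significant* digits rather than a
fixed number of decimal places, so a variance of 0.0129630 and a statistic of
2.32746 are both shown with the same information content.
"""

from __future__ import annotations

import json
import math
from typing import Any

__all__ = ["round_sig", "format_sig", "render_report"]


def round_sig(x: float, sigfigs: int = 5) -> float:
    """Round ``x`` to ``sigfigs`` significant digits (half-even at the cut)."""
    if not isinstance(x, (int, float)):
        return x
    if x == 0 or not math.isfinite(x):
        return float(x)
    return float(f"{x:.{sigfigs}g}")


def format_sig(x: float, sigfigs: int = 5) -> str:
    """Format ``x`` with ``sigfigs`` significant digits, without exponent
    notation for ordinary magnitudes."""
    v = round_sig(x, sigfigs)
    if v == int(v) and abs(v) < 1e15:
        return f"{v:g}"
    return f"{v:.{sigfigs}g}"


_RR_ROWS = [
    ("RR1 (referent vs T2)", "rr1"),
    ("RR2 (referent vs T1)", "rr2"),
    ("log(RR1/RR2)", "log_diff"),
    ("Var(log RR1)", "var_log_rr1"),
    ("Var(log RR2)", "var_log_rr2"),
    ("Cov(log RR1, log RR2)", "cov_log"),
    ("SE of log-difference", "se_log_diff"),
    ("zeta (RRR)", "zeta"),
    ("p-value for interaction", "p_interaction"),
    ("Risk-reduction, log-difference scale (%)", "rld_percent"),
]

_OR_ROWS = [
    ("OR1 (referent vs T2)", "or1"),
    ("OR2 (referent vs T1)", "or2"),
    ("log(OR1/OR2)", "log_diff"),
    ("Var(log OR1)", "var_log_or1"),
    ("Var(log OR2)", "var_log_or2"),
    ("Cov(log OR1, log OR2)", "cov_log"),
    ("SE of log-difference", "se_log_diff"),
    ("zeta (ROR)", "zeta"),
    ("p-value for interaction", "p_interaction"),
    ("OR reduction, log-difference scale (%)", "ror_reduction_percent"),
]

_EXACT_ROWS = [
    ("replicates requested", "n_reps"),
    ("replicates used", "n_used"),
    ("simulated Var(log RR1)", "var_log_rr1_sim"),
    ("simulated Var(log RR2)", "var_log_rr2_sim"),
    ("simulated Cov", "cov_log_sim"),
    ("zeta from simulated moments", "zeta_sim"),
    ("zeta from delta-method moments", "zeta_delta"),
    ("exact p-value (right tail)", "p_exact"),
    ("skewness of simulated statistic", "skewness"),
    ("excess kurtosis of simulated statistic", "excess_kurtosis"),
    ("seed", "seed"),
]


def _section(title: str, rows: list[tuple[str, str]], obj: Any, sigfigs: int) -> list[str]:
    lines = [title, "-" * len(title)]
    width = max(len(label) for label, _ in rows)
    for label, attr in rows:
        value = getattr(obj, attr)
        if isinstance(value, bool) or isinstance(value, int):
            text = str(value)
        else:
            text = format_sig(value, sigfigs)
        lines.append(f"{label:<{width}}  {text}")
    return lines


def render_report(results: dict[str, Any], output_format: str = "text", display_sigfigs: int = 5) -> str:
    """Render one or more results as a report document.

    Parameters
    ----------
    results
        Mapping with any of the keys ``"rr"``, ``"or"``, ``"exact"`` holding
        a :class:`~corrisk.ratio_comparison.RiskComparisonResult`,
        :class:`~corrisk.ratio_comparison.OddsComparisonResult` or
        :class:`~corrisk.exact_multinomial.ExactSimulationResult`.
    output_format
        ``"text"`` for a human-readable report, ``"json"`` for a document
        carrying full-precision values plus a rounded ``display`` block.
    """
    if not results:
        raise ValueError("no results to render")
    if output_format == "json":
        payload = {
            key: value.to_dict(display_sigfigs) for key, value in results.items()
        }
        return json.dumps(payload, indent=1)
    if output_format != "text":
        raise ValueError(f"unknown output format {output_format!r}")

    chunks: list[str] = []
    if "rr" in results:
        chunks.extend(_section("Correlated relative risks", _RR_ROWS, results["rr"], display_sigfigs))
        chunks.append("")
    if "or" in results:
        chunks.extend(_section("Correlated odds ratios", _OR_ROWS, results["or"], display_sigfigs))
        chunks.append("")
    if "exact" in results:
        chunks.extend(_section("Simulated exact statistics", _EXACT_ROWS, results["exact"], display_sigfigs))
        exact = results["exact"]
        if getattr(exact, "low_yield", False):
            chunks.append(
                "warning: more than half of the replicates were degenerate; "
                "interpret the simulated moments with caution"
            )
        chunks.append("")
    return "\n".join(chunks).rstrip() + "\n"
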