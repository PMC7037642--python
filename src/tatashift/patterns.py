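"""Exact binomial selection-pattern statistics.

Two questions are asked of each marker set's direction counts:

* Neutral drift: is the genome-wide excess of TBP-site-damaging over
  -improving variants present?  ``drift_confidence(n_gt, n_lt)`` is the
  acceptance probability of "damaging variants dominate",
  1 - P(X >= n_lt | n_gt + n_lt, 1/2).

* Equivalence of atherogenesis directions: can "accelerating and slowing
  markers are equally frequent" be rejected?  ``equivalence_p`` is the exact
  one-sided binomial tail at the larger of the two counts.

Both are exact Binomial(n, q) tail computations; the genome-wide reference
ratio 200:800 can be interrogated with ``binom_upper_tail`` at q = 0.2.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .annotation import MarkerCounts

__all__ = [
    "binom_upper_tail",
    "drift_confidence",
    "equivalence_p",
    "build_pattern_table",
    "format_probability",
]


def binom_upper_tail(k: int, n: int, q: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, q).

    Cumulative summation of the probability mass from k to n; for large n
    the terms are accumulated in log space.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(q)
        + (n - i) * math.log1p(-q)
    )
    if n > 1000:
        return float(np.exp(logsumexp(log_terms)))
    return float(np.exp(log_terms).sum())


def drift_confidence(n_gt: int, n_lt: int) -> float:
    """Acceptance probability of "affinity-damaging variants dominate".

    1 - P(X >= n_lt | n, 1/2): close to 1 when damaging ('<'-side) variants
    clearly outnumber improving ones, small when they clearly do not.
    """
    n = n_gt + n_lt
    if n < 1:
        raise ValueError("need at least one directional marker")
    return 1.0 - binom_upper_tail(n_lt, n, 0.5)


def equivalence_p(n_up: int, n_dn: int) -> float:
    """Exact tail P(X >= max(n_up, n_dn) | n_up + n_dn, 1/2).

    Small values reject the hypothesis that the two atherogenesis
    directions are equally frequent.
    """
    n = n_up + n_dn
    if n < 1:
        raise ValueError("need at least one classified marker")
    return binom_upper_tail(max(n_up, n_dn), n, 0.5)


def format_probability(p: float) -> str:
    """Display convention of the summary table: '>0.99', '<0.01', '<0.05',
    otherwise two decimals."""
    if p > 0.99:
        return ">0.99"
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return f"{p:.2f}"


def build_pattern_table(counts: list[MarkerCounts]) -> pd.DataFrame:
    """One result row per counts row, in the summary-table shape."""
    rows = []
    for c in counts:
        has_drift = (c.n_gt + c.n_lt) >= 1
        has_eq = (c.n_up + c.n_dn) >= 1
        drift = drift_confidence(c.n_gt, c.n_lt) if has_drift else float("nan")
        eq = equivalence_p(c.n_up, c.n_dn) if has_eq else float("nan")
        rows.append(
            {
                "set": c.set_label,
                "n_gene": c.n_gene,
                "n_snp": c.n_snp,
                "n_res": c.n_res,
                "n_gt": c.n_gt,
                "n_lt": c.n_lt,
                "drift_confidence": drift,
                "drift_display": format_probability(drift) if has_drift else "-",
                "n_up": c.n_up,
                "n_dn": c.n_dn,
                "equivalence_p": eq,
                "equivalence_display": format_probability(eq) if has_eq else "-",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set", "n_gene", "n_snp", "n_res", "n_gt", "n_lt",
            "drift_confidence", "drift_display", "n_up", "n_dn",
            "equivalence_p", "equivalence_display",
        ],
    )
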