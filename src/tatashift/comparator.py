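"""Fisher Z comparison of WT vs minor-allele affinity estimates.

Two ln K_D estimates with known standard errors are compared with the normal
(Fisher Z) test.  Because TBP-promoter affinity and transcription output are
proportionally related, a significant K_D increase in the minor allele reads
as an expression decrease ('<', "deficiency") and a significant decrease as
an expression increase ('>', "excess").  p-values are mapped onto the
significance bins {1e-6, 1e-3, 1e-2, 0.05} and the heuristic marker ranks
A (best) .. E (non-significant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .affinity import AffinityEstimate

__all__ = [
    "AlleleComparison",
    "ALPHA_BINS",
    "RANK_BY_BIN",
    "fisher_z_compare",
    "significance_bin",
    "assign_rank",
    "delta_sign",
    "alpha_label",
]

ALPHA_BINS = (1e-6, 1e-3, 1e-2, 0.05)
RANK_BY_BIN = {1e-6: "A", 1e-3: "B", 1e-2: "C", 0.05: "D", "ns": "E"}


@dataclass
class AlleleComparison:
    """Outcome of one WT vs minor comparison.

    delta: '>' expression increase (K_D falls), '<' decrease, '=' no change
    (equal estimates or non-significant).  decision mirrors the wording of
    the affinity-deficit report: "deficiency: significant" for '<',
    "excess: significant" for '>', else "insignificant".
    """

    snp_id: str
    ln_kd_wt: float
    ln_kd_min: float
    se_wt: float
    se_min: float
    z: float
    p: float
    alpha_bin: float | str
    rank: str
    delta: str
    decision: str
    gene: str | None = None


def significance_bin(p: float) -> float | str:
    """Smallest bin in {1e-6, 1e-3, 1e-2, 0.05} with p <= bin, else 'ns'."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    for b in ALPHA_BINS:
        if p <= b:
            return b
    return "ns"


def assign_rank(alpha_bin: float | str) -> str:
    """Heuristic rank letter for a significance bin (A best .. E worst)."""
    try:
        return RANK_BY_BIN[alpha_bin]
    except KeyError:
        raise ValueError(f"unknown significance bin {alpha_bin!r}") from None


def delta_sign(ln_kd_wt: float, ln_kd_min: float) -> str:
    """Raw direction of the predicted expression change, ignoring
    significance: '>' if K_D falls in the minor allele, '<' if it rises."""
    if ln_kd_min < ln_kd_wt:
        return ">"
    if ln_kd_min > ln_kd_wt:
        return "<"
    return "="


def fisher_z_compare(
    est_wt: AffinityEstimate,
    est_min: AffinityEstimate,
    snp_id: str = "",
    gene: str | None = None,
) -> AlleleComparison:
    """Two-tailed normal test on the difference of two ln K_D estimates."""
    if not (est_wt.se > 0 and est_min.se > 0):
        raise ValueError("both standard errors must be positive")
    diff = est_min.ln_kd - est_wt.ln_kd
    z = abs(diff) / float((est_wt.se**2 + est_min.se**2) ** 0.5)
    # clamp against underflow at extreme z so the p stays in (0, 1]
    p = min(max(float(2.0 * norm.sf(z)), 5e-324), 1.0)
    bin_ = significance_bin(p)
    rank = assign_rank(bin_)
    if bin_ == "ns" or diff == 0:
        delta = "="
        decision = "insignificant"
    elif diff < 0:
        delta = ">"
        decision = "excess: significant"
    else:
        delta = "<"
        decision = "deficiency: significant"
    return AlleleComparison(
        snp_id=snp_id,
        ln_kd_wt=est_wt.ln_kd,
        ln_kd_min=est_min.ln_kd,
        se_wt=est_wt.se,
        se_min=est_min.se,
        z=z,
        p=p,
        alpha_bin=bin_,
        rank=rank,
        delta=delta,
        decision=decision,
        gene=gene,
    )


def alpha_label(alpha_bin: float | str) -> str:
    """Render a bin the way the marker tables print it."""
    if alpha_bin == "ns":
        return "ns"
    if alpha_bin == 0.05:
        return "0.05"
    return f"10^{round(math.log10(alpha_bin))}"
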