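"""Agreement statistics between predicted and measured ln K_D.

Four correlation measures are reported for a set of (predicted, measured)
pairs: Pearson's r, Spearman's R, Kendall's tau (tau-b, tie-corrected) and
the Goodman-Kruskal gamma.  Gamma ignores tied pair-of-pairs entirely, which
suits in vitro K_D values quoted on a rounded nM scale; because validation
sets are small (a handful of tested SNPs), its p-value is obtained by
permutation rather than asymptotics.

The same machinery applies on the allele-difference scale: one
(minor - ancestral) difference pair per SNP, which removes the shared
promoter context and isolates the predicted shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConcordancePair",
    "ConcordanceReport",
    "gk_gamma",
    "compute_concordance",
    "to_delta_scale",
]


@dataclass
class ConcordancePair:
    label: str
    predicted_ln_kd: float
    measured_ln_kd: float


@dataclass
class ConcordanceReport:
    n: int
    pearson_r: float
    spearman_r: float
    kendall_tau: float
    gk_gamma: float
    p_values: dict[str, float] = field(default_factory=dict)


def _as_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        x, y = pairs
    else:
        x = [p.predicted_ln_kd for p in pairs]
        y = [p.measured_ln_kd for p in pairs]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-d coordinate arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("coordinates must be finite")
    return x, y


def _concordant_discordant(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    C = D = 0
    n = len(x)
    for i in range(n):
        dx = x[i + 1 :] - x[i]
        dy = y[i + 1 :] - y[i]
        s = np.sign(dx) * np.sign(dy)
        C += int((s > 0).sum())
        D += int((s < 0).sum())
    return C, D


def gk_gamma(pairs) -> float:
    """Goodman-Kruskal gamma: (C - D) / (C + D) over unordered pair-of-pairs,
    ties excluded; 0 when no untied pair exists."""
    x, y = _as_xy(pairs)
    if len(x) < 2:
        raise ValueError("gamma needs at least 2 points")
    C, D = _concordant_discordant(x, y)
    if C + D == 0:
        return 0.0
    return (C - D) / (C + D)


def compute_concordance(
    pairs, n_permutations: int = 10_000, seed: int = 0
) -> ConcordanceReport:
    """All four statistics with their p-values.

    Pearson/Spearman/Kendall p-values come from their standard null
    approximations; gamma's from a seeded permutation of the measured
    coordinate.  Gamma's permutation distribution is coarse and tie-rich at
    small n, so the mid-p convention (ties counted at half weight) is used:
    it keeps the null p-value distribution close to uniform where the plain
    counting estimator is visibly conservative.
    """
    x, y = _as_xy(pairs)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a coordinate; statistics undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    kt = stats.kendalltau(x, y, variant="b")
    g = gk_gamma((x, y))
    rng = np.random.default_rng(seed)
    strict = ties = 0
    for _ in range(n_permutations):
        gp = abs(gk_gamma((x, rng.permutation(y))))
        if gp > abs(g) + 1e-12:
            strict += 1
        elif abs(gp - abs(g)) <= 1e-12:
            ties += 1
    g_p = min((strict + 0.5 * (ties + 1)) / (1 + n_permutations), 1.0)
    return ConcordanceReport(
        n=n,
        pearson_r=float(pr.statistic),
        spearman_r=float(sr.statistic),
        kendall_tau=float(kt.statistic),
        gk_gamma=float(g),
        p_values={
            "pearson_r": float(pr.pvalue),
            "spearman_r": float(sr.pvalue),
            "kendall_tau": float(kt.pvalue),
            "gk_gamma": float(g_p),
        },
    )


def to_delta_scale(
    by_snp: dict[str, dict[str, ConcordancePair]]
) -> list[ConcordancePair]:
    """Collapse per-allele pairs to per-SNP (minor - ancestral) differences.

    ``by_snp`` maps snp_id -> {'wt': pair, 'min': pair}; SNPs missing an
    allele are skipped with a warning.
    """
    out: list[ConcordancePair] = []
    for snp_id, alleles in by_snp.items():
        if "wt" not in alleles or "min" not in alleles:
            warnings.warn(f"SNP {snp_id}: missing an allele, skipped on delta scale")
            continue
        wt, mn = alleles["wt"], alleles["min"]
        out.append(
            ConcordancePair(
                label=snp_id,
                predicted_ln_kd=mn.predicted_ln_kd - wt.predicted_ln_kd,
                measured_ln_kd=mn.measured_ln_kd - wt.measured_ln_kd,
            )
        )
    return out
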