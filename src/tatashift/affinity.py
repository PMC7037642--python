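"""Three-step TBP-promoter binding affinity model.

TBP binding to a proximal promoter is scored as the superposition of three
steps observed for the TBP-DNA association pathway: (1) one-dimensional
sliding of TBP along the duplex, (2) sequence recognition when TBP stops at a
TATA-like site, and (3) fixation of the complex by the ~90 degree DNA bend.
Each W-long window of the input sequence receives

    ln K_D(window) = b0 + b1 * slide + b2 * recognition + b3 * bend

where *slide* and *bend* are means of dinucleotide-step tables over the W-1
steps of the window, and *recognition* is the log-odds position-weight-matrix
score of the window.  The promoter estimate is governed by its single best
(lowest ln K_D) site: the minimum over all windows, leftmost on ties.  The
standard error attached to every estimate is the regression residual sigma of
the calibration that produced the coefficients.

All numeric content (step tables, PWM, coefficients, residual sigma) lives in
:class:`AffinityModelParams` and is replaceable; :func:`calibrate_model` fits
the four coefficients against observed dissociation constants.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AffinityModelParams",
    "AffinityEstimate",
    "DINUCLEOTIDES",
    "sliding_term",
    "recognition_term",
    "bending_term",
    "window_lnkd",
    "estimate_affinity",
    "calibrate_model",
    "pwm_counts_to_logodds",
    "pwm_consensus",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DINUCLEOTIDES = ["".join(p) for p in itertools.product(BASES, repeat=2)]


@dataclass
class AffinityModelParams:
    """Numeric content of the three-step model.

    slide_table / bend_table: dinucleotide-step contributions (16 entries).
    pwm: (W, 4) log-odds weights, columns in A,C,G,T order.
    coeffs: (b0, b1, b2, b3) combining intercept, sliding, recognition, bend.
    residual_se: sigma of the calibration residuals, ln-nM units.
    """

    slide_table: dict[str, float]
    pwm: np.ndarray
    bend_table: dict[str, float]
    coeffs: tuple[float, float, float, float]
    residual_se: float
    window_len: int = 15

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        for name, table in (("slide_table", self.slide_table),
                            ("bend_table", self.bend_table)):
            missing = [d for d in DINUCLEOTIDES if d not in table]
            if missing:
                raise ValueError(f"{name} lacks dinucleotides {missing}")
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must have shape (window_len, 4)")
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if self.pwm.shape[0] != self.window_len:
            raise ValueError(
                f"pwm width {self.pwm.shape[0]} != window_len {self.window_len}"
            )
        if not self.residual_se > 0:
            raise ValueError("residual_se must be positive")
        self.coeffs = tuple(float(c) for c in self.coeffs)
        if len(self.coeffs) != 4:
            raise ValueError("coeffs must be (b0, b1, b2, b3)")


@dataclass
class AffinityEstimate:
    """ln K_D (ln-nM) of the governing site, with its standard error."""

    ln_kd: float
    se: float
    best_window_start: int
    component_scores: tuple[float, float, float]  # (slide, recognition, bend)

    @property
    def kd_nm(self) -> float:
        return math.exp(self.ln_kd)


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"non-ACGT base {e.args[0]!r} in sequence") from None


def sliding_term(window: str, slide_table: dict[str, float]) -> float:
    """Mean sliding contribution over the W-1 dinucleotide steps."""
    if len(window) < 2:
        raise ValueError("window must be at least 2 nt for dinucleotide steps")
    window = window.upper()
    _encode(window)  # validates alphabet
    steps = [slide_table[window[i : i + 2]] for i in range(len(window) - 1)]
    return float(np.mean(steps))


def recognition_term(window: str, pwm: np.ndarray) -> float:
    """Log-odds PWM score: sum of the observed base's weight per position."""
    pwm = np.asarray(pwm, dtype=float)
    if len(window) != pwm.shape[0]:
        raise ValueError(
            f"window length {len(window)} != pwm width {pwm.shape[0]}"
        )
    idx = _encode(window)
    return float(pwm[np.arange(len(window)), idx].sum())


def bending_term(window: str, bend_table: dict[str, float]) -> float:
    """Mean bend-propensity contribution over the W-1 dinucleotide steps."""
    return sliding_term(window, bend_table)


def window_lnkd(window: str, params: AffinityModelParams) -> float:
    """ln K_D of a single window under the three-step decomposition."""
    b0, b1, b2, b3 = params.coeffs
    return (
        b0
        + b1 * sliding_term(window, params.slide_table)
        + b2 * recognition_term(window, params.pwm)
        + b3 * bending_term(window, params.bend_table)
    )


def _component_matrix(seq: str, params: AffinityModelParams) -> np.ndarray:
    """(n_windows, 3) slide/recognition/bend scores for every window of seq."""
    W = params.window_len
    idx = _encode(seq)
    n = len(seq) - W + 1
    if n < 1:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than window_len {W}"
        )
    step_idx = idx[:-1] * 4 + idx[1:]
    slide_vals = np.array([params.slide_table[d] for d in DINUCLEOTIDES])[step_idx]
    bend_vals = np.array([params.bend_table[d] for d in DINUCLEOTIDES])[step_idx]
    # rolling means over W-1 steps via cumulative sums
    cs_slide = np.concatenate(([0.0], np.cumsum(slide_vals)))
    cs_bend = np.concatenate(([0.0], np.cumsum(bend_vals)))
    slide = (cs_slide[W - 1 :][: n] - cs_slide[: n]) / (W - 1)
    bend = (cs_bend[W - 1 :][: n] - cs_bend[: n]) / (W - 1)
    # recognition via explicit windowed sum (W small, n modest)
    base_w = np.take_along_axis(
        np.broadcast_to(params.pwm, (n, W, 4)),
        np.lib.stride_tricks.sliding_window_view(idx, W)[..., None],
        axis=2,
    )[..., 0]
    recog = base_w.sum(axis=1)
    return np.column_stack([slide, recog, bend])


def estimate_affinity(seq: str, params: AffinityModelParams) -> AffinityEstimate:
    """Best-site ln K_D over all windows of ``seq`` (leftmost argmin)."""
    comps = _component_matrix(seq, params)
    b0, b1, b2, b3 = params.coeffs
    lnkd = b0 + comps @ np.array([b1, b2, b3])
    best = int(np.argmin(lnkd))  # np.argmin returns the leftmost minimum
    return AffinityEstimate(
        ln_kd=float(lnkd[best]),
        se=params.residual_se,
        best_window_start=best,
        component_scores=tuple(float(x) for x in comps[best]),
    )


def calibrate_model(
    pairs: list[tuple[str, float]],
    base_params: AffinityModelParams,
    max_iter: int = 50,
    se_floor: float = 1e-6,
) -> AffinityModelParams:
    """Fit (b0..b3) by least squares against observed K_D values (nM).

    The component tables of ``base_params`` stay fixed; only the combining
    coefficients and the residual sigma are re-estimated.  Because the
    governing window depends on the coefficients, the argmin assignment and
    the regression are alternated until the assignment is stable (or
    ``max_iter`` rounds).
    """
    if len(pairs) < 8:
        raise ValueError(f"need at least 8 calibration pairs, got {len(pairs)}")
    y = np.log([kd for _, kd in pairs])
    if np.any(~np.isfinite(y)):
        raise ValueError("observed K_D values must be positive finite")
    comp_all = [_component_matrix(seq, base_params) for seq, _ in pairs]

    params = base_params
    assign = None
    for _ in range(max_iter):
        b0, b1, b2, b3 = params.coeffs
        w = np.array([b1, b2, b3])
        new_assign = [int(np.argmin(b0 + c @ w)) for c in comp_all]
        if new_assign == assign:
            break
        assign = new_assign
        X = np.column_stack(
            [np.ones(len(pairs))]
            + [np.array([c[a, j] for c, a in zip(comp_all, assign)]) for j in range(3)]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient calibration design; a component score is "
                "constant across pairs -- refit with fewer free coefficients"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(pairs) - X.shape[1], 1)
        sigma = max(float(np.sqrt(resid @ resid / dof)), se_floor)
        params = replace(params, coeffs=tuple(beta), residual_se=sigma)
    return params


def pwm_counts_to_logodds(
    counts: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    """Base-count matrix -> log-odds against a uniform background."""
    counts = np.asarray(counts, dtype=float)
    freq = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return np.log(freq / 0.25)


def pwm_consensus(pwm: np.ndarray) -> str:
    """Per-column argmax string of a weight matrix."""
    return "".join(BASES[i] for i in np.asarray(pwm).argmax(axis=1))
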