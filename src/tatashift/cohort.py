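"""Synthetic promoter/SNP cohorts with known ground truth.

Emulates the shape of the study's inputs without any database access: 70 bp
proximal promoters with a TATA-like site planted where clinically relevant
TBP-site SNPs cluster (TSS-relative -50..-20), point mutations placed inside
or outside the site with a controllable split of affinity-raising vs
affinity-lowering minor alleles, and noisy pseudo-measurements of ln K_D.
The three-step affinity model itself provides the truth labels, so every
downstream stage (comparator, counts, pattern statistics, concordance) can
be checked against known generating proportions.

What this does NOT emulate: linkage structure, allele frequencies, database
ascertainment, or any sequence composition beyond a uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affinity import (
    AffinityModelParams,
    estimate_affinity,
    pwm_consensus,
)
from .records import SnpContextRecord

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "plant_tata_promoter",
    "simulate_snp_cohort",
    "simulate_measurements",
]

BASES = "ACGT"

# site placement window, TSS-relative (clinical TBP-site SNPs sit at -51..-20)
SITE_WINDOW = (-50, -20)

FLANK = 10  # printed context width on each side of the variant


@dataclass
class CohortSpec:
    """Generating conditions for one synthetic cohort."""

    n_snps: int
    promoter_len: int = 70
    planted_site_strength: float = 0.85
    prop_affinity_up: float = 0.5
    in_site_fraction: float = 0.5
    measurement_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_site_strength", "prop_affinity_up", "in_site_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth for one simulated SNP."""

    promoter: str
    position: int          # 0-based index of the mutated base
    in_site: bool
    ref: str
    alt: str
    ln_kd_wt: float
    ln_kd_min: float

    @property
    def affinity_up(self) -> bool:
        """True when the minor allele increases TBP affinity (K_D falls)."""
        return self.ln_kd_min < self.ln_kd_wt

    @property
    def direction(self) -> str:
        """'up', 'down' or 'equal'.  Mutations outside the governing window
        leave the best-site minimum untouched, so 'equal' is a real outcome,
        not an artefact."""
        if self.ln_kd_min < self.ln_kd_wt:
            return "up"
        if self.ln_kd_min > self.ln_kd_wt:
            return "down"
        return "equal"


def plant_tata_promoter(
    spec: CohortSpec, rng: np.random.Generator, params: AffinityModelParams
) -> tuple[str, int, int]:
    """A uniform-background promoter with one planted TATA-like site.

    Returns (sequence, site_start, site_end) with 0-based half-open site
    coordinates.  Each site position matches the PWM consensus with
    probability ``planted_site_strength``, otherwise it is a uniform draw.
    """
    W = params.window_len
    L = spec.promoter_len
    if L < W + 2:
        raise ValueError(f"promoter length {L} too short for a {W} nt site")
    seq = list(rng.choice(list(BASES), size=L))
    consensus = pwm_consensus(params.pwm)
    # site fully inside the TSS-relative placement window, clipped to the
    # promoter; TSS-relative position p maps to index L + p
    lo = max(L + SITE_WINDOW[0], 0)
    hi = min(L + SITE_WINDOW[1], L) - W
    if hi < lo:
        lo, hi = 0, L - W
    start = int(rng.integers(lo, hi + 1))
    for i, base in enumerate(consensus):
        if rng.random() < spec.planted_site_strength:
            seq[start + i] = base
    return "".join(seq), start, start + W


def _try_realise(
    promoter: str,
    positions: list[int],
    want_up: bool,
    rng: np.random.Generator,
    params: AffinityModelParams,
    ln_kd_wt: float,
    max_positions: int = 12,
) -> tuple[int, str, float]:
    """Scan shuffled candidate positions for a base change realising the
    wanted direction; falls back to the last mutation tried."""
    order = list(positions)
    rng.shuffle(order)
    pos = alt = lnkd = None
    for p in order[:max_positions]:
        alts = [b for b in BASES if b != promoter[p]]
        rng.shuffle(alts)
        for cand in alts:
            mutated = promoter[:p] + cand + promoter[p + 1 :]
            cand_lnkd = estimate_affinity(mutated, params).ln_kd
            pos, alt, lnkd = p, cand, cand_lnkd
            if (cand_lnkd < ln_kd_wt) == want_up and cand_lnkd != ln_kd_wt:
                return pos, alt, lnkd
    return pos, alt, lnkd


def simulate_snp_cohort(
    spec: CohortSpec, params: AffinityModelParams
) -> list[tuple[SnpContextRecord, CohortTruth]]:
    """Simulate ``spec.n_snps`` single-base variants with truth labels.

    Each SNP gets its own promoter; the mutated position falls inside the
    planted site with probability ``in_site_fraction``; the alt base is
    chosen to raise affinity with probability ``prop_affinity_up`` (when no
    base can realise the wanted direction, the realised direction is kept
    and recorded truthfully).
    """
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[SnpContextRecord, CohortTruth]] = []
    for i in range(spec.n_snps):
        promoter, s0, s1 = plant_tata_promoter(spec, rng, params)
        L = len(promoter)
        in_site = bool(rng.random() < spec.in_site_fraction)
        want_up = bool(rng.random() < spec.prop_affinity_up)
        ln_kd_wt = estimate_affinity(promoter, params).ln_kd
        # keep FLANK nt of context on both sides of the variant
        if in_site:
            cand = [p for p in range(s0, s1) if FLANK <= p < L - FLANK]
        else:
            cand = [
                p for p in range(FLANK, L - FLANK) if not (s0 <= p < s1)
            ]
        pos, alt, ln_kd_min = _try_realise(
            promoter, cand, want_up, rng, params, ln_kd_wt
        )
        ref = promoter[pos]
        truth = CohortTruth(
            promoter=promoter,
            position=pos,
            in_site=s0 <= pos < s1,
            ref=ref,
            alt=alt,
            ln_kd_wt=ln_kd_wt,
            ln_kd_min=ln_kd_min,
        )
        record = SnpContextRecord(
            gene=f"SYN{i:04d}",
            snp_id=f"syn{i:04d}",
            flank5=promoter[pos - FLANK : pos],
            wt_allele=ref,
            min_alleles=[alt],
            flank3=promoter[pos + 1 : pos + 1 + FLANK],
        )
        out.append((record, truth))
    return out


def simulate_measurements(
    true_ln_kd, noise_sd: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Pseudo-measured ln K_D: i.i.d. Gaussian noise on the ln scale."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    true_ln_kd = np.asarray(true_ln_kd, dtype=float)
    return true_ln_kd + rng.normal(0.0, noise_sd, size=true_ln_kd.shape)
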