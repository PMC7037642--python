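"""Gene-level mapping from expression change to atherogenesis direction.

A curated rule per gene states what over- and under-expression do to
atherogenesis (accelerate, decelerate, or unknown).  A significant allele
comparison joined to its gene's rule yields a candidate marker with an
atherogenesis direction; non-significant comparisons and genes without a
rule stay unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .comparator import AlleleComparison

__all__ = [
    "GeneDirectionRule",
    "CandidateMarker",
    "MarkerCounts",
    "load_direction_rules",
    "classify_marker",
    "summarize_counts",
]

_DIRECTIONS = ("accel", "decel", "unknown")


@dataclass
class GeneDirectionRule:
    gene: str
    on_overexpression: str
    on_underexpression: str
    citation: str = ""

    def __post_init__(self) -> None:
        for d in (self.on_overexpression, self.on_underexpression):
            if d not in _DIRECTIONS:
                raise ValueError(f"direction must be one of {_DIRECTIONS}, got {d!r}")
        if self.on_overexpression == "unknown" and self.on_underexpression == "unknown":
            raise ValueError(f"rule for {self.gene} has no known direction")


@dataclass
class CandidateMarker:
    comparison: AlleleComparison
    gene: str
    as_direction: str  # 'accel' | 'decel' | 'unclassified'


@dataclass
class MarkerCounts:
    """Per-set marker tallies in the layout of the summary table."""

    set_label: str
    n_gt: int = 0        # expression increase, K_D falls
    n_lt: int = 0        # expression decrease, K_D rises
    n_eq: int = 0
    n_up: int = 0        # atherogenesis accelerated
    n_dn: int = 0        # atherogenesis slowed
    unclassified: int = 0
    n_gene: int | None = None
    n_snp: int | None = None
    n_res: int | None = None

    def __post_init__(self) -> None:
        if self.n_res is None:
            self.n_res = self.n_gt + self.n_lt + self.n_eq


def load_direction_rules(source) -> dict[str, GeneDirectionRule]:
    """Read a rules TSV (gene, on_over, on_under, citation) into a map."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    rules: dict[str, GeneDirectionRule] = {}
    for _, row in df.iterrows():
        rule = GeneDirectionRule(
            gene=row["gene"].strip(),
            on_overexpression=row["on_over"].strip(),
            on_underexpression=row["on_under"].strip(),
            citation="" if pd.isna(row.get("citation")) else str(row["citation"]),
        )
        prev = rules.get(rule.gene)
        if prev is not None and (
            prev.on_overexpression != rule.on_overexpression
            or prev.on_underexpression != rule.on_underexpression
        ):
            raise ValueError(f"conflicting duplicate rules for gene {rule.gene}")
        rules[rule.gene] = rule
    return rules


def classify_marker(
    cmp: AlleleComparison, rules: dict[str, GeneDirectionRule]
) -> CandidateMarker:
    """Join a comparison to its gene rule.

    Delta '>' consults the over-expression direction, '<' the
    under-expression one; rank-E (non-significant) or '=' comparisons and
    genes without a rule are 'unclassified' (with a warning for the latter).
    """
    gene = cmp.gene or ""
    if cmp.rank == "E" or cmp.delta == "=":
        return CandidateMarker(cmp, gene, "unclassified")
    rule = rules.get(gene)
    if rule is None:
        warnings.warn(f"no direction rule for gene {gene!r}; marker unclassified")
        return CandidateMarker(cmp, gene, "unclassified")
    direction = (
        rule.on_overexpression if cmp.delta == ">" else rule.on_underexpression
    )
    if direction == "unknown":
        direction = "unclassified"
    return CandidateMarker(cmp, gene, direction)


def summarize_counts(
    markers: list[CandidateMarker], set_label: str = ""
) -> MarkerCounts:
    """Tally expression-direction and atherogenesis-direction counts."""
    c = MarkerCounts(set_label=set_label)
    for m in markers:
        if m.comparison.delta == ">":
            c.n_gt += 1
        elif m.comparison.delta == "<":
            c.n_lt += 1
        else:
            c.n_eq += 1
        if m.as_direction == "accel":
            c.n_up += 1
        elif m.as_direction == "decel":
            c.n_dn += 1
        else:
            c.unclassified += 1
    c.n_res = c.n_gt + c.n_lt + c.n_eq
    return c
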