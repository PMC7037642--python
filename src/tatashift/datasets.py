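"""Accessors for the packaged data: marker fixture, gene rules, summary-table
reference counts, and the default affinity-model parameters."""

from __future__ import annotations

import tomllib
from importlib import resources

import numpy as np
import pandas as pd

from .affinity import AffinityModelParams, pwm_counts_to_logodds
from .annotation import GeneDirectionRule, MarkerCounts, load_direction_rules
from .records import SnpContextRecord, parse_context_table

__all__ = [
    "load_deletion_notes",
    "load_marker_records",
    "load_gene_rules",
    "load_table1_reference",
    "default_params",
    "load_dinucleotide_table",
]


def _path(name: str):
    return resources.files("tatashift").joinpath("data", name)


def load_deletion_notes() -> dict[str, str]:
    df = pd.read_csv(_path("deletion_notes.tsv"), sep="\t", comment="#")
    return dict(zip(df["key"], df["sequence"]))


def load_marker_records() -> list[SnpContextRecord]:
    """All data rows of the study's marker tables (238 records)."""
    with _path("atherogenesis_markers.tsv").open() as fh:
        return parse_context_table(fh, load_deletion_notes())


def load_gene_rules() -> dict[str, GeneDirectionRule]:
    with _path("gene_direction_rules.tsv").open() as fh:
        return load_direction_rules(fh)


def load_table1_reference() -> list[MarkerCounts]:
    """The summary table's printed per-set count cells, as MarkerCounts."""
    df = pd.read_csv(
        _path("table1_reference.tsv"), sep="\t", comment="#", na_values=["-"]
    )
    out = []
    for _, r in df.iterrows():
        def _i(col):
            return None if pd.isna(r[col]) else int(r[col])

        out.append(
            MarkerCounts(
                set_label=str(r["set"]),
                n_gt=_i("n_gt") or 0,
                n_lt=_i("n_lt") or 0,
                n_up=_i("n_up") or 0,
                n_dn=_i("n_dn") or 0,
                n_gene=_i("n_gene"),
                n_snp=_i("n_snp"),
                n_res=_i("n_res"),
            )
        )
    return out


def load_dinucleotide_table(name: str) -> dict[str, float]:
    df = pd.read_csv(_path(name), sep="\t", comment="#")
    return dict(zip(df["dinucleotide"], df["value"].astype(float)))


def default_params() -> AffinityModelParams:
    """The shipped three-step model: TATA PWM, step tables, default coeffs."""
    with _path("model_defaults.toml").open("rb") as fh:
        cfg = tomllib.load(fh)["model"]
    counts = pd.read_csv(_path("tbp_pwm_counts.tsv"), sep="\t", comment="#")
    pwm = pwm_counts_to_logodds(
        np.asarray(counts[["A", "C", "G", "T"]], dtype=float),
        pseudocount=cfg["pwm_pseudocount"],
    )
    return AffinityModelParams(
        slide_table=load_dinucleotide_table("slide_dinucleotides.tsv"),
        pwm=pwm,
        bend_table=load_dinucleotide_table("bend_dinucleotides.tsv"),
        coeffs=(cfg["b0"], cfg["b1"], cfg["b2"], cfg["b3"]),
        residual_se=cfg["residual_se"],
        window_len=cfg["window_len"],
    )
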