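"""End-to-end batch stages: context table -> marker table -> pattern table.

Wires the stages together deterministically: parse records, materialise
per-allele sequences, estimate both alleles' ln K_D, compare with the Fisher
Z-test, classify against the gene rules, and tally per-set counts for the
selection-pattern statistics.  Each printed table row is one marker: rows
listing several minor alleles are evaluated per allele and reported at row
granularity (first allele), matching the tables' own bookkeeping; set
``per_allele=True`` for one output row per expanded allele.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import datasets
from .affinity import AffinityModelParams, calibrate_model, estimate_affinity
from .annotation import (
    CandidateMarker,
    GeneDirectionRule,
    MarkerCounts,
    classify_marker,
    summarize_counts,
)
from .cohort import CohortSpec, simulate_measurements, simulate_snp_cohort
from .comparator import alpha_label, fisher_z_compare
from .concordance import ConcordancePair, ConcordanceReport, compute_concordance
from .patterns import build_pattern_table
from .records import (
    SnpContextRecord,
    build_allele_sequences,
    expand_minor_alleles,
    parse_context_table,
    records_to_frame,
)

__all__ = [
    "run_batch",
    "run_patterns",
    "run_validate",
    "run_simulate",
    "run_calibrate",
    "markers_from_records",
]

MARKER_COLUMNS = [
    "set", "gene", "snp_id", "kd_wt_nM", "kd_min_nM", "delta", "z",
    "alpha", "rank", "decision", "as_direction",
]


def markers_from_records(
    records: list[SnpContextRecord],
    params: AffinityModelParams,
    rules: dict[str, GeneDirectionRule],
    per_allele: bool = False,
) -> list[CandidateMarker]:
    """Estimate, compare and classify every record.

    Returns one marker per record (its first minor allele) unless
    ``per_allele`` asks for one marker per expanded allele.
    """
    markers: list[CandidateMarker] = []
    for rec in records:
        expanded = expand_minor_alleles(rec)
        chosen = expanded if per_allele else expanded[:1]
        for sub in chosen:
            wt_seq, min_seq = build_allele_sequences(sub)
            est_wt = estimate_affinity(wt_seq, params)
            est_min = estimate_affinity(min_seq, params)
            cmp = fisher_z_compare(est_wt, est_min, snp_id=sub.snp_id, gene=sub.gene)
            markers.append(classify_marker(cmp, rules))
    return markers


def _marker_frame(
    markers: list[CandidateMarker], records: list[SnpContextRecord] | None = None
) -> pd.DataFrame:
    sets = {r.snp_id: r.table_set for r in records or []}
    rows = []
    for m in markers:
        c = m.comparison
        rows.append(
            {
                "set": sets.get(c.snp_id.split(":")[0], sets.get(c.snp_id)),
                "gene": m.gene,
                "snp_id": c.snp_id,
                "kd_wt_nM": float(np.exp(c.ln_kd_wt)),
                "kd_min_nM": float(np.exp(c.ln_kd_min)),
                "delta": c.delta,
                "z": c.z,
                "alpha": alpha_label(c.alpha_bin),
                "rank": c.rank,
                "decision": c.decision,
                "as_direction": m.as_direction,
            }
        )
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def run_batch(
    context,
    params: AffinityModelParams | None = None,
    rules: dict[str, GeneDirectionRule] | None = None,
    deletion_notes: dict[str, str] | None = None,
    per_allele: bool = False,
) -> pd.DataFrame:
    """Context table (path/stream or parsed records) -> marker table."""
    if params is None:
        params = datasets.default_params()
    if rules is None:
        rules = datasets.load_gene_rules()
    if isinstance(context, list):
        records = context
    else:
        if deletion_notes is None:
            deletion_notes = datasets.load_deletion_notes()
        records = parse_context_table(context, deletion_notes)
    markers = markers_from_records(records, params, rules, per_allele=per_allele)
    return _marker_frame(markers, records)


def run_patterns(counts: list[MarkerCounts]) -> pd.DataFrame:
    """Counts rows -> summary-table-style pattern statistics."""
    return build_pattern_table(counts)


def counts_from_marker_frame(df: pd.DataFrame, by: str = "set") -> list[MarkerCounts]:
    """Tally a marker table into per-set MarkerCounts rows."""
    out = []
    for label, grp in df.groupby(by, dropna=False):
        c = MarkerCounts(set_label=str(label))
        c.n_gt = int((grp["delta"] == ">").sum())
        c.n_lt = int((grp["delta"] == "<").sum())
        c.n_eq = int((grp["delta"] == "=").sum())
        c.n_up = int((grp["as_direction"] == "accel").sum())
        c.n_dn = int((grp["as_direction"] == "decel").sum())
        c.unclassified = int((grp["as_direction"] == "unclassified").sum())
        c.n_res = len(grp)
        c.n_gene = int(grp["gene"].nunique())
        out.append(c)
    return out


def run_validate(
    pairs_df: pd.DataFrame, n_permutations: int = 10_000, seed: int = 0
) -> dict[str, ConcordanceReport]:
    """Predicted-vs-measured concordance on absolute and difference scales.

    ``pairs_df`` columns: snp_id, allele ('wt'|'min'), predicted_ln_kd,
    measured_ln_kd.  Returns reports keyed 'absolute' and 'delta'.
    """
    pairs = [
        ConcordancePair(
            label=f"{r.snp_id}:{r.allele}",
            predicted_ln_kd=float(r.predicted_ln_kd),
            measured_ln_kd=float(r.measured_ln_kd),
        )
        for r in pairs_df.itertuples()
    ]
    by_snp: dict[str, dict[str, ConcordancePair]] = {}
    for r, p in zip(pairs_df.itertuples(), pairs):
        by_snp.setdefault(str(r.snp_id), {})[str(r.allele)] = p
    from .concordance import to_delta_scale

    reports = {
        "absolute": compute_concordance(pairs, n_permutations, seed),
    }
    deltas = to_delta_scale(by_snp)
    if len(deltas) >= 3:
        reports["delta"] = compute_concordance(deltas, n_permutations, seed + 1)
    return reports


def run_simulate(
    spec: CohortSpec, params: AffinityModelParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (context, truth, measurements) tables."""
    if params is None:
        params = datasets.default_params()
    cohort = simulate_snp_cohort(spec, params)
    context = records_to_frame([rec for rec, _ in cohort])
    truth = pd.DataFrame(
        {
            "snp_id": [rec.snp_id for rec, _ in cohort],
            "position": [t.position for _, t in cohort],
            "in_site": [t.in_site for _, t in cohort],
            "affinity_up": [t.affinity_up for _, t in cohort],
            "ln_kd_wt": [t.ln_kd_wt for _, t in cohort],
            "ln_kd_min": [t.ln_kd_min for _, t in cohort],
        }
    )
    rng = np.random.default_rng(spec.seed + 1)
    meas_rows = []
    for rec, t in cohort:
        for allele, true_val in (("wt", t.ln_kd_wt), ("min", t.ln_kd_min)):
            meas_rows.append(
                {
                    "snp_id": rec.snp_id,
                    "allele": allele,
                    "predicted_ln_kd": true_val,
                    "measured_ln_kd": float(
                        simulate_measurements([true_val], spec.measurement_noise_sd, rng)[0]
                    ),
                }
            )
    return context, truth, pd.DataFrame(meas_rows)


def run_calibrate(
    records: list[SnpContextRecord] | None = None,
    base_params: AffinityModelParams | None = None,
    which: str = "wt",
) -> AffinityModelParams:
    """Calibrate the combining coefficients against printed K_D columns.

    By default fits the WT rows of the packaged marker tables: sequence =
    flank5+wt+flank3, response = printed WT K_D.
    """
    if records is None:
        records = datasets.load_marker_records()
    if base_params is None:
        base_params = datasets.default_params()
    pairs = []
    for rec in records:
        sub = expand_minor_alleles(rec)[0]
        wt_seq, min_seq = build_allele_sequences(sub)
        if which in ("wt", "both") and rec.kd_wt is not None:
            pairs.append((wt_seq, rec.kd_wt))
        if which in ("min", "both") and rec.kd_min is not None:
            pairs.append((min_seq, rec.kd_min))
    return calibrate_model(pairs, base_params)
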