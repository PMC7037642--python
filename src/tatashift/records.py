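"""SNP context records and promoter/variant plumbing.

The unit of input is one row of a marker context table: a gene symbol, an SNP
identifier, the ancestral (WT) and minor alleles, and the printed 10-nt
flanking context on each side.  Deletion alleles are written either as ``-``
(the allele contributes no bases) or as a ``<n>bp`` shorthand that is resolved
against a notes map (the tables' footnotes).  Per-allele DNA sequences are
materialised by concatenating ``flank5 + allele + flank3``.

Coordinates for whole-promoter editing are TSS-relative: position -1 is the
base immediately 5' of the transcription start; there is no position 0.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "SnpContextRecord",
    "PromoterVariant",
    "parse_context_table",
    "write_context_table",
    "records_to_frame",
    "expand_minor_alleles",
    "build_allele_sequences",
    "apply_variant_to_promoter",
    "read_promoters_fasta",
    "read_variants_tsv",
    "read_variants_vcf",
]

_DNA_RE = re.compile(r"^[ACGT]+$")
_SHORTHAND_RE = re.compile(r"^(\d+)bp$")

REQUIRED_COLUMNS = ("gene", "snp_id", "flank5", "wt", "min", "flank3")
OPTIONAL_COLUMNS = ("kd_wt", "kd_min", "delta", "z", "alpha", "rank", "as", "set")


class ContextParseError(ValueError):
    """Raised when a context-table row cannot be interpreted."""


def _check_dna(s: str, what: str, row: str) -> str:
    s = s.strip().upper()
    if not _DNA_RE.match(s):
        raise ContextParseError(
            f"{what} {s!r} in row {row!r} contains non-ACGT characters"
        )
    return s


@dataclass
class SnpContextRecord:
    """One row of a marker context table.

    ``wt_allele`` and entries of ``min_alleles`` are uppercase DNA strings or
    ``"-"`` for a deletion allele.  The printed annotation columns (K_D pair,
    expression-change symbol, significance, rank, atherogenesis direction)
    are optional and carried verbatim.
    """

    gene: str
    snp_id: str
    flank5: str
    wt_allele: str
    min_alleles: list[str]
    flank3: str
    kd_wt: float | None = None
    kd_min: float | None = None
    delta: str | None = None          # '>' or '<'
    z: float | None = None
    alpha: float | None = None        # printed significance bin
    rank: str | None = None           # 'A'..'E'
    as_direction: str | None = None   # 'accel' or 'decel'
    other_neutral_alleles: bool = False
    table_set: str | None = None

    def __post_init__(self) -> None:
        self.flank5 = _check_dna(self.flank5, "flank5", self.snp_id)
        self.flank3 = _check_dna(self.flank3, "flank3", self.snp_id)
        if self.wt_allele != "-":
            self.wt_allele = _check_dna(self.wt_allele, "wt allele", self.snp_id)
        if not self.min_alleles:
            raise ContextParseError(f"row {self.snp_id!r} has no minor allele")
        self.min_alleles = [
            a if a == "-" else _check_dna(a, "minor allele", self.snp_id)
            for a in self.min_alleles
        ]
        for kd in (self.kd_wt, self.kd_min):
            if kd is not None and not kd > 0:
                raise ContextParseError(
                    f"row {self.snp_id!r}: printed K_D must be positive, got {kd}"
                )


@dataclass
class PromoterVariant:
    """A variant on a TSS-anchored promoter, in TSS-relative coordinates."""

    promoter_id: str
    tss_relative_pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.tss_relative_pos == 0:
            raise ValueError("there is no TSS-relative position 0")
        if self.ref == "-" and self.alt == "-":
            raise ValueError("ref and alt cannot both be '-'")
        if self.ref != "-":
            self.ref = _check_dna(self.ref, "ref", self.promoter_id)
        if self.alt != "-":
            self.alt = _check_dna(self.alt, "alt", self.promoter_id)


def _resolve_allele(
    raw: str,
    deletion_notes: dict[str, str] | None,
    row_id: str,
    gene: str = "",
) -> tuple[str, bool]:
    """Normalise one printed allele; returns (allele, had_star_flag).

    Deletion shorthands are looked up first gene-qualified ("GENE:18bp") and
    then bare ("18bp"), since different genes' footnotes may reuse a length.
    """
    a = raw.strip()
    starred = a.endswith("*")
    a = a.rstrip("*").strip()
    if a == "-":
        return "-", starred
    m = _SHORTHAND_RE.match(a)
    if m:
        seq = (deletion_notes or {}).get(f"{gene}:{a}") or (deletion_notes or {}).get(a)
        if seq is None:
            raise ContextParseError(
                f"row {row_id!r}: deletion shorthand {a!r} has no notes entry"
            )
        return _check_dna(seq, "deletion sequence", row_id), starred
    return _check_dna(a, "allele", row_id), starred


def parse_context_table(
    source, deletion_notes: dict[str, str] | None = None
) -> list[SnpContextRecord]:
    """Read a tab-separated marker context table into records.

    ``source`` is a path or open text stream.  Required columns: gene,
    snp_id, flank5, wt, min, flank3; the printed annotation columns are
    picked up when present.  Trailing ``*`` markers on alleles (the tables'
    "also includes other neutral alleles" footnote) are stripped and kept as
    a flag.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ContextParseError(f"missing required columns: {missing}")
    records: list[SnpContextRecord] = []
    for _, row in df.iterrows():
        row_id = str(row["snp_id"])
        gene = str(row["gene"]).strip()
        wt, wt_star = _resolve_allele(str(row["wt"]), deletion_notes, row_id, gene)
        minors, star = [], wt_star
        for raw in str(row["min"]).split(","):
            a, s = _resolve_allele(raw, deletion_notes, row_id, gene)
            minors.append(a)
            star = star or s

        def _opt(col, conv=float):
            v = row.get(col)
            if v is None or pd.isna(v) or str(v).strip() in ("", "-"):
                return None
            return conv(str(v).strip())

        records.append(
            SnpContextRecord(
                gene=str(row["gene"]).strip(),
                snp_id=row_id,
                flank5=str(row["flank5"]),
                wt_allele=wt,
                min_alleles=minors,
                flank3=str(row["flank3"]),
                kd_wt=_opt("kd_wt"),
                kd_min=_opt("kd_min"),
                delta=_opt("delta", str),
                z=_opt("z"),
                alpha=_opt("alpha"),
                rank=_opt("rank", str),
                as_direction=_opt("as", str),
                other_neutral_alleles=star,
                table_set=_opt("set", str),
            )
        )
    return records


def records_to_frame(records: list[SnpContextRecord]) -> pd.DataFrame:
    """Render records back to the tabular layout used by the parser."""
    rows = []
    for r in records:
        rows.append(
            {
                "set": r.table_set,
                "gene": r.gene,
                "snp_id": r.snp_id,
                "flank5": r.flank5,
                "wt": r.wt_allele,
                "min": ",".join(r.min_alleles) + ("*" if r.other_neutral_alleles else ""),
                "flank3": r.flank3,
                "kd_wt": r.kd_wt,
                "kd_min": r.kd_min,
                "delta": r.delta,
                "z": r.z,
                "alpha": r.alpha,
                "rank": r.rank,
                "as": r.as_direction,
            }
        )
    return pd.DataFrame(rows)


def write_context_table(records: list[SnpContextRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def expand_minor_alleles(record: SnpContextRecord) -> list[SnpContextRecord]:
    """One record per minor allele; ids get a ``:<allele>`` suffix when the
    row lists several minors (mirroring e.g. ``rs966076891:t``)."""
    if len(record.min_alleles) == 1:
        return [record]
    out = []
    for allele in record.min_alleles:
        suffix = allele.lower() if allele != "-" else "-"
        out.append(
            replace(
                record,
                snp_id=f"{record.snp_id}:{suffix}",
                min_alleles=[allele],
            )
        )
    return out


def build_allele_sequences(record: SnpContextRecord) -> tuple[str, str]:
    """Materialise (wt_seq, min_seq) as flank5 + allele + flank3."""
    if len(record.min_alleles) != 1:
        raise ValueError(
            f"record {record.snp_id!r} has {len(record.min_alleles)} minor alleles; "
            "expand_minor_alleles first"
        )
    if len(record.flank5) < 1 or len(record.flank3) < 1:
        raise ValueError(f"record {record.snp_id!r} has an empty flank")
    wt = "" if record.wt_allele == "-" else record.wt_allele
    mn = "" if record.min_alleles[0] == "-" else record.min_alleles[0]
    return record.flank5 + wt + record.flank3, record.flank5 + mn + record.flank3


def apply_variant_to_promoter(seq: str, var: PromoterVariant) -> str:
    """Edit a TSS-anchored promoter sequence (position -1 = last base)."""
    seq = seq.upper()
    L = len(seq)
    pos = var.tss_relative_pos
    if pos >= 0 or -pos > L:
        raise ValueError(
            f"position {pos} outside the promoter (length {L}, upstream positions "
            f"-1..-{L})"
        )
    idx = L + pos
    if var.ref == var.alt:
        return seq
    if var.ref == "-":
        # insertion 5' of the base at `pos`
        return seq[:idx] + var.alt + seq[idx:]
    found = seq[idx : idx + len(var.ref)]
    if found != var.ref:
        raise ValueError(
            f"reference mismatch at {pos}: expected {var.ref!r}, found {found!r}"
        )
    alt = "" if var.alt == "-" else var.alt
    if idx + len(var.ref) > L:
        raise ValueError(f"variant at {pos} runs past the promoter 3' end")
    return seq[:idx] + alt + seq[idx + len(var.ref) :]


def read_promoters_fasta(path) -> dict[str, str]:
    """TSS-anchored promoter sequences keyed by record id (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_variants_tsv(source) -> list[PromoterVariant]:
    """Variants as TSV with columns promoter_id, pos, ref, alt."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    return [
        PromoterVariant(
            promoter_id=str(r["promoter_id"]),
            tss_relative_pos=int(r["pos"]),
            ref=str(r["ref"]),
            alt=str(r["alt"]),
        )
        for _, r in df.iterrows()
    ]


def read_variants_vcf(path, tss_offset: int | None = None) -> list[PromoterVariant]:
    """Minimal VCF: CHROM = promoter id, POS = 1-based position within the
    promoter, converted to TSS-relative coordinates via ``tss_offset`` (the
    1-based POS of the transcription start; defaults to a ``##tss_offset=``
    header line)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if tss_offset is None:
        for line in vcf.raw_header.splitlines():
            if line.startswith("##tss_offset="):
                tss_offset = int(line.split("=", 1)[1])
                break
    if tss_offset is None:
        raise ValueError("tss_offset not given and no ##tss_offset header line")
    out = []
    for v in vcf:
        if v.POS >= tss_offset:
            raise ValueError(
                f"POS {v.POS} at/after the TSS offset {tss_offset}; only "
                "upstream promoter variants are supported"
            )
        for alt in v.ALT:
            ref, a, pos = v.REF, alt, v.POS
            # strip the shared anchor base of VCF-style indels; the edit
            # then starts one base downstream
            if len(ref) != len(a) and ref[:1] == a[:1]:
                ref, a, pos = ref[1:] or "-", a[1:] or "-", pos + 1
            out.append(
                PromoterVariant(
                    promoter_id=v.CHROM,
                    tss_relative_pos=pos - tss_offset,
                    ref=ref,
                    alt=a,
                )
            )
    return out
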