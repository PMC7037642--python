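"""Context-table parsing, allele expansion and promoter editing."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tatashift import datasets
from tatashift.records import (
    ContextParseError,
    PromoterVariant,
    SnpContextRecord,
    apply_variant_to_promoter,
    build_allele_sequences,
    expand_minor_alleles,
    parse_context_table,
    read_promoters_fasta,
    read_variants_tsv,
    read_variants_vcf,
    records_to_frame,
)

HEADER = "gene\tsnp_id\tflank5\twt\tmin\tflank3\n"


def test_parse_resolves_deletion_shorthand():
    tsv = HEADER + "CETP\trs1427119663\tcgtgggggct\t18bp\t-\tgggctccagg\n"
    recs = parse_context_table(tsv, {"18bp": "gggcggacatacatatac"})
    assert len(recs) == 1
    assert len(recs[0].wt_allele) == 18
    assert recs[0].min_alleles == ["-"]


def test_parse_empty_body_gives_empty_list():
    assert parse_context_table(HEADER.rstrip("\n") + "\n") == []


def test_parse_splits_minor_allele_list():
    tsv = HEADER + "CETP\trs569033466\tatacatatac\tg\ta, t, c\tggctccaggc\n"
    (rec,) = parse_context_table(tsv)
    assert rec.min_alleles == ["A", "T", "C"]


def test_parse_star_flag_stripped_and_kept():
    tsv = HEADER + "F3\trs563763767\tccctttatag\tc\tt*\tgcgcggggca\n"
    (rec,) = parse_context_table(tsv)
    assert rec.min_alleles == ["T"]
    assert rec.other_neutral_alleles


@pytest.mark.parametrize(
    "row",
    [
        "X\tr1\tacgtacgtac\t99bp\t-\tacgtacgtac",     # unknown shorthand
        "X\tr2\tacgnacgtac\ta\tg\tacgtacgtac",        # non-ACGT flank
        "X\tr3\tacgtacgtac\ta\tn\tacgtacgtac",        # non-ACGT allele
    ],
)
def test_parse_errors_name_the_row(row):
    with pytest.raises(ContextParseError):
        parse_context_table(HEADER + row + "\n")


def test_roundtrip_fixture_records(marker_records):
    """Writing the packaged tables back to TSV and re-parsing is lossless."""
    frame = records_to_frame(marker_records)
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    again = parse_context_table(buf, datasets.load_deletion_notes())
    assert again == marker_records


def test_expand_minor_alleles_suffixes_ids():
    tsv = HEADER + "CETP\trs569033466\tatacatatac\tg\ta, t, c\tggctccaggc\n"
    (rec,) = parse_context_table(tsv)
    out = expand_minor_alleles(rec)
    assert [r.snp_id for r in out] == [
        "rs569033466:a", "rs569033466:t", "rs569033466:c"
    ]
    single = SnpContextRecord("G", "rs1", "acgtacgtac", "A", ["G"], "acgtacgtac")
    assert expand_minor_alleles(single) == [single]
    deletion = SnpContextRecord("G", "rs2", "acgtacgtac", "A", ["-"], "acgtacgtac")
    assert len(expand_minor_alleles(deletion)) == 1


def test_expand_then_build_total_over_fixture(marker_records):
    """Every packaged record yields valid per-allele sequence pairs."""
    for rec in marker_records:
        for sub in expand_minor_alleles(rec):
            wt, mn = build_allele_sequences(sub)
            assert set(wt) <= set("ACGT") and set(mn) <= set("ACGT")
            assert len(wt) >= 20 and len(mn) >= 20


def test_build_allele_sequences_lengths(marker_records):
    by_id = {r.snp_id: r for r in marker_records}
    wt, mn = build_allele_sequences(by_id["rs1427119663"])  # 18 bp deletion
    assert (len(wt), len(mn)) == (38, 20)
    wt, mn = build_allele_sequences(by_id["rs587778905"])   # 21bp -> taaa
    assert (len(wt), len(mn)) == (41, 24)
    same = SnpContextRecord("G", "rs0", "aacc", "T", ["T"], "ggtt")
    assert build_allele_sequences(same)[0] == build_allele_sequences(same)[1]


def test_apply_variant_substitution_and_identity():
    seq = "A" * 39 + "C" + "A" * 30  # C at TSS-relative -31
    out = apply_variant_to_promoter(seq, PromoterVariant("p", -31, "C", "T"))
    assert len(out) == 70 and out[39] == "T"
    assert out.replace("T", "C", 1).count("C") == 1
    ident = apply_variant_to_promoter(seq, PromoterVariant("p", -31, "C", "C"))
    assert ident == seq


def test_apply_variant_deletion_shortens():
    seq = "ACGT" * 20  # 80-mer
    ref = seq[10:28]   # 18 bases at TSS-relative -70
    out = apply_variant_to_promoter(seq, PromoterVariant("p", -70, ref, "-"))
    assert len(out) == 62
    assert out == seq[:10] + seq[28:]


def test_apply_variant_errors():
    seq = "ACGTACGTAC"
    with pytest.raises(ValueError, match="mismatch"):
        apply_variant_to_promoter(seq, PromoterVariant("p", -1, "A", "G"))
    with pytest.raises(ValueError, match="outside"):
        apply_variant_to_promoter(seq, PromoterVariant("p", -11, "A", "G"))
    with pytest.raises(ValueError):
        PromoterVariant("p", 0, "A", "G")
    with pytest.raises(ValueError):
        PromoterVariant("p", -1, "-", "-")


@settings(max_examples=50, deadline=None)
@given(
    seq=st.text(alphabet="ACGT", min_size=5, max_size=60),
    data=st.data(),
)
def test_substitution_inverse_restores_sequence(seq, data):
    pos = data.draw(st.integers(min_value=-len(seq), max_value=-1))
    alt = data.draw(st.sampled_from("ACGT"))
    ref = seq[len(seq) + pos]
    edited = apply_variant_to_promoter(seq, PromoterVariant("p", pos, ref, alt))
    back = apply_variant_to_promoter(edited, PromoterVariant("p", pos, alt, ref))
    assert back == seq


def test_fasta_tsv_and_vcf_variant_loading(tmp_path):
    """Promoters from FASTA plus variants from TSV or minimal VCF produce
    the same edited sequence."""
    promoter = "A" * 39 + "C" + "A" * 30  # C at TSS-relative -31
    (tmp_path / "prom.fa").write_text(">p1 tss_anchored\n" + promoter + "\n")
    (tmp_path / "vars.tsv").write_text(
        "promoter_id\tpos\tref\talt\np1\t-31\tC\tT\n"
    )
    vcf = (
        "##fileformat=VCFv4.2\n"
        "##tss_offset=71\n"
        "##contig=<ID=p1,length=70>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "p1\t40\trsX\tC\tT\t.\t.\t.\n"
    )
    (tmp_path / "vars.vcf").write_text(vcf)

    proms = read_promoters_fasta(tmp_path / "prom.fa")
    assert proms["p1"] == promoter
    (tsv_var,) = read_variants_tsv(tmp_path / "vars.tsv")
    (vcf_var,) = read_variants_vcf(tmp_path / "vars.vcf")
    assert tsv_var.tss_relative_pos == vcf_var.tss_relative_pos == -31
    edited_a = apply_variant_to_promoter(proms["p1"], tsv_var)
    edited_b = apply_variant_to_promoter(proms["p1"], vcf_var)
    assert edited_a == edited_b
    assert edited_a[39] == "T"


def test_vcf_indel_anchor_stripping(tmp_path):
    promoter = "ACGT" * 10  # 40-mer
    vcf = (
        "##fileformat=VCFv4.2\n"
        "##tss_offset=41\n"
        "##contig=<ID=p1,length=40>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "p1\t4\trsD\tTACG\tT\t.\t.\t.\n"
    )
    (tmp_path / "d.vcf").write_text(vcf)
    (var,) = read_variants_vcf(tmp_path / "d.vcf")
    assert (var.ref, var.alt, var.tss_relative_pos) == ("ACG", "-", -36)
    edited = apply_variant_to_promoter(promoter, var)
    assert len(edited) == 37
    assert edited == promoter[:4] + promoter[7:]
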