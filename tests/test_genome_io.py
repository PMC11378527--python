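"""Unit tests for FASTA/GFF3/domain-table I/O and phase arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrshuffle import (CdsSegment, GenomeSequence, TranscriptModel,
                        extract_cds, next_phase, parse_domtblout,
                        parse_expression_table, parse_fasta, parse_gff3,
                        parse_interpro_tsv, translate_cds,
                        validate_phase_chain, write_fasta, write_gff3)
from lrrshuffle.genome_io import (AlphabetError, FormatError, LinkageError,
                                  MissingPhaseError)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_fasta_roundtrip(tmp_path):
    seqs = [GenomeSequence(id="chr1", residues="ACGTACGTACGTNN"),
            GenomeSequence(id="chr2", residues="TTTT")]
    path = tmp_path / "x.fa"
    write_fasta(seqs, path, width=5)
    back = parse_fasta(path)
    assert [(s.id, s.residues) for s in back] == \
        [(s.id, s.residues) for s in seqs]


def test_fasta_lowercase_uppercased(tmp_path):
    path = tmp_path / "x.fa"
    path.write_text(">s1\nacgt\n")
    assert parse_fasta(path)[0].residues == "ACGT"


def test_fasta_duplicate_id_rejected(tmp_path):
    path = tmp_path / "x.fa"
    path.write_text(">s1\nACGT\n>s1\nTTTT\n")
    with pytest.raises(FormatError):
        parse_fasta(path)


def test_fasta_bad_alphabet(tmp_path):
    path = tmp_path / "x.fa"
    path.write_text(">s1\nACGU\n")
    with pytest.raises(AlphabetError):
        parse_fasta(path)
    assert parse_fasta(path, map_unknown_to_n=True)[0].residues == "ACGN"


def test_fasta_empty_file_rejected(tmp_path):
    path = tmp_path / "x.fa"
    path.write_text("")
    with pytest.raises(FormatError):
        parse_fasta(path)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

TOY_GFF = """##gff-version 3
chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=m1;Parent=g1
chr1\tsrc\texon\t1\t40\t.\t+\t.\tID=e1;Parent=m1
chr1\tsrc\texon\t61\t100\t.\t+\t.\tID=e2;Parent=m1
chr1\tsrc\tCDS\t11\t20\t.\t+\t0\tID=c1;Parent=m1
chr1\tsrc\tCDS\t61\t90\t.\t+\t2\tID=c2;Parent=m1
"""


def test_parse_gff3_toy(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    genes = parse_gff3(path)
    assert len(genes) == 1
    gene = genes[0]
    assert gene.gene_id == "g1" and gene.strand == "+"
    tx = gene.transcripts[0]
    # 1-based inclusive -> 0-based half-open
    assert tx.exons == [(0, 40), (60, 100)]
    assert [(c.start, c.end, c.phase) for c in tx.cds_segments] == \
        [(10, 20, 0), (60, 90, 2)]


def test_parse_gff3_missing_phase(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF.replace("\t0\tID=c1", "\t.\tID=c1"))
    with pytest.raises(MissingPhaseError):
        parse_gff3(path)


def test_parse_gff3_orphan_exon(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF.replace("Parent=m1\nchr1\tsrc\texon\t61",
                                    "Parent=mX\nchr1\tsrc\texon\t61", 1))
    with pytest.raises(LinkageError):
        parse_gff3(path)


def test_gff3_roundtrip(tmp_path, noiseless_bundle):
    path = tmp_path / "rt.gff3"
    write_gff3(noiseless_bundle.gene_models, path)
    back = {g.gene_id: g for g in parse_gff3(path)}
    for gene in noiseless_bundle.gene_models:
        got = back[gene.gene_id]
        assert got.strand == gene.strand and got.seq_id == gene.seq_id
        for tx, tx2 in zip(sorted(gene.transcripts,
                                  key=lambda t: t.transcript_id),
                           sorted(got.transcripts,
                                  key=lambda t: t.transcript_id)):
            assert tx2.exons == tx.exons
            assert tx2.cds_segments == tx.cds_segments


# ---------------------------------------------------------------------------
# phase arithmetic
# ---------------------------------------------------------------------------

def test_next_phase_examples():
    # 10-bp segment starting in phase 0 leaves 1 dangling base -> phase 2
    assert next_phase(10, 0) == 2
    # canonical repeat exon: 72 bp in phase 2 -> phase 2 again
    assert next_phase(72, 2) == 2
    assert next_phase(3, 0) == 0
    assert next_phase(4, 0) == 2
    assert next_phase(5, 0) == 1


@given(st.lists(st.integers(min_value=1, max_value=300), min_size=1,
                max_size=8))
@settings(deadline=None, max_examples=50)
def test_phase_chain_of_split_cds_is_consistent(lengths):
    """Any CDS split into segments with propagated phases validates."""
    phases = [0]
    for n in lengths[:-1]:
        phases.append(next_phase(n, phases[-1]))
    pos, segs = 0, []
    for n, ph in zip(lengths, phases):
        segs.append(CdsSegment(start=pos, end=pos + n, phase=ph))
        pos += n + 10
    tx = TranscriptModel(transcript_id="t", exons=[(s.start, s.end)
                                                  for s in segs],
                         cds_segments=segs)
    assert validate_phase_chain(tx, "+").consistent


def test_phase_chain_mismatch_reported():
    segs = [CdsSegment(0, 10, 0), CdsSegment(20, 50, 0)]  # expected phase 2
    tx = TranscriptModel(transcript_id="t", exons=[(0, 10), (20, 50)],
                         cds_segments=segs)
    report = validate_phase_chain(tx, "+")
    assert not report.consistent
    (bad,) = report.mismatches
    assert (bad.expected_phase, bad.observed_phase) == (2, 0)


# ---------------------------------------------------------------------------
# extraction & translation
# ---------------------------------------------------------------------------

def test_extract_cds_both_strands():
    genome = GenomeSequence(id="c", residues="ATGAAA")
    tx = TranscriptModel(transcript_id="t", exons=[(0, 6)],
                         cds_segments=[CdsSegment(0, 6, 0)])
    assert extract_cds(tx, genome, "+") == "ATGAAA"
    assert extract_cds(tx, genome, "-") == "TTTCAT"


def test_translate_cds_examples():
    assert translate_cds("ATGTAA", 0) == ("M*", True)
    assert translate_cds("ATGAAA", 0) == ("MK", False)
    # phase 1 drops the leading base: "TGA" -> stop
    assert translate_cds("ATGA", 1) == ("*", True)
    # trailing partial codon dropped
    assert translate_cds("ATGAA", 0) == ("M", False)


def test_translate_phase2_72bp_gives_23_residues(noiseless_bundle):
    truth = noiseless_bundle.truth["roco_001"]
    codons = truth.repeat_codons[0]
    exon = "CG" + "".join(codons) + "G"   # 2 phase bases + 69 nt + dangling
    assert len(exon) == 72
    peptide, stop = translate_cds(exon, 2)
    assert len(peptide) == 23 and not stop
    assert peptide == truth.repeat_peptides[0]


def test_translate_cds_rejects_bad_phase():
    with pytest.raises(ValueError):
        translate_cds("ATG", 3)
    with pytest.raises(ValueError):
        translate_cds("", 0)


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------

DOMTBL_LINE = ("prot1 - 500 LRR_1 PF00560.17 60 1e-20 80.0 0.0 1 1 "
               "1e-18 1e-18 75.0 0.0 1 60 10 100 9 101 0.95 -\n")


def test_parse_domtblout(tmp_path):
    path = tmp_path / "h.domtblout"
    path.write_text("# comment\n\n" + DOMTBL_LINE)
    hits, summary = parse_domtblout(path)
    assert summary.n_hits == 1 and summary.n_skipped == 0
    (h,) = hits
    assert h.protein_id == "prot1"
    assert h.signature_acc == "PF00560"      # version stripped
    assert (h.ali_start, h.ali_end) == (10, 100)
    assert h.ievalue == pytest.approx(1e-18)
    assert h.score == pytest.approx(75.0)


def test_parse_domtblout_skips_malformed(tmp_path):
    path = tmp_path / "h.domtblout"
    path.write_text(DOMTBL_LINE + "broken row\n")
    hits, summary = parse_domtblout(path)
    assert len(hits) == 1 and summary.n_skipped == 1


def test_parse_interpro_tsv(tmp_path):
    row = "\t".join(["prot1", "md5", "500", "SMART", "SM00368", "domain",
                     "5", "28", "2e-9", "T", "01-01-2024", "IPR003591", "-"])
    path = tmp_path / "h.tsv"
    path.write_text(row + "\n")
    hits, summary = parse_interpro_tsv(path)
    # one member-signature hit plus one integrated-accession hit
    assert summary.n_hits == 2
    accs = {h.signature_acc for h in hits}
    assert accs == {"SM00368", "IPR003591"}
    assert all(h.ali_start == 5 and h.ali_end == 28 for h in hits)


def test_synthetic_domain_tables_roundtrip(tmp_path, noiseless_bundle):
    from lrrshuffle.synthetic_data import write_domtblout, write_interpro_tsv
    dpath, ipath = tmp_path / "h.domtblout", tmp_path / "h.tsv"
    write_domtblout(noiseless_bundle.domtbl_hits,
                    noiseless_bundle.proteome_lengths, dpath)
    write_interpro_tsv(noiseless_bundle.interpro_hits,
                       noiseless_bundle.proteome_lengths, ipath)
    dhits, dsum = parse_domtblout(dpath)
    ihits, isum = parse_interpro_tsv(ipath)
    assert dsum.n_skipped == 0 and isum.n_skipped == 0
    assert len(dhits) == len(noiseless_bundle.domtbl_hits)
    want = {(h.protein_id, h.signature_acc, h.ali_start, h.ali_end)
            for h in noiseless_bundle.domtbl_hits}
    got = {(h.protein_id, h.signature_acc, h.ali_start, h.ali_end)
           for h in dhits}
    assert got == want
    # interpro rows re-emit member + integrated accession
    assert {h.protein_id for h in ihits} == \
        {h.protein_id for h in noiseless_bundle.interpro_hits}


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def test_parse_expression_table(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("gene_id\tcondition\tcontrol_value\ttreated_value\tpvalue\n"
                    "g1\tHyperS\t10.0\t40.0\t0.01\n"
                    "g2\tHyperS\t5.0\t5.0\t\n")
    recs = parse_expression_table(path)
    assert len(recs) == 2
    assert recs[0].pvalue == pytest.approx(0.01)
    assert recs[1].pvalue is None
    assert math.isclose(recs[0].treated_value / recs[0].control_value, 4.0)


def test_parse_expression_table_missing_column(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("gene_id\tcondition\tcontrol_value\n" "g1\tHyperS\t10.0\n")
    with pytest.raises(FormatError):
        parse_expression_table(path)
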