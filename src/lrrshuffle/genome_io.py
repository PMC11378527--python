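"""Standard-format I/O and the internal gene-model representation.

Coordinate conventions
----------------------
GFF3 coordinates are 1-based inclusive; they are converted to 0-based
half-open intervals at parse time and converted back only when writing.
All in-memory arithmetic uses 0-based half-open intervals.

``phase`` follows GFF3 CDS semantics: the number of bases (0, 1 or 2) to
remove from the 5' end of a CDS segment to reach the first complete codon.
For a minus-strand gene the 5' end of a segment is its *high*-coordinate
side, and translation order is reverse genomic order.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, broken hierarchy...)."""


class AlphabetError(FormatError):
    """Sequence contains characters outside the accepted DNA alphabet."""


class MissingPhaseError(FormatError):
    """A CDS row lacks the phase this pipeline requires."""


class LinkageError(FormatError):
    """A feature's Parent attribute references an unknown ID."""


class RangeError(ValueError):
    """Genomic coordinates fall outside the host sequence."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One DNA sequence (chromosome / scaffold / contig)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CdsSegment:
    """One CDS row: 0-based half-open genomic interval plus GFF3 phase."""

    start: int
    end: int
    phase: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"empty/inverted CDS segment {self.start}..{self.end}")
        if self.phase not in (0, 1, 2):
            raise MissingPhaseError(f"CDS phase must be 0/1/2, got {self.phase!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One mRNA: exon intervals plus CDS segments, genomic order."""

    transcript_id: str
    exons: list[tuple[int, int]]
    cds_segments: list[CdsSegment]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.cds_segments = sorted(self.cds_segments, key=lambda c: c.start)

    def cds_in_translation_order(self, strand: str) -> list[CdsSegment]:
        return self.cds_segments if strand == "+" else self.cds_segments[::-1]


@dataclass
class GeneModel:
    """A gene with its transcripts on one strand of one host sequence."""

    gene_id: str
    seq_id: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise FormatError(f"gene {self.gene_id}: no transcripts")


@dataclass(frozen=True)
class DomainHit:
    """One profile/signature match on a protein (1-based inclusive coords)."""

    protein_id: str
    signature_acc: str
    ali_start: int
    ali_end: int
    ievalue: float
    score: float
    source: str  # hmmsearch | interproscan

    def __post_init__(self) -> None:
        if not (1 <= self.ali_start <= self.ali_end):
            raise FormatError(
                f"bad alignment coords {self.ali_start}..{self.ali_end} "
                f"for {self.protein_id}/{self.signature_acc}"
            )
        if self.ievalue < 0:
            raise FormatError("i-Evalue must be >= 0")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class ExpressionRecord:
    """Normalized expression of one gene in one condition vs its control."""

    gene_id: str
    condition: str
    control_value: float
    treated_value: float
    pvalue: float | None = None
    printed_log2fc: float | None = None
    checkable: bool = False

    def __post_init__(self) -> None:
        if self.control_value < 0 or self.treated_value < 0:
            raise FormatError(
                f"negative expression for {self.gene_id}/{self.condition}"
            )
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise FormatError(f"p-value out of [0,1] for {self.gene_id}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: str | os.PathLike, *, map_unknown_to_n: bool = False
                ) -> list[GenomeSequence]:
    """Read a multi-record DNA FASTA.

    Sequences are uppercased; characters outside ``ACGTN`` raise
    :class:`AlphabetError` unless ``map_unknown_to_n`` is set, in which
    case they are replaced by ``N``.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if map_unknown_to_n:
            residues = "".join(c if c in DNA_ALPHABET else "N" for c in residues)
        records.append(GenomeSequence(id=rec.id, residues=residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Iterable[GenomeSequence], path: str | os.PathLike,
                *, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.length, width):
                fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def parse_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS hierarchies from a GFF3 file.

    Returns one :class:`GeneModel` per ``gene`` row. CDS phases are taken
    verbatim from column 8 and are mandatory. Orphan exon/CDS features
    (Parent missing or unknown) raise :class:`LinkageError`.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = {f.id for f in db.all_features()}

    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent")
            if not parents:
                raise LinkageError(f"{ftype} at {feat.seqid}:{feat.start} has no Parent")
            for pid in parents:
                if pid not in known_ids:
                    raise LinkageError(
                        f"{ftype} Parent {pid!r} references an unknown ID"
                    )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = [(f.start - 1, f.end)
                     for f in db.children(mrna, featuretype="exon")]
            cds = []
            for f in db.children(mrna, featuretype="CDS"):
                if f.frame in (None, "", "."):
                    raise MissingPhaseError(
                        f"CDS of {mrna.id} at {f.seqid}:{f.start} lacks a phase"
                    )
                cds.append(CdsSegment(start=f.start - 1, end=f.end,
                                      phase=int(f.frame)))
            transcripts.append(
                TranscriptModel(transcript_id=mrna.id, exons=exons,
                                cds_segments=cds)
            )
        genes.append(GeneModel(gene_id=gene.id, seq_id=gene.seqid,
                               strand=gene.strand, transcripts=transcripts))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene models as GFF3 (deterministic row order)."""

    def row(seqid, ftype, start0, end0, strand, phase, attrs):
        return "\t".join([
            seqid, "lrrshuffle", ftype, str(start0 + 1), str(end0), ".",
            strand, phase, attrs,
        ])

    lines = ["##gff-version 3"]
    for gene in sorted(genes, key=lambda g: g.gene_id):
        gstart = min(t.exons[0][0] for t in gene.transcripts)
        gend = max(t.exons[-1][1] for t in gene.transcripts)
        lines.append(row(gene.seq_id, "gene", gstart, gend, gene.strand, ".",
                         f"ID={gene.gene_id}"))
        for tx in gene.transcripts:
            lines.append(row(gene.seq_id, "mRNA", tx.exons[0][0],
                             tx.exons[-1][1], gene.strand, ".",
                             f"ID={tx.transcript_id};Parent={gene.gene_id}"))
            for i, (s, e) in enumerate(tx.exons, 1):
                lines.append(row(gene.seq_id, "exon", s, e, gene.strand, ".",
                                 f"ID={tx.transcript_id}.exon{i};"
                                 f"Parent={tx.transcript_id}"))
            for i, seg in enumerate(tx.cds_segments, 1):
                lines.append(row(gene.seq_id, "CDS", seg.start, seg.end,
                                 gene.strand, str(seg.phase),
                                 f"ID={tx.transcript_id}.cds{i};"
                                 f"Parent={tx.transcript_id}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# phase arithmetic
# ---------------------------------------------------------------------------

def next_phase(length: int, phase: int) -> int:
    """GFF3 phase propagated across a CDS segment of ``length`` bases."""
    return (3 - ((length - phase) % 3)) % 3


@dataclass(frozen=True)
class PhaseJunction:
    index: int            # junction between segment i and i+1 (translation order)
    expected_phase: int
    observed_phase: int

    @property
    def consistent(self) -> bool:
        return self.expected_phase == self.observed_phase


@dataclass(frozen=True)
class PhaseChainReport:
    transcript_id: str
    junctions: tuple[PhaseJunction, ...]

    @property
    def consistent(self) -> bool:
        return all(j.consistent for j in self.junctions)

    @property
    def mismatches(self) -> tuple[PhaseJunction, ...]:
        return tuple(j for j in self.junctions if not j.consistent)


def validate_phase_chain(transcript: TranscriptModel, strand: str = "+"
                         ) -> PhaseChainReport:
    """Check that stored CDS phases propagate consistently along a transcript.

    For consecutive segments i, i+1 in translation order the expected phase
    of segment i+1 is ``(3 - ((len_i - phase_i) mod 3)) mod 3``. A single
    segment is vacuously consistent.
    """
    segs = transcript.cds_in_translation_order(strand)
    if not segs:
        raise FormatError(f"transcript {transcript.transcript_id} has no CDS")
    junctions = []
    for i in range(len(segs) - 1):
        expected = next_phase(len(segs[i]), segs[i].phase)
        junctions.append(PhaseJunction(index=i, expected_phase=expected,
                                       observed_phase=segs[i + 1].phase))
    return PhaseChainReport(transcript_id=transcript.transcript_id,
                            junctions=tuple(junctions))


# ---------------------------------------------------------------------------
# CDS extraction & translation
# ---------------------------------------------------------------------------

def extract_cds(transcript: TranscriptModel, genome: GenomeSequence,
                strand: str = "+") -> str:
    """Spliced coding sequence in translation order (5'->3' of the mRNA).

    Phase bases of the first segment are *not* removed here; pass the first
    segment's phase to :func:`translate_cds`.
    """
    for seg in transcript.cds_segments:
        if seg.start < 0 or seg.end > genome.length:
            raise RangeError(
                f"CDS {seg.start}..{seg.end} outside {genome.id} "
                f"(length {genome.length})"
            )
    joined = "".join(genome.residues[seg.start:seg.end]
                     for seg in transcript.cds_segments)
    if strand == "-":
        joined = str(Seq(joined).reverse_complement())
    return joined


def translate_cds(cds: str, phase: int = 0) -> tuple[str, bool]:
    """Translate a coding string with the standard genetic code.

    Drops ``phase`` leading bases and any trailing partial codon. Stops are
    kept as ``*``; the returned flag is True when any stop codon occurs.
    Codons containing ambiguous bases translate to ``X``.
    """
    if not cds:
        raise ValueError("empty CDS")
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0/1/2, got {phase!r}")
    trimmed = cds[phase:]
    trimmed = trimmed[:len(trimmed) - (len(trimmed) % 3)]
    if not trimmed:
        return "", False
    peptide = str(Seq(trimmed).translate())
    return peptide, "*" in peptide


# ---------------------------------------------------------------------------
# domain-hit tables
# ---------------------------------------------------------------------------

@dataclass
class ParseSummary:
    n_rows: int = 0
    n_hits: int = 0
    n_skipped: int = 0


def _strip_version(acc: str) -> str:
    return acc.split(".")[0]


def parse_domtblout(path: str | os.PathLike
                    ) -> tuple[list[DomainHit], ParseSummary]:
    """Read HMMER3 ``--domtblout`` per-domain output (hmmsearch direction:
    query = profile, target = protein). Malformed rows are skipped and
    counted."""
    hits: list[DomainHit] = []
    summary = ParseSummary()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            summary.n_rows += 1
            fields = line.split()
            try:
                acc = fields[4]
                if acc == "-":
                    acc = fields[3]
                hits.append(DomainHit(
                    protein_id=fields[0],
                    signature_acc=_strip_version(acc),
                    ali_start=int(fields[17]),
                    ali_end=int(fields[18]),
                    ievalue=float(fields[12]),
                    score=float(fields[13]),
                    source="hmmsearch",
                ))
                summary.n_hits += 1
            except (IndexError, ValueError, FormatError) as exc:
                summary.n_skipped += 1
                logger.warning("skipping malformed domtblout row: %s (%s)",
                               line.rstrip(), exc)
    return hits, summary


def parse_interpro_tsv(path: str | os.PathLike
                       ) -> tuple[list[DomainHit], ParseSummary]:
    """Read InterProScan TSV output.

    Each row yields one hit for the member-database signature (column 5);
    when column 12 carries an integrated InterPro accession a second hit is
    emitted under that accession so architecture rules can match either.
    """
    hits: list[DomainHit] = []
    summary = ParseSummary()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            summary.n_rows += 1
            fields = line.rstrip("\n").split("\t")
            try:
                if len(fields) < 9:
                    raise ValueError("too few columns")
                protein_id = fields[0]
                sig = fields[4]
                start, end = int(fields[6]), int(fields[7])
                try:
                    # column 9 is the member-database e-value (or "-")
                    evalue = max(float(fields[8]), 0.0)
                except ValueError:
                    evalue = 0.0
                hits.append(DomainHit(protein_id=protein_id,
                                      signature_acc=sig, ali_start=start,
                                      ali_end=end, ievalue=evalue,
                                      score=evalue, source="interproscan"))
                summary.n_hits += 1
                if len(fields) > 11 and fields[11] not in ("", "-"):
                    hits.append(DomainHit(protein_id=protein_id,
                                          signature_acc=fields[11],
                                          ali_start=start, ali_end=end,
                                          ievalue=0.0, score=evalue,
                                          source="interproscan"))
                    summary.n_hits += 1
            except (IndexError, ValueError, FormatError) as exc:
                summary.n_skipped += 1
                logger.warning("skipping malformed InterProScan row: %s (%s)",
                               line.rstrip(), exc)
    return hits, summary


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def parse_expression_table(path: str | os.PathLike) -> list[ExpressionRecord]:
    """Read a long-format expression TSV.

    Required columns: gene_id, condition, control_value, treated_value,
    pvalue. Optional: printed_log2fc (reference value transcribed from a
    publication table) and checkable (whether that reference equals the
    naive log2 ratio of the printed values).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition", "control_value", "treated_value",
                "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"expression table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pv = getattr(row, "pvalue")
        records.append(ExpressionRecord(
            gene_id=str(row.gene_id),
            condition=str(row.condition),
            control_value=float(row.control_value),
            treated_value=float(row.treated_value),
            pvalue=None if pd.isna(pv) else float(pv),
            printed_log2fc=(float(row.printed_log2fc)
                            if "printed_log2fc" in df.columns
                            and not pd.isna(row.printed_log2fc) else None),
            checkable=bool(getattr(row, "checkable", False)),
        ))
    return records


def write_expression_table(records: Sequence[ExpressionRecord],
                           path: str | os.PathLike) -> None:
    rows = [{
        "gene_id": r.gene_id, "condition": r.condition,
        "control_value": r.control_value, "treated_value": r.treated_value,
        "pvalue": "" if r.pvalue is None else r.pvalue,
    } for r in sorted(records, key=lambda r: (r.gene_id, r.condition))]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
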