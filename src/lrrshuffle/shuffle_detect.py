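"""Detection of canonical shuffled-LRR exon arrays.

The canonical unit is a 72-bp coding exon in GFF3 phase 2: its first two
bases complete the codon split by the upstream junction, the following 69
bases (positions 3-71) encode a 23-residue leucine-rich repeat, and base 72
begins the codon completed by the next exon, so phase 2 propagates along
the whole array. Within the 23-mer a 17-residue segment matches the LRR
consensus ``LxxLxxLxxLxLxxNxL`` where each L position admits any of
{L, V, I, A} and position 15 is asparagine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .genome_io import (GeneModel, GenomeSequence, RangeError,
                        TranscriptModel, translate_cds)

#: 1-based positions of hydrophobic anchors within the 17-mer consensus
HYDROPHOBIC_ANCHORS = (1, 4, 7, 10, 12, 17)
#: 1-based position of the conserved asparagine within the 17-mer
ASN_ANCHOR = 15
HYDROPHOBIC_CLASS = frozenset("LVIA")
CONSENSUS = "LxxLxxLxxLxLxxNxL"


@dataclass(frozen=True)
class LrrExonSpec:
    """Parameters of the canonical shuffled-LRR exon model."""

    exon_length: int = 72
    phase: int = 2
    repeat_length: int = 23
    consensus: str = CONSENSUS
    hydrophobic_class: frozenset = HYDROPHOBIC_CLASS
    min_hydrophobic_matches: int = 4
    require_asn: bool = True
    min_run: int = 3
    length_tolerance: int = 0

    def __post_init__(self) -> None:
        if len(self.consensus) != 17:
            raise ValueError("consensus segment must be 17 residues")
        dangling = (self.exon_length - self.phase) % 3
        if self.phase + 3 * self.repeat_length + dangling != self.exon_length:
            raise ValueError(
                "inconsistent geometry: exon_length must equal "
                "phase + 3*repeat_length + dangling"
            )

    @property
    def n_offsets(self) -> int:
        return self.repeat_length - len(self.consensus) + 1


@dataclass(frozen=True)
class LrrExonCall:
    """One CDS exon judged against the canonical repeat model."""

    transcript_id: str
    exon_index: int                 # translation order, 0-based
    interval: tuple[int, int]       # 0-based half-open genomic
    length: int
    phase: int
    repeat_peptide: str
    best_offset: int
    anchor_score: int
    qualifies: bool


@dataclass(frozen=True)
class LrrArray:
    """A maximal run of consecutive qualifying LRR exons."""

    transcript_id: str
    start_exon_index: int
    end_exon_index: int
    calls: tuple[LrrExonCall, ...]

    @property
    def run_length(self) -> int:
        return self.end_exon_index - self.start_exon_index + 1


def match_lrr_motif(peptide: str, spec: LrrExonSpec = LrrExonSpec()
                    ) -> tuple[int, int, bool]:
    """Slide the 17-mer consensus over a repeat peptide.

    Returns ``(best_offset, anchor_score, passes)``. The window may start at
    any of the ``repeat_length - 17 + 1`` offsets; at each, the score counts
    matched hydrophobic anchors (consensus positions 1,4,7,10,12,17 in
    {L,V,I,A}) plus one for Asn at position 15. The best offset maximises
    the score, ties to the smallest offset; the motif passes if any offset
    satisfies the anchor rule (Asn present when required, and at least
    ``min_hydrophobic_matches`` hydrophobic anchors).
    """
    if len(peptide) != spec.repeat_length:
        raise ValueError(
            f"peptide length {len(peptide)} != repeat_length {spec.repeat_length}"
        )
    best_offset, best_score, passes = 0, -1, False
    for offset in range(spec.n_offsets):
        window = peptide[offset:offset + 17]
        hydro = sum(window[p - 1] in spec.hydrophobic_class
                    for p in HYDROPHOBIC_ANCHORS)
        asn = window[ASN_ANCHOR - 1] == "N"
        score = hydro + int(asn)
        if score > best_score:
            best_offset, best_score = offset, score
        if (asn or not spec.require_asn) and hydro >= spec.min_hydrophobic_matches:
            passes = True
    return best_offset, best_score, passes


def call_lrr_exons(transcript: TranscriptModel, genome: GenomeSequence,
                   strand: str = "+", spec: LrrExonSpec = LrrExonSpec()
                   ) -> list[LrrExonCall]:
    """Judge every CDS segment of a transcript against the repeat model.

    Segments are visited in translation order; on the minus strand the
    coding-strand sequence of each segment is its reverse complement.
    Segments too short to hold a repeat yield non-qualifying calls with an
    empty peptide rather than an error.
    """
    calls: list[LrrExonCall] = []
    for idx, seg in enumerate(transcript.cds_in_translation_order(strand)):
        if seg.start < 0 or seg.end > genome.length:
            raise RangeError(
                f"CDS {seg.start}..{seg.end} outside {genome.id}"
            )
        raw = genome.residues[seg.start:seg.end]
        coding = str(Seq(raw).reverse_complement()) if strand == "-" else raw
        needed = seg.phase + 3 * spec.repeat_length
        if len(coding) < needed:
            calls.append(LrrExonCall(
                transcript_id=transcript.transcript_id, exon_index=idx,
                interval=(seg.start, seg.end), length=len(seg),
                phase=seg.phase, repeat_peptide="", best_offset=0,
                anchor_score=0, qualifies=False))
            continue
        peptide, _ = translate_cds(coding[:needed], seg.phase)
        best_offset, score, passes = match_lrr_motif(peptide, spec)
        length_ok = abs(len(seg) - spec.exon_length) <= spec.length_tolerance
        phase_ok = seg.phase == spec.phase
        calls.append(LrrExonCall(
            transcript_id=transcript.transcript_id, exon_index=idx,
            interval=(seg.start, seg.end), length=len(seg), phase=seg.phase,
            repeat_peptide=peptide, best_offset=best_offset,
            anchor_score=score, qualifies=length_ok and phase_ok and passes))
    return calls


def detect_arrays(calls: Sequence[LrrExonCall],
                  spec: LrrExonSpec = LrrExonSpec()) -> list[LrrArray]:
    """Maximal runs of consecutive qualifying calls with length >= min_run."""
    arrays: list[LrrArray] = []
    run: list[LrrExonCall] = []
    for call in calls:
        if call.qualifies:
            run.append(call)
        else:
            if len(run) >= spec.min_run:
                arrays.append(_make_array(run))
            run = []
    if len(run) >= spec.min_run:
        arrays.append(_make_array(run))
    return arrays


def _make_array(run: list[LrrExonCall]) -> LrrArray:
    return LrrArray(transcript_id=run[0].transcript_id,
                    start_exon_index=run[0].exon_index,
                    end_exon_index=run[-1].exon_index,
                    calls=tuple(run))


@dataclass(frozen=True)
class GeneScan:
    gene_id: str
    max_run_length: int
    n_qualifying_exons: int
    has_shuffling_lrr: bool
    is_roco: bool
    error: str | None = None


@dataclass(frozen=True)
class ScanReport:
    genes: tuple[GeneScan, ...]

    @property
    def n_shuffling(self) -> int:
        return sum(g.has_shuffling_lrr for g in self.genes)

    @property
    def n_shuffling_non_roco(self) -> int:
        return sum(g.has_shuffling_lrr and not g.is_roco for g in self.genes)

    @property
    def n_errors(self) -> int:
        return sum(g.error is not None for g in self.genes)


def genome_scan(genes: Iterable[GeneModel],
                genome: dict[str, GenomeSequence] | Sequence[GenomeSequence],
                spec: LrrExonSpec = LrrExonSpec(),
                roco_ids: Iterable[str] = ()) -> ScanReport:
    """Scan annotated genes for shuffled-LRR exon arrays genome-wide.

    Per gene the best transcript statistics are reported (max array run
    length and max qualifying-exon count over transcripts). Genes on
    contigs absent from the FASTA get an error entry; the scan continues.
    """
    if not isinstance(genome, dict):
        genome = {g.id: g for g in genome}
    roco_set = set(roco_ids)
    results: list[GeneScan] = []
    for gene in genes:
        host = genome.get(gene.seq_id)
        if host is None:
            results.append(GeneScan(gene_id=gene.gene_id, max_run_length=0,
                                    n_qualifying_exons=0,
                                    has_shuffling_lrr=False,
                                    is_roco=gene.gene_id in roco_set,
                                    error=f"contig {gene.seq_id!r} missing"))
            continue
        max_run = 0
        max_qual = 0
        for tx in gene.transcripts:
            calls = call_lrr_exons(tx, host, gene.strand, spec)
            arrays = detect_arrays(calls, spec)
            if arrays:
                max_run = max(max_run, max(a.run_length for a in arrays))
            max_qual = max(max_qual, sum(c.qualifies for c in calls))
        results.append(GeneScan(gene_id=gene.gene_id, max_run_length=max_run,
                                n_qualifying_exons=max_qual,
                                has_shuffling_lrr=max_run >= spec.min_run,
                                is_roco=gene.gene_id in roco_set))
    return ScanReport(genes=tuple(results))
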