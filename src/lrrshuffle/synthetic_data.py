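"""Synthetic genomes, annotations, domain tables and expression tables.

The generator emits exactly the structures the analysis assumes, with a
ground-truth record for every planted feature, so each pipeline stage can
be tested without external downloads.

A planted ROCO-like gene is laid out as::

    [leader exon][intron][72-bp repeat exon] x N [intron][tail exon]

where every repeat exon is in GFF3 phase 2: two bases completing the codon
split at the upstream junction, 69 bases encoding one 23-residue LRR unit,
and one dangling base opening the next split codon. All split (junction)
codons use one fixed codon, so any alternative-splicing subset of repeat
exons still recombines into the same junction residue and the variant's
peptide is the leader + the retained repeats + the tail.

Repeat units descend from one consensus-conforming base repeat under a
per-codon i.i.d. substitution model: synonymous changes at one rate,
nonsynonymous changes at another, the latter multiplied at the planted
diversifying-selection sites. Negative gene classes (LRR-only, ROC-only,
wrong exon length, wrong phase, plain) exercise every gate of the
detector and the identification cascade.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .genome_io import (CdsSegment, DomainHit, ExpressionRecord, GeneModel,
                        GenomeSequence, TranscriptModel, write_expression_table,
                        write_fasta, write_gff3)
from .repeat_profile import RepeatFamily, build_family
from .roco_identify import GROUP1_2, GROUP3, GROUP4

# base repeat: consensus 17-mer at offset 0 so the planted selection sites
# (14, 16, 18, 19 within the 23-mer) never touch a consensus anchor
BASE_REPEAT_PEPTIDE = "LAGLKELDSLELTTNGLSGSKAE"
JUNCTION_CODON = "GAG"   # Glu at every exon junction
STOP_CODON = "TAA"

_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
from .repeat_profile import SENSE_CODONS, _CODON_AA  # noqa: E402

_SYNONYMS = {}
for _c in SENSE_CODONS:
    _SYNONYMS[_c] = [d for d in SENSE_CODONS
                     if _CODON_AA[d] == _CODON_AA[_c] and d != _c]


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated cohort."""

    seed: int = 0
    n_roco_genes: int = 5
    n_lrr_only_genes: int = 3
    n_roc_only_genes: int = 3
    n_plain_genes: int = 2
    n_wrong_length_genes: int = 1
    n_wrong_phase_genes: int = 1
    repeats_range: tuple[int, int] = (4, 49)
    repeats_per_gene: tuple[int, ...] | None = None   # override, ROCO genes
    exon_length: int = 72
    phase: int = 2
    repeat_length: int = 23
    base_repeat_peptide: str = BASE_REPEAT_PEPTIDE
    synonymous_rate: float = 0.1
    nonsynonymous_rate: float = 0.075
    selected_sites: tuple[int, ...] = (14, 16, 18, 19)
    selection_multiplier: float = 8.0
    intron_length_range: tuple[int, int] = (80, 200)
    max_transcripts: int = 9
    n_transcripts_fixed: int | None = None   # force this many per ROCO gene
    minus_strand_prob: float = 0.5
    leader_peptide: str = "MDTS"
    tail_length_aa: int = 250
    cor_prob: float = 0.16
    group_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)  # 1_2, 3, 4
    conditions: tuple[str, ...] = ("HyperS", "HypoS", "Oxi", "Cu_4", "Cu_8")
    deg_prob: float = 0.3
    planted_log2fc_range: tuple[float, float] = (1.5, 3.5)
    expression_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.minus_strand_prob, self.cor_prob, self.deg_prob,
                  self.synonymous_rate, self.nonsynonymous_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0,1]")
        if self.intron_length_range[0] > self.intron_length_range[1]:
            raise ConfigError("intron length min > max")
        if self.repeats_range[0] > self.repeats_range[1] or self.repeats_range[0] < 1:
            raise ConfigError("bad repeats_range")
        if not set(self.selected_sites) <= set(range(1, self.repeat_length + 1)):
            raise ConfigError("selected sites must lie within the repeat unit")
        if len(self.base_repeat_peptide) != self.repeat_length:
            raise ConfigError("base repeat length != repeat_length")
        dangling = (self.exon_length - self.phase) % 3
        if self.phase + 3 * self.repeat_length + dangling != self.exon_length:
            raise ConfigError("exon geometry inconsistent")
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ConfigError("group_probs must sum to 1")


@dataclass
class GeneTruth:
    gene_id: str
    gene_class: str              # roco | lrr_only | roc_only | plain | wrong_length | wrong_phase
    strand: str
    seq_id: str
    n_repeats: int
    repeat_peptides: list[str]
    repeat_codons: list[list[str]]
    repeat_exon_intervals: list[tuple[int, int]]   # genomic, translation order
    transcript_combinations: dict[str, list[tuple[int, int]]]
    group_label: str | None
    has_cor: bool
    protein_length: int
    peptide: str
    cds: str
    is_shuffling: bool
    roc_span: tuple[int, int] | None


@dataclass
class SimBundle:
    config: SimConfig
    sequences: list[GenomeSequence]
    gene_models: list[GeneModel]
    domtbl_hits: list[DomainHit]
    interpro_hits: list[DomainHit]
    expression: list[ExpressionRecord]
    proteome_lengths: dict[str, int]
    truth: dict[str, GeneTruth]
    planted_log2fc: dict[tuple[str, str], float]

    @property
    def roco_ids(self) -> list[str]:
        return sorted(g for g, t in self.truth.items() if t.gene_class == "roco")


# ---------------------------------------------------------------------------
# codon-level machinery
# ---------------------------------------------------------------------------

def reverse_translate(peptide: str) -> list[str]:
    return [_CODON_OF[a] for a in peptide]


def _mutate_codon(codon: str, syn_p: float, nonsyn_p: float,
                  rng: np.random.Generator) -> str:
    if rng.random() < syn_p and _SYNONYMS[codon]:
        codon = _SYNONYMS[codon][rng.integers(len(_SYNONYMS[codon]))]
    if rng.random() < nonsyn_p:
        aa = _CODON_AA[codon]
        others = [c for c in SENSE_CODONS if _CODON_AA[c] != aa]
        codon = others[rng.integers(len(others))]
    return codon


def mutate_repeat(base_codons: Sequence[str], config: SimConfig,
                  rng: np.random.Generator) -> list[str]:
    out = []
    for site, codon in enumerate(base_codons, start=1):
        mult = (config.selection_multiplier
                if site in config.selected_sites else 1.0)
        out.append(_mutate_codon(codon, config.synonymous_rate,
                                 min(config.nonsynonymous_rate * mult, 1.0),
                                 rng))
    return out


def generate_repeat_family(n_units: int, config: SimConfig | None = None,
                           seed: int = 0) -> RepeatFamily:
    """Directly simulate a repeat family (codon matrix) for the selection
    screen, without building a whole genome around it."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    base = reverse_translate(config.base_repeat_peptide)
    rows = [mutate_repeat(base, config, rng) for _ in range(n_units)]
    peptides = ["".join(_CODON_AA[c] for c in row) for row in rows]
    return build_family(peptides, codons=rows,
                        unit_length=config.repeat_length)


# ---------------------------------------------------------------------------
# gene assembly
# ---------------------------------------------------------------------------

def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _intron(config: SimConfig, rng: np.random.Generator) -> str:
    lo, hi = config.intron_length_range
    n = int(rng.integers(lo, hi + 1))
    return "GT" + _random_dna(max(n - 4, 0), rng) + "AG"


@dataclass
class _LocalGene:
    """A gene built in local plus-sense coordinates before placement."""
    sequence: str
    exon_intervals: list[tuple[int, int]]        # translation order, local
    phases: list[int]
    repeat_slots: list[int]                      # indices into exon list that are repeats
    cds: str
    peptide: str
    repeat_peptides: list[str]
    repeat_codons: list[list[str]]


def _build_repeat_gene(n_repeats: int, config: SimConfig,
                       rng: np.random.Generator, *,
                       extra_repeat_codons: int = 0,
                       phase0: bool = False,
                       mutate: bool = True) -> _LocalGene:
    """Assemble leader + repeat exons + tail in local coordinates.

    ``extra_repeat_codons`` pads each repeat exon (wrong-length class);
    ``phase0`` builds whole-codon repeat exons in phase 0 (wrong-phase
    class).
    """
    base = reverse_translate(config.base_repeat_peptide)
    leader = reverse_translate(config.leader_peptide)
    tail_aa = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                 size=config.tail_length_aa))
    tail = reverse_translate(tail_aa)

    repeat_codon_rows = []
    for _ in range(n_repeats):
        row = mutate_repeat(base, config, rng) if mutate else list(base)
        repeat_codon_rows.append(row)

    codons: list[str] = list(leader)
    exon_bounds: list[tuple[int, int]] = []   # in CDS coordinates
    phases: list[int] = []
    if phase0:
        # leader exon ends on a codon boundary; repeat exons are whole codons
        pos = 3 * len(leader)
        exon_bounds.append((0, pos))
        phases.append(0)
        for row in repeat_codon_rows:
            unit = list(row) + [JUNCTION_CODON] * (1 + extra_repeat_codons)
            codons += unit
            nxt = pos + 3 * len(unit)
            exon_bounds.append((pos, nxt))
            phases.append(0)
            pos = nxt
        codons += tail + [STOP_CODON]
        exon_bounds.append((pos, 3 * len(codons)))
        phases.append(0)
    else:
        codons.append(JUNCTION_CODON)
        pos = 3 * len(leader) + 1          # leader takes 1 base of the junction codon
        exon_bounds.append((0, pos))
        phases.append(0)
        for row in repeat_codon_rows:
            unit = list(row) + [JUNCTION_CODON] * extra_repeat_codons
            codons += unit
            codons.append(JUNCTION_CODON)
            nxt = pos + 2 + 3 * len(unit) + 1
            exon_bounds.append((pos, nxt))
            phases.append(config.phase)
            pos = nxt
        codons += tail + [STOP_CODON]
        exon_bounds.append((pos, 3 * len(codons)))
        phases.append(config.phase)

    cds = "".join(codons)
    peptide = "".join(_CODON_AA[c] for c in codons[:-1])

    # interleave introns: local genomic sequence and exon intervals
    sequence_parts = []
    local_intervals = []
    cursor = 0
    for i, (s, e) in enumerate(exon_bounds):
        if i > 0:
            intron = _intron(config, rng)
            sequence_parts.append(intron)
            cursor += len(intron)
        sequence_parts.append(cds[s:e])
        local_intervals.append((cursor, cursor + (e - s)))
        cursor += e - s
    return _LocalGene(
        sequence="".join(sequence_parts),
        exon_intervals=local_intervals,
        phases=phases,
        repeat_slots=list(range(1, 1 + n_repeats)),
        cds=cds, peptide=peptide,
        repeat_peptides=["".join(_CODON_AA[c] for c in row)
                         for row in repeat_codon_rows],
        repeat_codons=repeat_codon_rows,
    )


def _build_plain_gene(config: SimConfig, rng: np.random.Generator) -> _LocalGene:
    """An ordinary multi-exon gene with no repeat structure."""
    n_aa = int(rng.integers(120, 360))
    aa = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_aa - 1))
    codons = reverse_translate(aa) + [STOP_CODON]
    cds = "".join(codons)
    n_exons = int(rng.integers(2, 5))
    cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1,
                             replace=False).tolist())
    bounds = list(zip([0] + cuts, cuts + [len(cds)]))
    phases = [0]
    for s, e in bounds[:-1]:
        phases.append((3 - ((e - s - phases[-1]) % 3)) % 3)
    sequence_parts, local_intervals = [], []
    cursor = 0
    for i, (s, e) in enumerate(bounds):
        if i > 0:
            intron = _intron(config, rng)
            sequence_parts.append(intron)
            cursor += len(intron)
        sequence_parts.append(cds[s:e])
        local_intervals.append((cursor, cursor + (e - s)))
        cursor += e - s
    return _LocalGene(sequence="".join(sequence_parts),
                      exon_intervals=local_intervals, phases=phases,
                      repeat_slots=[], cds=cds,
                      peptide="".join(_CODON_AA[c] for c in codons[:-1]),
                      repeat_peptides=[], repeat_codons=[])


def _choose_subsets(n_repeats: int, n_variants: int,
                    rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Distinct proper subsets of repeat indices for splice variants."""
    full = tuple(range(n_repeats))
    subsets: list[tuple[int, ...]] = [full]
    seen = {full}
    attempts = 0
    while len(subsets) < n_variants and attempts < 200 * n_variants:
        attempts += 1
        keep = tuple(i for i in range(n_repeats) if rng.random() < 0.6)
        if keep and keep not in seen:
            seen.add(keep)
            subsets.append(keep)
    return subsets


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def generate(config: SimConfig, out_dir: str | os.PathLike | None = None
             ) -> SimBundle:
    """Generate the full synthetic bundle; optionally write it to disk."""
    rng = np.random.default_rng(config.seed)
    classes = (["roco"] * config.n_roco_genes
               + ["lrr_only"] * config.n_lrr_only_genes
               + ["roc_only"] * config.n_roc_only_genes
               + ["plain"] * config.n_plain_genes
               + ["wrong_length"] * config.n_wrong_length_genes
               + ["wrong_phase"] * config.n_wrong_phase_genes)

    contig_parts: list[str] = []
    cursor = 0
    seq_id = "contig_1"
    gene_models: list[GeneModel] = []
    truth: dict[str, GeneTruth] = {}
    domtbl: list[DomainHit] = []
    interpro: list[DomainHit] = []
    lengths: dict[str, int] = {}
    roco_index = 0

    for gi, gene_class in enumerate(classes, start=1):
        gene_id = f"{gene_class}_{gi:03d}"
        if gene_class in ("roco", "lrr_only"):
            if (gene_class == "roco" and config.repeats_per_gene
                    and roco_index < len(config.repeats_per_gene)):
                n_rep = config.repeats_per_gene[roco_index]
            else:
                n_rep = int(rng.integers(config.repeats_range[0],
                                         config.repeats_range[1] + 1))
            if gene_class == "roco":
                roco_index += 1
            local = _build_repeat_gene(n_rep, config, rng)
        elif gene_class == "wrong_length":
            n_rep = int(rng.integers(config.repeats_range[0],
                                     min(config.repeats_range[1], 12) + 1))
            local = _build_repeat_gene(n_rep, config, rng,
                                       extra_repeat_codons=1)
        elif gene_class == "wrong_phase":
            n_rep = int(rng.integers(config.repeats_range[0],
                                     min(config.repeats_range[1], 12) + 1))
            local = _build_repeat_gene(n_rep, config, rng, phase0=True)
        elif gene_class == "roc_only":
            n_rep = 0
            local = _build_plain_gene(config, rng)
        else:
            n_rep = 0
            local = _build_plain_gene(config, rng)

        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        spacer = _random_dna(int(rng.integers(200, 500)), rng)
        contig_parts.append(spacer)
        cursor += len(spacer)
        g0 = cursor
        glen = len(local.sequence)
        if strand == "+":
            contig_parts.append(local.sequence)
            to_genomic = lambda s, e: (g0 + s, g0 + e)
        else:
            contig_parts.append(_revcomp(local.sequence))
            to_genomic = lambda s, e: (g0 + glen - e, g0 + glen - s)
        cursor += glen

        genomic_intervals = [to_genomic(s, e) for s, e in local.exon_intervals]

        # transcripts: primary + splice-variant subsets for ROCO genes
        if gene_class == "roco" and n_rep >= 2 and config.max_transcripts > 1:
            if config.n_transcripts_fixed is not None:
                n_tx = config.n_transcripts_fixed
            else:
                n_tx = int(rng.integers(1, config.max_transcripts + 1))
            subsets = _choose_subsets(n_rep, n_tx, rng)
        else:
            subsets = [tuple(range(n_rep))] if n_rep else [()]

        transcripts = []
        combos: dict[str, list[tuple[int, int]]] = {}
        for ti, subset in enumerate(subsets, start=1):
            tid = f"{gene_id}.t{ti}"
            keep_slots = ([0] + [local.repeat_slots[k] for k in subset]
                          + [len(local.exon_intervals) - 1]
                          if local.repeat_slots else
                          list(range(len(local.exon_intervals))))
            exons = [genomic_intervals[k] for k in keep_slots]
            cds = [CdsSegment(start=genomic_intervals[k][0],
                              end=genomic_intervals[k][1],
                              phase=local.phases[k]) for k in keep_slots]
            transcripts.append(TranscriptModel(transcript_id=tid,
                                               exons=exons,
                                               cds_segments=cds))
            combos[tid] = [genomic_intervals[local.repeat_slots[k]]
                           for k in subset]
        gene_models.append(GeneModel(gene_id=gene_id, seq_id=seq_id,
                                     strand=strand, transcripts=transcripts))

        protein_length = len(local.peptide)
        lengths[gene_id] = protein_length
        group_label, has_cor, roc_span = _emit_domain_hits(
            gene_id, gene_class, n_rep, protein_length, config, rng,
            domtbl, interpro)

        truth[gene_id] = GeneTruth(
            gene_id=gene_id, gene_class=gene_class, strand=strand,
            seq_id=seq_id, n_repeats=n_rep,
            repeat_peptides=local.repeat_peptides,
            repeat_codons=local.repeat_codons,
            repeat_exon_intervals=[genomic_intervals[k]
                                   for k in local.repeat_slots],
            transcript_combinations=combos,
            group_label=group_label, has_cor=has_cor,
            protein_length=protein_length, peptide=local.peptide,
            cds=local.cds,
            is_shuffling=gene_class in ("roco", "lrr_only") and n_rep >= 3,
            roc_span=roc_span)

    contig_parts.append(_random_dna(300, rng))
    sequences = [GenomeSequence(id=seq_id, residues="".join(contig_parts))]

    expression, planted = _emit_expression(truth, config, rng)

    bundle = SimBundle(config=config, sequences=sequences,
                       gene_models=gene_models, domtbl_hits=domtbl,
                       interpro_hits=interpro, expression=expression,
                       proteome_lengths=lengths, truth=truth,
                       planted_log2fc=planted)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _emit_domain_hits(gene_id, gene_class, n_rep, protein_length, config,
                      rng, domtbl, interpro):
    """Append the domain-table rows mirroring a gene's planted architecture."""
    nl = len(config.leader_peptide)
    lrr_start = nl + 1
    lrr_end = nl + 24 * n_rep if n_rep else nl + 1
    group_label = None
    has_cor = False
    roc_span = None

    def dom(acc, s, e, ieval=1e-12):
        domtbl.append(DomainHit(protein_id=gene_id, signature_acc=acc,
                                ali_start=s, ali_end=e, ievalue=ieval,
                                score=80.0, source="hmmsearch"))

    def ipr(acc, s, e):
        interpro.append(DomainHit(protein_id=gene_id, signature_acc=acc,
                                  ali_start=s, ali_end=e, ievalue=1e-10,
                                  score=1e-10, source="interproscan"))

    if gene_class == "roco":
        for k in range(n_rep):
            s = nl + 24 * k + 1
            dom("PF00560", s, s + 22)
        roc_len = int(rng.integers(90, 180))
        roc_start = lrr_end + 10
        roc_span = (roc_start, roc_start + roc_len - 1)
        dom("PF08477", *roc_span, ieval=1e-25)
        has_cor = rng.random() < config.cor_prob
        if has_cor:
            cor_len = int(rng.integers(112, 190))
            cor_start = min(roc_span[1] + 5, protein_length - cor_len)
            dom("PF16095", cor_start, cor_start + cor_len - 1, ieval=1e-15)
        u = rng.random()
        if u < config.group_probs[0]:
            group_label = GROUP1_2
            ipr("IPR003591", lrr_start, lrr_end)
        elif u < config.group_probs[0] + config.group_probs[1]:
            group_label = GROUP3
            ipr("IPR003591", lrr_start, lrr_end)
            ipr("IPR009003", min(roc_span[1] + 20, protein_length - 40),
                protein_length)
        else:
            group_label = GROUP4
            ipr("SM00368", lrr_start, lrr_end)
            ipr("IPR010297", min(roc_span[1] + 20, protein_length - 40),
                protein_length)
    elif gene_class in ("lrr_only", "wrong_length", "wrong_phase"):
        for k in range(n_rep):
            s = nl + 24 * k + 1
            dom("PF00560", s, s + 22)
        ipr("IPR003591", lrr_start, lrr_end)
    elif gene_class == "roc_only":
        roc_len = int(rng.integers(90, min(180, protein_length - 10)))
        roc_start = max(1, protein_length - roc_len - 5)
        dom("PF08477", roc_start, roc_start + roc_len - 1, ieval=1e-25)
    return group_label, has_cor, roc_span


def _emit_expression(truth, config, rng):
    records: list[ExpressionRecord] = []
    planted: dict[tuple[str, str], float] = {}
    for gene_id in sorted(truth):
        if truth[gene_id].gene_class != "roco":
            continue
        for cond in config.conditions:
            control = float(np.exp(rng.normal(np.log(200.0), 1.0)))
            if rng.random() < config.deg_prob:
                lo, hi = config.planted_log2fc_range
                fc = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
                pval = float(rng.uniform(1e-4, 0.04))
            else:
                fc = 0.0
                pval = float(rng.uniform(0.05, 1.0))
            planted[(gene_id, cond)] = fc
            noise = rng.normal(0.0, config.expression_noise_sd)
            treated = control * 2.0 ** (fc + noise)
            records.append(ExpressionRecord(gene_id=gene_id, condition=cond,
                                            control_value=control,
                                            treated_value=treated,
                                            pvalue=pval))
    return records, planted


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_DOMTBL_HEADER = (
    "#                                                               --- full sequence --- "
    "-------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen   "
    "E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  "
    "from    to  from    to  acc description of target\n"
)

_QUERY_NAME = {"PF00560": "LRR_1", "PF08477": "Roc", "PF16095": "COR"}


def write_domtblout(hits: Sequence[DomainHit], lengths: dict[str, int],
                    path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for i, h in enumerate(sorted(hits, key=lambda h: (h.protein_id,
                                                          h.ali_start)), 1):
            qname = _QUERY_NAME.get(h.signature_acc, h.signature_acc)
            qlen = h.ali_end - h.ali_start + 1
            fh.write(" ".join([
                h.protein_id, "-", str(lengths.get(h.protein_id, 0)),
                qname, f"{h.signature_acc}.1", str(qlen),
                f"{h.ievalue:.2g}", f"{h.score:.1f}", "0.0",
                "1", "1", f"{h.ievalue:.2g}", f"{h.ievalue:.2g}",
                f"{h.score:.1f}", "0.0", "1", str(qlen),
                str(h.ali_start), str(h.ali_end),
                str(h.ali_start), str(h.ali_end), "0.90", "-",
            ]) + "\n")


_MEMBER_OF = {"IPR003591": ("SMART", "SM00369"),
              "IPR009003": ("SUPERFAMILY", "SSF50494"),
              "IPR010297": ("Pfam", "PF06008")}


def write_interpro_tsv(hits: Sequence[DomainHit], lengths: dict[str, int],
                       path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.protein_id, h.ali_start)):
            analysis, member = _MEMBER_OF.get(
                h.signature_acc, ("SMART" if h.signature_acc.startswith("SM")
                                  else "Pfam", h.signature_acc))
            ipr = h.signature_acc if h.signature_acc.startswith("IPR") else "-"
            fh.write("\t".join([
                h.protein_id, "md5", str(lengths.get(h.protein_id, 0)),
                analysis, member, "domain", str(h.ali_start),
                str(h.ali_end), f"{h.score:.2g}", "T", "01-01-2024",
                ipr, "-",
            ]) + "\n")


def write_bundle(bundle: SimBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the bundle to standard-format files; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("fasta", "genome.fa"), ("gff3", "models.gff3"),
        ("domtblout", "hits.domtblout"), ("interpro", "hits.interpro.tsv"),
        ("expression", "expression.tsv"), ("lengths", "protein_lengths.tsv"),
        ("truth", "truth.json")]}
    write_fasta(bundle.sequences, paths["fasta"])
    write_gff3(bundle.gene_models, paths["gff3"])
    write_domtblout(bundle.domtbl_hits, bundle.proteome_lengths,
                    paths["domtblout"])
    write_interpro_tsv(bundle.interpro_hits, bundle.proteome_lengths,
                       paths["interpro"])
    write_expression_table(bundle.expression, paths["expression"])
    with open(paths["lengths"], "w") as fh:
        fh.write("protein_id\tlength\n")
        for pid in sorted(bundle.proteome_lengths):
            fh.write(f"{pid}\t{bundle.proteome_lengths[pid]}\n")
    truth_json = {
        gid: {**asdict(t),
              "transcript_combinations": {
                  tid: [list(iv) for iv in combo]
                  for tid, combo in t.transcript_combinations.items()}}
        for gid, t in bundle.truth.items()}
    with open(paths["truth"], "w") as fh:
        json.dump({"truth": truth_json,
                   "planted_log2fc": {f"{g}|{c}": v for (g, c), v
                                      in bundle.planted_log2fc.items()},
                   "seed": bundle.config.seed}, fh, indent=1)
    return paths
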