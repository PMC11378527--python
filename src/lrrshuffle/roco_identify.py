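"""ROCO-family identification from domain-hit tables.

ROCO proteins carry an N-terminal leucine-rich-repeat (LRR) region followed
by a Ras-of-complex (ROC) GTPase domain, optionally trailed by a
C-terminal-of-Roc (COR) dimerization domain. Identification is a cascade
over pre-computed profile hits: an LRR gate (PF00560), then a ROC gate
(PF08477); COR hits (PF16095) are attached as annotation only, since the
COR profile is not reliably detected by general-purpose scans of these
proteomes. Architecture groups are assigned from accessory signatures:
group 3 has a C-terminal peptidase fold (IPR009003), group 4 a distinct
LRR subfamily (SM00368) plus a C-terminal DUF900 domain (IPR010297), and
the remaining canonical members are reported as the merged group1_2 label
(separating 1 from 2 needs a ROC phylogeny, not domain content).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Mapping, Sequence

from .genome_io import DomainHit, GeneModel

logger = logging.getLogger(__name__)

PF_LRR = "PF00560"
PF_ROC = "PF08477"
PF_COR = "PF16095"
IPR_LRR_TYPICAL = "IPR003591"
IPR_PEPTIDASE = "IPR009003"
IPR_DUF900 = "IPR010297"
SM_LRR = "SM00368"

GROUP1_2 = "group1_2"
GROUP3 = "group3"
GROUP4 = "group4"
UNCLASSIFIED = "unclassified"

LRR_SIGNATURES = frozenset({PF_LRR, IPR_LRR_TYPICAL, SM_LRR})


@dataclass
class RocoCandidate:
    """One protein passing the LRR+ROC cascade."""

    protein_id: str
    lrr_hits: list[DomainHit]
    roc_hits: list[DomainHit]
    cor_hits: list[DomainHit] = field(default_factory=list)
    other_hits: list[DomainHit] = field(default_factory=list)
    protein_length: int | None = None
    group_label: str = GROUP1_2
    conflict: bool = False

    @property
    def roc_span(self) -> tuple[int, int]:
        """Span of the longest ROC hit (1-based inclusive)."""
        best = max(self.roc_hits, key=lambda h: (h.length, -h.ali_start))
        return (best.ali_start, best.ali_end)

    @property
    def roc_length(self) -> int:
        s, e = self.roc_span
        return e - s + 1

    @property
    def cor_length(self) -> int | None:
        if not self.cor_hits:
            return None
        best = max(self.cor_hits, key=lambda h: (h.length, -h.ali_start))
        return best.length

    @property
    def lrr_count(self) -> int:
        return len(self.lrr_hits)

    @property
    def n_terminal_lrr(self) -> bool:
        return (min(h.ali_start for h in self.lrr_hits)
                < min(h.ali_start for h in self.roc_hits))


def identify_rocos(proteome_lengths: Mapping[str, int],
                   hits: Iterable[DomainHit],
                   e_threshold: float = 1e-5) -> list[RocoCandidate]:
    """Run the identification cascade over a table of domain hits.

    Keep proteins with >=1 LRR (PF00560) hit at i-Evalue <= threshold; of
    those, keep proteins with >=1 ROC (PF08477) hit at the same threshold.
    COR hits are attached without gating. Candidates whose earliest LRR hit
    is not N-terminal of the earliest ROC hit are retained but marked
    unclassified with a warning. Hits on proteins missing from
    ``proteome_lengths`` are logged and skipped.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for hit in hits:
        if hit.protein_id not in proteome_lengths:
            logger.warning("hit on unknown protein %s skipped", hit.protein_id)
            continue
        by_protein[hit.protein_id].append(hit)

    candidates: list[RocoCandidate] = []
    for pid in sorted(by_protein):
        phits = by_protein[pid]
        lrr = [h for h in phits if h.signature_acc == PF_LRR
               and h.ievalue <= e_threshold]
        if not lrr:
            continue
        roc = [h for h in phits if h.signature_acc == PF_ROC
               and h.ievalue <= e_threshold]
        if not roc:
            continue
        cor = [h for h in phits if h.signature_acc == PF_COR]
        other = [h for h in phits
                 if h.signature_acc not in (PF_LRR, PF_ROC, PF_COR)]
        # SMART/InterPro LRR signatures count toward the LRR region too
        lrr += [h for h in other if h.signature_acc in LRR_SIGNATURES]
        other = [h for h in other if h.signature_acc not in LRR_SIGNATURES]
        cand = RocoCandidate(protein_id=pid, lrr_hits=sorted(lrr, key=lambda h: h.ali_start),
                             roc_hits=sorted(roc, key=lambda h: h.ali_start),
                             cor_hits=sorted(cor, key=lambda h: h.ali_start),
                             other_hits=sorted(other, key=lambda h: (h.signature_acc, h.ali_start)),
                             protein_length=proteome_lengths[pid])
        if not cand.n_terminal_lrr:
            logger.warning("candidate %s lacks N-terminal LRR ordering", pid)
            cand.group_label = UNCLASSIFIED
        else:
            cand.group_label = classify_group(cand)
            cand.conflict = _has_conflict(cand)
        candidates.append(cand)
    return candidates


def _signatures(candidate: RocoCandidate) -> set[str]:
    return {h.signature_acc
            for h in (candidate.lrr_hits + candidate.roc_hits
                      + candidate.cor_hits + candidate.other_hits)}


def _has_conflict(candidate: RocoCandidate) -> bool:
    sigs = _signatures(candidate)
    return (_peptidase_c_terminal(candidate)
            and SM_LRR in sigs and IPR_DUF900 in sigs)


def _peptidase_c_terminal(candidate: RocoCandidate) -> bool:
    roc_end = candidate.roc_span[1]
    return any(h.signature_acc == IPR_PEPTIDASE and h.ali_start > roc_end
               for h in candidate.other_hits)


def classify_group(candidate: RocoCandidate) -> str:
    """Architecture group of a candidate, precedence group3 > group4 > group1_2."""
    sigs = _signatures(candidate)
    if _peptidase_c_terminal(candidate):
        return GROUP3
    if SM_LRR in sigs and IPR_DUF900 in sigs:
        return GROUP4
    if IPR_LRR_TYPICAL in sigs or PF_LRR in sigs:
        return GROUP1_2
    return UNCLASSIFIED


@dataclass(frozen=True)
class Stat:
    min: float
    mean: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("min <= mean <= max violated")


@dataclass(frozen=True)
class FamilySummary:
    n_genes: int
    per_species: dict[str, int]
    mean_protein_length: float | None
    roc_length: Stat | None
    cor_positive: int
    cor_length: Stat | None
    lrr_hit_count: Stat | None
    lrr_unit_count: Stat | None
    exon_count: Stat | None
    group_counts: dict[str, int]


def _stat(values: Sequence[float]) -> Stat | None:
    if not values:
        return None
    return Stat(min=min(values), mean=mean(values), max=max(values))


def summarize_family(candidates: Sequence[RocoCandidate],
                     gene_models: Mapping[str, GeneModel] | None = None,
                     lrr_unit_counts: Mapping[str, int] | None = None,
                     species_of: Mapping[str, str] | None = None,
                     count_cds_exons: bool = True) -> FamilySummary:
    """Family-level descriptive statistics.

    ROC length uses the longest PF08477 hit per protein; the LRR motif
    count is reported both as Pfam hit rows and, when a detector run is
    supplied via ``lrr_unit_counts``, as qualifying repeat units. Exon
    counts default to CDS-bearing exons of the longest transcript
    (``count_cds_exons=False`` counts all exon rows).
    """
    if not candidates:
        raise ValueError("no candidates to summarize")
    per_species: dict[str, int] = defaultdict(int)
    for c in candidates:
        sp = species_of.get(c.protein_id, "unknown") if species_of else "all"
        per_species[sp] += 1
    lengths = [c.protein_length for c in candidates
               if c.protein_length is not None]
    exon_counts = []
    if gene_models:
        for c in candidates:
            gm = gene_models.get(c.protein_id)
            if gm is None:
                continue
            if count_cds_exons:
                n = max(len(t.cds_segments) for t in gm.transcripts)
            else:
                n = max(len(t.exons) for t in gm.transcripts)
            exon_counts.append(n)
    group_counts: dict[str, int] = defaultdict(int)
    for c in candidates:
        group_counts[c.group_label] += 1
    cor_lengths = [c.cor_length for c in candidates if c.cor_length]
    unit_counts = ([lrr_unit_counts[c.protein_id] for c in candidates
                    if c.protein_id in lrr_unit_counts]
                   if lrr_unit_counts else [])
    return FamilySummary(
        n_genes=len(candidates),
        per_species=dict(per_species),
        mean_protein_length=mean(lengths) if lengths else None,
        roc_length=_stat([c.roc_length for c in candidates]),
        cor_positive=sum(1 for c in candidates if c.cor_hits),
        cor_length=_stat(cor_lengths),
        lrr_hit_count=_stat([c.lrr_count for c in candidates]),
        lrr_unit_count=_stat(unit_counts),
        exon_count=_stat(exon_counts),
        group_counts=dict(group_counts),
    )
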