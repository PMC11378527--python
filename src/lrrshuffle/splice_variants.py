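"""Alternative-splicing catalogs of shuffled-LRR genes.

Transcripts of one gene are compared by the LRR exons they retain: each
combination is the ordered tuple of qualifying-exon genomic intervals
present in the transcript, so isoforms that differ only in non-LRR exons
collapse together by default (a strict mode compares full exon chains).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GeneModel
from .shuffle_detect import LrrExonCall


@dataclass(frozen=True)
class SpliceCatalog:
    gene_id: str
    combinations: dict[str, tuple[tuple[int, int], ...]]  # transcript -> exon tuple
    exon_usage: dict[tuple[int, int], int]
    jaccard: np.ndarray           # over sorted transcript ids
    transcript_order: tuple[str, ...]

    @property
    def n_transcripts(self) -> int:
        return len(self.combinations)

    @property
    def n_distinct_combinations(self) -> int:
        return len(set(self.combinations.values()))


def build_catalog(gene: GeneModel,
                  calls_per_transcript: Mapping[str, Sequence[LrrExonCall]],
                  strict: bool = False) -> SpliceCatalog:
    """Catalog LRR-exon combinations across a gene's transcripts.

    ``calls_per_transcript`` holds the detector output for each transcript.
    In strict mode the combination is the full CDS-exon chain rather than
    the qualifying-LRR subset.
    """
    order = tuple(sorted(t.transcript_id for t in gene.transcripts))
    combos: dict[str, tuple[tuple[int, int], ...]] = {}
    usage: Counter = Counter()
    for tid in order:
        calls = calls_per_transcript.get(tid, ())
        if strict:
            combo = tuple(c.interval for c in calls)
        else:
            combo = tuple(c.interval for c in calls if c.qualifies)
        combos[tid] = combo
        for interval in set(combo):
            usage[interval] += 1
    n = len(order)
    jac = np.ones((n, n))
    sets = [set(combos[t]) for t in order]
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            jac[i, j] = jac[j, i] = (
                len(sets[i] & sets[j]) / len(union) if union else 1.0
            )
    return SpliceCatalog(gene_id=gene.gene_id, combinations=combos,
                         exon_usage=dict(usage), jaccard=jac,
                         transcript_order=order)


def combination_capacity(n_exons: int, constraint: str = "any_subset") -> int:
    """Number of non-empty LRR-exon combinations a gene could splice.

    ``any_subset`` counts all non-empty subsets (2^n - 1); ``contiguous_runs``
    counts non-empty contiguous spans (n(n+1)/2).
    """
    if n_exons < 0:
        raise ValueError("n_exons must be >= 0")
    if constraint == "any_subset":
        return 2 ** n_exons - 1
    if constraint == "contiguous_runs":
        return n_exons * (n_exons + 1) // 2
    raise ValueError(f"unknown constraint {constraint!r}")
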