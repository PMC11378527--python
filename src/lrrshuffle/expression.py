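"""Differential-expression arithmetic and DEG classification.

Fold changes are plain log2 ratios of the provided normalized values (no
shrinkage, no renormalization); a gene is called differentially expressed
when ``|log2FC| > 1`` and ``p < 0.05`` by default. Matrices for heatmaps
are clustered hierarchically (average linkage, Euclidean) with
deterministic ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .genome_io import ExpressionRecord, parse_expression_table

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"


class UndefinedFoldChangeError(ValueError):
    def __init__(self, gene_id: str | None = None, condition: str | None = None):
        self.gene_id = gene_id
        self.condition = condition
        where = f" for {gene_id}/{condition}" if gene_id else ""
        super().__init__(f"fold change undefined on non-positive input{where}")


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    condition: str
    log2fc: float
    pvalue: float | None
    status: str
    fc_threshold: float
    p_threshold: float
    missing_pvalue: bool = False


def log2_fold_change(treated_value: float, control_value: float,
                     gene_id: str | None = None,
                     condition: str | None = None) -> float:
    """log2(treated / control); both values must be strictly positive."""
    if treated_value <= 0 or control_value <= 0:
        raise UndefinedFoldChangeError(gene_id, condition)
    return math.log2(treated_value / control_value)


def classify_deg(log2fc: float, pvalue: float | None,
                 fc_threshold: float = 1.0, p_threshold: float = 0.05) -> str:
    """Three-way DEG status: up / down / not_significant."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if pvalue is None:
        return NOT_SIGNIFICANT
    if pvalue < p_threshold and log2fc > fc_threshold:
        return UP
    if pvalue < p_threshold and log2fc < -fc_threshold:
        return DOWN
    return NOT_SIGNIFICANT


def call_degs(records: Iterable[ExpressionRecord], fc_threshold: float = 1.0,
              p_threshold: float = 0.05) -> list[DegCall]:
    calls = []
    for r in sorted(records, key=lambda r: (r.gene_id, r.condition)):
        fc = log2_fold_change(r.treated_value, r.control_value,
                              r.gene_id, r.condition)
        calls.append(DegCall(
            gene_id=r.gene_id, condition=r.condition, log2fc=fc,
            pvalue=r.pvalue,
            status=classify_deg(fc, r.pvalue, fc_threshold, p_threshold),
            fc_threshold=fc_threshold, p_threshold=p_threshold,
            missing_pvalue=r.pvalue is None))
    return calls


@dataclass(frozen=True)
class ClusteredMatrix:
    matrix: pd.DataFrame          # genes x conditions
    leaf_order: tuple[str, ...]   # gene ids in dendrogram order
    transform: str
    linkage_method: str = "average"
    metric: str = "euclidean"


def expression_matrix(records: Sequence[ExpressionRecord],
                      transform: str = "log2fc",
                      linkage_method: str = "average",
                      metric: str = "euclidean",
                      log10_offset: float = 1.0) -> ClusteredMatrix:
    """Gene x condition matrix plus a hierarchical-clustering leaf order.

    ``log2fc`` fills cells with log2(treated/control); ``log10_value``
    with log10(treated + offset). Rows and columns are sorted by label
    before clustering so the result is independent of input order; genes
    whose values are all missing are dropped with a warning.
    """
    if not records:
        raise ValueError("no expression records")
    if transform not in ("log2fc", "log10_value"):
        raise ValueError(f"unknown transform {transform!r}")
    cells = {}
    for r in sorted(records, key=lambda r: (r.gene_id, r.condition)):
        if transform == "log2fc":
            try:
                value = log2_fold_change(r.treated_value, r.control_value)
            except UndefinedFoldChangeError:
                value = np.nan
        else:
            value = math.log10(r.treated_value + log10_offset)
        cells[(r.gene_id, r.condition)] = value
    df = pd.Series(cells).unstack()
    df = df.sort_index(axis=0).sort_index(axis=1)
    all_missing = df.index[df.isna().all(axis=1)]
    if len(all_missing):
        import logging
        logging.getLogger(__name__).warning(
            "dropping all-missing gene rows: %s", list(all_missing))
        df = df.drop(index=all_missing)
    filled = df.fillna(0.0)
    if len(df) >= 2:
        z = linkage(pdist(filled.values, metric=metric),
                    method=linkage_method)
        order = tuple(df.index[i] for i in leaves_list(z))
    else:
        order = tuple(df.index)
    return ClusteredMatrix(matrix=df, leaf_order=order, transform=transform,
                           linkage_method=linkage_method, metric=metric)


def load_table1_fixture(block: str = "microarray") -> list[ExpressionRecord]:
    """Bundled expression fixtures: 'microarray', 'rpkm' or 'tpm'."""
    if block not in ("microarray", "rpkm", "tpm"):
        raise ValueError(f"unknown fixture block {block!r}")
    path = resources.files("lrrshuffle.fixtures") / f"table1_{block}.tsv"
    with resources.as_file(path) as p:
        return parse_expression_table(p)
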