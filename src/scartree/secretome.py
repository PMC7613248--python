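"""Secretome expression scoring across cell types.

Scores how much of each cell type's transcriptional output is devoted to
genes encoding secreted proteins (a user-supplied gene list), then builds
the clustered cell-type x gene summary matrices: depth-normalize each cell
to 10,000 transcripts, average per cell type, log-transform, keep genes
expressed at a mean of >= 10 in at least one type, z-score per gene across
cell types with a cap at 5 keeping genes that reach z > 2 somewhere, and
order both axes by Ward hierarchical clustering. Neuronal and myelin cells
are excluded from these summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 10_000
DEFAULT_EXCLUDE = ("neuronal", "myelin")

__all__ = [
    "normalize_per_cell",
    "secretome_fraction",
    "mean_log_expression_and_filter",
    "z_transform_capped",
    "ward_cluster",
    "WardResult",
]


def _check_nonneg(matrix: pd.DataFrame) -> None:
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression matrix has negative entries")


def normalize_per_cell(matrix: pd.DataFrame, scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Scale every cell (row) to ``scale`` total transcripts.

    Cells with zero counts are dropped with a warning. Within-cell gene
    proportions are preserved exactly.
    """
    _check_nonneg(matrix)
    totals = matrix.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("dropping %d zero-count cells", int(zero.sum()))
        matrix, totals = matrix.loc[~zero], totals[~zero]
    return matrix.div(totals, axis=0) * scale


def _restrict(
    matrix: pd.DataFrame, annotation: pd.DataFrame, exclude_types: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.Series]:
    ann = annotation.set_index("cell_barcode") if "cell_barcode" in annotation else annotation
    ann = ann.loc[ann.index.intersection(matrix.index)]
    keep = ~ann["cell_type"].isin(exclude_types)
    ann = ann[keep]
    return matrix.loc[ann.index], ann


def _geneset_in_matrix(matrix: pd.DataFrame, geneset: list[str]) -> list[str]:
    if not geneset:
        raise ValueError("empty secretome gene set")
    present = [g for g in geneset if g in matrix.columns]
    missing = len(geneset) - len(present)
    if missing:
        logger.info("%d secretome genes absent from the matrix", missing)
    return present


def secretome_fraction(
    matrix: pd.DataFrame,
    geneset: list[str],
    annotation: pd.DataFrame,
    scale: float = DEFAULT_SCALE,
    exclude_types: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> pd.Series:
    """Mean percentage of transcripts in the secretome gene set, per
    (cell type, time point) group.

    ``matrix`` must already be depth-normalized to ``scale``. Neuronal and
    myelin cells are excluded by default.
    """
    genes = _geneset_in_matrix(matrix, geneset)
    sub, ann = _restrict(matrix, annotation, exclude_types)
    pct = sub[genes].sum(axis=1) / scale * 100.0
    grouped = pct.groupby([ann["cell_type"], ann["timepoint"]]).mean()
    grouped.name = "secretome_pct"
    return grouped


def mean_log_expression_and_filter(
    matrix: pd.DataFrame,
    geneset: list[str],
    annotation: pd.DataFrame,
    min_mean: float = 10.0,
    exclude_types: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> pd.DataFrame:
    """log(1 + mean normalized expression) per cell type, secretome genes.

    Genes are kept iff their mean normalized expression reaches
    ``min_mean`` (inclusive) in at least one cell type.
    """
    genes = _geneset_in_matrix(matrix, geneset)
    sub, ann = _restrict(matrix, annotation, exclude_types)
    means = sub[genes].groupby(ann["cell_type"]).mean()
    keep = means.columns[(means >= min_mean).any(axis=0)]
    return np.log1p(means[keep])


def z_transform_capped(
    type_means: pd.DataFrame, cap: float = 5.0, min_z: float = 2.0
) -> pd.DataFrame:
    """Per-gene z-scores across cell types, capped from above.

    z uses the population standard deviation (ddof=0) over cell types;
    values above ``cap`` are set to ``cap``; genes are retained iff their
    maximum z exceeds ``min_z`` strictly. Zero-variance genes are dropped
    with a warning.
    """
    if len(type_means) < 2:
        raise ValueError("need at least two cell types to z-transform")
    mu = type_means.mean(axis=0)
    sd = type_means.std(axis=0, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("dropping %d zero-variance genes", int(flat.sum()))
    z = (type_means.loc[:, ~flat] - mu[~flat]) / sd[~flat]
    z = z.clip(upper=cap)
    keep = z.columns[(z > min_z).any(axis=0)]
    return z[keep]


@dataclass
class WardResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    ordered: pd.DataFrame  # input matrix with both axes in dendrogram order


def ward_cluster(matrix: pd.DataFrame) -> WardResult:
    """Ward hierarchical clustering of both axes (Euclidean distance)."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 matrix to cluster both axes")
    x = matrix.to_numpy(float)
    row_z = sch.linkage(x, method="ward")
    col_z = sch.linkage(x.T, method="ward")
    ordered = matrix.iloc[sch.leaves_list(row_z), sch.leaves_list(col_z)]
    return WardResult(row_linkage=row_z, col_linkage=col_z, ordered=ordered)
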