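"""Heat-map ordering: row z-scoring and (1 - Pearson) complete-linkage clustering."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class ClusterView:
    """Dendrogram and leaf order for one axis of a matrix.

    ``linkage`` is the standard (n-1) x 4 merge table; ``leaf_order`` is the
    dendrogram leaf sequence as labels; ``dropped`` lists zero-variance rows
    removed before computing correlations.
    """

    labels: list
    linkage: np.ndarray
    leaf_order: list
    dropped: list


def zscore_rows(matrix: pd.DataFrame | np.ndarray, ddof: int = 1):
    """Center and scale each row by its sample standard deviation.

    Zero-variance rows become all-zero with a warning. Requires at least two
    columns.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a matrix with at least two columns")
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows z-scored to all-zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd == 0, 0.0, (values - mu) / sd)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


def correlation_linkage(matrix: pd.DataFrame | np.ndarray, axis: str = "rows") -> ClusterView:
    """Complete-linkage agglomeration on d = 1 - Pearson correlation.

    ``axis`` chooses whether rows or columns are clustered. Zero-variance
    rows (undefined correlation) are dropped with a logged reason. Ties are
    broken by the library's deterministic merge ordering.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        labels = list(matrix.index) if axis == "rows" else list(matrix.columns)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = list(range(values.shape[0] if axis == "rows" else values.shape[1]))
    if axis == "cols":
        values = values.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    if values.shape[0] < 2:
        raise ValueError("need at least two observations to cluster")
    sd = values.std(axis=1)
    keep = sd > 0
    dropped = [lab for lab, ok in zip(labels, keep) if not ok]
    if dropped:
        logger.warning("dropped %d zero-variance rows before clustering: %s",
                       len(dropped), dropped[:10])
    values = values[keep]
    labels = [lab for lab, ok in zip(labels, keep) if ok]
    if values.shape[0] < 2:
        raise ValueError("fewer than two rows with non-zero variance")
    corr = np.corrcoef(values)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    order = [labels[i] for i in leaves_list(z)]
    return ClusterView(labels=labels, linkage=z, leaf_order=order, dropped=dropped)


def cluster_view(matrix: pd.DataFrame) -> dict:
    """Convenience: z-score rows, cluster both axes, return orders + matrix.

    Returns ``{"z": DataFrame, "rows": ClusterView, "cols": ClusterView}``
    with the z-scored matrix reindexed to dendrogram order.
    """
    z = zscore_rows(matrix)
    rows = correlation_linkage(z, axis="rows")
    cols = correlation_linkage(z, axis="cols")
    ordered = z.loc[rows.leaf_order, cols.leaf_order]
    return {"z": ordered, "rows": rows, "cols": cols}
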