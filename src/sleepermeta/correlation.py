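"""Correlation of gene expression with windowed sleep history and rebound.

Expression is gene-level TPM; genes with TPM < 1 in strictly more than half
of the samples are dropped, biological replicates are averaged per condition
and the mean is log2(x+1)-transformed (average first, then log). For each
gene and each nested window k = 1..12 h, a Pearson correlation is computed
across conditions between the condition-mean expression and either the
cumulative sleep in the k hours before sampling (history) or the cumulative
post-sampling sleep minus its matched baseline (rebound; circadian control
conditions excluded). Significance is Benjamini-Hochberg q < 0.05, adjusted
across genes separately within each window by default (optionally pooled
across all gene x window tests). A gene's summary sign comes from the
minimum-q significant window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import bh_adjust

logger = logging.getLogger(__name__)

SIG_Q = 0.05
POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"


@dataclass
class CorrelationResults:
    """Per-gene, per-window correlation statistics plus a per-gene summary.

    ``long`` columns: gene_id, window_hours, r, p, q.
    ``summary`` columns: gene_id, summary_sign, best_window, best_q,
    mixed_sign (True when significant windows disagree in sign).
    """

    target: str  # history | rebound
    long: pd.DataFrame
    summary: pd.DataFrame
    n_conditions: int

    def significant_genes(self, sign: str | None = None) -> set:
        sub = self.summary[self.summary["summary_sign"] != NONE]
        if sign is not None:
            sub = sub[sub["summary_sign"] == sign]
        return set(sub["gene_id"])


def filter_low_expression(tpm: pd.DataFrame, min_tpm: float = 1.0) -> pd.DataFrame:
    """Drop genes with TPM < min_tpm in strictly more than half of samples.

    A gene low in exactly half of an even sample count is retained (the
    exclusion rule is "more than 50%").
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least two samples")
    if tpm.empty:
        raise ValueError("empty expression matrix")
    low = (tpm.to_numpy() < min_tpm).sum(axis=1)
    keep = low <= tpm.shape[1] / 2
    return tpm.loc[keep]


def condition_means(
    tpm: pd.DataFrame,
    sample_condition: dict[str, str] | pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-condition mean TPM, then log2(mean + 1): averaging precedes the log."""
    mapping = pd.Series(sample_condition)
    missing = [s for s in tpm.columns if s not in mapping.index]
    if missing:
        raise ValueError(f"samples without a condition: {missing}")
    grouped = tpm.T.groupby(mapping.reindex(tpm.columns)).mean().T
    if (grouped.count(axis=0) == 0).any():
        raise ValueError("condition with no samples")
    return np.log2(grouped + pseudocount)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from the t transform
    (n-2 degrees of freedom). Inputs must have equal length >= 3 and
    non-zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _pearson_genes(expr: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided p of a genes x n matrix against y.

    Rows (or a y) with zero variance yield NaN and are skipped downstream.
    """
    n = y.size
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    xc = expr - expr.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[(sx == 0) | (sy == 0)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[np.isnan(r)] = np.nan
    return r, p


def _summarise(genes, windows, r_mat, q_mat) -> pd.DataFrame:
    rows = []
    for i, gene in enumerate(genes):
        q_row = q_mat[i]
        r_row = r_mat[i]
        sig = np.where(np.nan_to_num(q_row, nan=1.0) < SIG_Q)[0]
        if sig.size == 0:
            rows.append(
                {"gene_id": gene, "summary_sign": NONE, "best_window": 0,
                 "best_q": np.nan, "mixed_sign": False}
            )
            continue
        best = sig[np.argmin(q_row[sig])]  # ties resolved at the lowest window
        signs = np.sign(r_row[sig])
        mixed = bool((signs > 0).any() and (signs < 0).any())
        if mixed:
            warnings.warn(
                f"gene {gene}: significant windows disagree in sign; "
                "summary taken from the minimum-q window"
            )
        rows.append(
            {
                "gene_id": gene,
                "summary_sign": POSITIVE if r_row[best] > 0 else NEGATIVE,
                "best_window": int(windows[best]),
                "best_q": float(q_row[best]),
                "mixed_sign": mixed,
            }
        )
    return pd.DataFrame(rows)


def _correlate(ce: pd.DataFrame, metric: pd.DataFrame, target: str,
               bh_family: str) -> CorrelationResults:
    conds = [c for c in ce.columns if c in metric.index]
    if len(conds) < 3:
        raise ValueError("need at least 3 conditions for correlation")
    expr = ce[conds].to_numpy(dtype=float)
    genes = ce.index.to_numpy()
    windows = [int(k) for k in metric.columns]
    r_mat = np.empty((len(genes), len(windows)))
    p_mat = np.empty_like(r_mat)
    for j, k in enumerate(metric.columns):
        y = metric.loc[conds, k].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("%s window %s: constant metric, window skipped", target, k)
            r_mat[:, j] = np.nan
            p_mat[:, j] = np.nan
            continue
        r_mat[:, j], p_mat[:, j] = _pearson_genes(expr, y)
    q_mat = np.full_like(p_mat, np.nan)
    if bh_family == "per_window":
        for j in range(p_mat.shape[1]):
            ok = ~np.isnan(p_mat[:, j])
            if ok.any():
                q_mat[ok, j] = bh_adjust(p_mat[ok, j])
    elif bh_family == "pooled":
        ok = ~np.isnan(p_mat)
        if ok.any():
            q_mat[ok] = bh_adjust(p_mat[ok])
    else:
        raise ValueError(f"unknown BH family {bh_family!r}")
    long = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, len(windows)),
            "window_hours": np.tile(windows, len(genes)),
            "r": r_mat.ravel(),
            "p": p_mat.ravel(),
            "q": q_mat.ravel(),
        }
    )
    summary = _summarise(genes, windows, r_mat, q_mat)
    return CorrelationResults(target=target, long=long, summary=summary,
                              n_conditions=len(conds))


def correlate_history(
    ce: pd.DataFrame,
    history: pd.DataFrame,
    bh_family: str = "per_window",
) -> CorrelationResults:
    """Correlate condition-mean expression with cumulative pre-sampling sleep.

    ``ce`` is genes x conditions (log2 condition means); ``history`` is
    conditions x window (1..12 h, minutes asleep). All conditions with both
    expression and behaviour enter, including circadian timepoints.
    """
    return _correlate(ce, history, "history", bh_family)


def correlate_rebound(
    ce: pd.DataFrame,
    rebound: pd.DataFrame,
    exclude: set | None = None,
    bh_family: str = "per_window",
) -> CorrelationResults:
    """Correlate expression with per-window sleep rebound, dropping the
    excluded (circadian control) conditions before fitting."""
    exclude = set(exclude or ())
    keep = [c for c in rebound.index if c not in exclude]
    if not keep:
        raise ValueError("all conditions excluded")
    return _correlate(ce[[c for c in ce.columns if c in keep]],
                      rebound.loc[keep], "rebound", bh_family)


def history_rebound_intersections(
    hist: CorrelationResults, reb: CorrelationResults
) -> dict[str, set]:
    """Partition genes significant in BOTH analyses by their sign pattern.

    Keys: ``pos_neg`` (history-positive, rebound-negative), ``neg_pos``,
    ``pos_pos``, ``neg_neg``. The four cells are disjoint and cover exactly
    the doubly-significant genes.
    """
    cells = {"pos_neg": set(), "neg_pos": set(), "pos_pos": set(), "neg_neg": set()}
    h = dict(zip(hist.summary["gene_id"], hist.summary["summary_sign"]))
    r = dict(zip(reb.summary["gene_id"], reb.summary["summary_sign"]))
    for gene in set(h) & set(r):
        hs, rs = h[gene], r[gene]
        if hs == NONE or rs == NONE:
            continue
        key = f"{'pos' if hs == POSITIVE else 'neg'}_{'pos' if rs == POSITIVE else 'neg'}"
        cells[key].add(gene)
    return cells
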