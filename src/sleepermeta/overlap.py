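"""Pairwise overlap enrichment between experiments' gene lists.

For each unordered pair of experiments and each category (sleep or wake),
the two gene lists are restricted to the background — the intersection of
genes detected in both experiments (TPM > 0 in strictly more than half of
each experiment's samples) — and tested with a one-sided (enrichment,
upper-tail) Fisher's exact test. P-values are Benjamini-Hochberg adjusted
within each category family. The reported odds ratio is the sample
(unconditional) ratio (a*d)/(b*c) of the 2x2 table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class OverlapStat:
    exp_a: str
    exp_b: str
    category: str
    background_n: int
    a_n: int
    b_n: int
    overlap_n: int
    odds_ratio: float
    p: float
    q: float = float("nan")


def detect_background(tpm: pd.DataFrame, sample_ids: list[str], experiment_id: str = "") -> set:
    """Genes detected in an experiment: TPM > 0 in strictly more than half
    of the experiment's samples (ties at exactly half fail)."""
    if not sample_ids:
        raise ValueError(f"experiment {experiment_id!r}: no samples")
    sub = tpm[list(sample_ids)]
    nonzero = (sub.to_numpy() > 0).sum(axis=1)
    keep = nonzero > len(sample_ids) / 2
    return set(tpm.index[keep])


def hypergeom_tail(overlap_n, background_n, a_n, b_n):
    """Upper-tail hypergeometric probability P(K >= overlap_n) of drawing at
    least ``overlap_n`` of the ``a_n`` special genes in ``b_n`` draws from a
    background of ``background_n``. Vectorised over array inputs."""
    return stats.hypergeom.sf(np.asarray(overlap_n) - 1, background_n, a_n, b_n)


def _sample_odds_ratio(k: int, a_n: int, b_n: int, m: int) -> float:
    a = k
    b = a_n - k
    c = b_n - k
    d = m - a_n - b_n + k
    if a * d == 0:
        return 0.0
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def fisher_overlap(list_a: set, list_b: set, background: set, *,
                   exp_a: str = "A", exp_b: str = "B", category: str = "") -> OverlapStat:
    """One-sided Fisher enrichment of the overlap between two gene lists.

    Lists are clipped to the background (with a logged warning if anything
    fell outside); the p-value is the upper hypergeometric tail, so p = 1
    when the observed overlap is the least extreme possible.
    """
    if not background:
        raise ValueError("empty background")
    a = set(list_a) & background
    b = set(list_b) & background
    if len(a) != len(list_a) or len(b) != len(list_b):
        logger.warning(
            "%s vs %s: %d/%d list genes outside background were clipped",
            exp_a, exp_b, (len(list_a) - len(a)) + (len(list_b) - len(b)),
            len(list_a) + len(list_b),
        )
    m = len(background)
    k = len(a & b)
    p = float(hypergeom_tail(k, m, len(a), len(b)))
    return OverlapStat(
        exp_a=exp_a,
        exp_b=exp_b,
        category=category,
        background_n=m,
        a_n=len(a),
        b_n=len(b),
        overlap_n=k,
        odds_ratio=_sample_odds_ratio(k, len(a), len(b), m),
        p=min(p, 1.0),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1
    and returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_matrix(
    lists: dict[str, set],
    backgrounds: dict[str, set],
    category: str,
) -> list[OverlapStat]:
    """All unordered pairwise overlap tests for one category, BH-adjusted
    within the category family and flagged significant at q < 0.05.

    ``lists`` maps experiment -> gene list for this category; ``backgrounds``
    maps experiment -> detected gene set. Each pair's background is the
    intersection of the two experiments' detected sets.
    """
    exps = sorted(lists)
    if len(exps) < 2:
        raise ValueError("need at least two experiments")
    out = []
    for ea, eb in combinations(exps, 2):
        bg = backgrounds[ea] & backgrounds[eb]
        out.append(
            fisher_overlap(lists[ea], lists[eb], bg, exp_a=ea, exp_b=eb, category=category)
        )
    q = bh_adjust([s.p for s in out])
    for s, qv in zip(out, q):
        s.q = float(qv)
    return out


def overlap_frame(statistics: list[OverlapStat]) -> pd.DataFrame:
    """Long-form table of overlap statistics (one row per pair/category)."""
    rows = []
    for s in statistics:
        rows.append(
            {
                "exp_a": s.exp_a,
                "exp_b": s.exp_b,
                "category": s.category,
                "background_n": s.background_n,
                "a_n": s.a_n,
                "b_n": s.b_n,
                "overlap_n": s.overlap_n,
                "odds_ratio": s.odds_ratio,
                "p": s.p,
                "q": s.q,
                "significant": s.q < 0.05,
            }
        )
    return pd.DataFrame(rows)


def display_cell(s: OverlapStat) -> str:
    """Rounded odds ratio with the overlap count in parentheses, the display
    convention for pairwise matrix cells, e.g. ``"79 (23)"``."""
    od = "inf" if np.isinf(s.odds_ratio) else str(int(round(s.odds_ratio)))
    return f"{od} ({s.overlap_n})"


def upset_counts(membership: pd.DataFrame) -> dict[tuple, int]:
    """Exclusive intersection counts over a gene x experiment boolean table.

    Each gene is tallied once under the exact combination of experiments
    supporting it, so the counts sum to the number of genes.
    """
    counts: dict[tuple, int] = {}
    cols = list(membership.columns)
    arr = membership.to_numpy(dtype=bool)
    for row in arr:
        combo = tuple(c for c, flag in zip(cols, row) if flag)
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def upset_frame(counts: dict[tuple, int]) -> pd.DataFrame:
    rows = [
        {"combination": ";".join(combo), "degree": len(combo), "count": n}
        for combo, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])
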