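"""Per-experiment directional classification of genes as sleep- or wake-associated.

Each differential-expression contrast compares a manipulated condition to its
control and carries a polarity: genes up-regulated under sleep-promoting
manipulations, or down-regulated under wake-promoting ones, are sleep-
associated; the converse are wake-associated. Gates are strict:
|log2FC| > threshold and q < 0.05. Two named thresholds are used throughout:
FC1 (|log2FC| > 1) and FC0.5 (|log2FC| > 0.5).

Baseline circadian data contribute only through the cycling gate: transcripts
whose peak-trough amplitude passes the same fold-change cut at a rhythmicity
q < 0.05 become "cycling wild-cards" that can support either direction in the
cross-experiment consistency tally, but never a directional call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SLEEP_PROMOTING, WAKE_PROMOTING

MAX_Q = 0.05

CALL_SLEEP = "sleep"
CALL_WAKE = "wake"
CALL_WILDCARD = "cycling_wildcard"
CALL_NONE = "none"

CALL_COLUMNS = ["gene_id", "experiment_id", "call", "log2fc", "qvalue"]


@dataclass(frozen=True)
class Thresholds:
    """A named gate: minimum |log2FC| (strict >) and maximum q (strict <)."""

    name: str
    min_abs_log2fc: float
    max_q: float = MAX_Q

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0:
            raise ValueError("min_abs_log2fc must be positive")
        if not 0 < self.max_q < 1:
            raise ValueError("max_q must be in (0, 1)")

    @classmethod
    def from_name(cls, name: str) -> "Thresholds":
        cuts = {"FC1": 1.0, "FC0.5": 0.5}
        if name not in cuts:
            raise ValueError(f"unknown threshold {name!r}; expected one of {sorted(cuts)}")
        return cls(name=name, min_abs_log2fc=cuts[name])


FC1 = Thresholds.from_name("FC1")
FC05 = Thresholds.from_name("FC0.5")


@dataclass
class DETable:
    """One experiment's differential-expression table plus its polarity."""

    experiment_id: str
    polarity: str  # wake_promoting | sleep_promoting
    table: pd.DataFrame  # columns gene_id, log2fc, qvalue

    def __post_init__(self) -> None:
        if self.polarity not in (WAKE_PROMOTING, SLEEP_PROMOTING):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        required = {"gene_id", "log2fc", "qvalue"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")
        q = self.table["qvalue"]
        if ((q < 0) | (q > 1)).any():
            raise ValueError(f"{self.experiment_id}: q-values outside [0, 1]")
        if self.table["gene_id"].duplicated().any():
            raise ValueError(f"{self.experiment_id}: duplicate gene rows")


def classify_experiment(de: DETable, thr: Thresholds) -> pd.DataFrame:
    """Directional sleep/wake calls for one experiment.

    Returns one row per gene in the table with call in
    {sleep, wake, none}; genes failing the |log2FC|/q gate are "none"
    (tested, not regulated) — distinct from genes absent from the table,
    which receive no row and no judgement.
    """
    if de.polarity not in (WAKE_PROMOTING, SLEEP_PROMOTING):
        raise ValueError(f"unknown polarity {de.polarity!r}")
    lfc = de.table["log2fc"].to_numpy(dtype=float)
    q = de.table["qvalue"].to_numpy(dtype=float)
    passes = (np.abs(lfc) > thr.min_abs_log2fc) & (q < thr.max_q)
    up = lfc > 0
    if de.polarity == SLEEP_PROMOTING:
        call = np.where(up, CALL_SLEEP, CALL_WAKE)
    else:
        call = np.where(up, CALL_WAKE, CALL_SLEEP)
    call = np.where(passes, call, CALL_NONE)
    return pd.DataFrame(
        {
            "gene_id": de.table["gene_id"].to_numpy(),
            "experiment_id": de.experiment_id,
            "call": call,
            "log2fc": lfc,
            "qvalue": q,
        }
    )


def amplitude(expression_by_timepoint) -> float:
    """Peak-trough amplitude on the log2 scale: max minus min of the
    per-timepoint mean expression. Accepts one value or an array of
    replicate values per timepoint."""
    means = [float(np.mean(v)) for v in expression_by_timepoint]
    if len(means) < 2:
        raise ValueError("amplitude needs at least two timepoints")
    return max(means) - min(means)


def cycling_calls(
    cyc: pd.DataFrame,
    thr: Thresholds,
    experiment_id: str = "baseline",
) -> pd.DataFrame:
    """Wild-card calls for baseline-cycling transcripts.

    Genes with amplitude_log2 > threshold and q < 0.05 receive a
    cycling_wildcard call attributed to the baseline experiment; the same
    per-threshold fold-change cut as the DE gate is applied.
    """
    required = {"gene_id", "amplitude_log2", "qvalue"}
    if not required.issubset(cyc.columns):
        raise ValueError(f"cycling table needs columns {sorted(required)}")
    if (cyc["amplitude_log2"] < 0).any():
        raise ValueError("negative cycling amplitude")
    passes = (cyc["amplitude_log2"] > thr.min_abs_log2fc) & (cyc["qvalue"] < thr.max_q)
    sub = cyc.loc[passes]
    return pd.DataFrame(
        {
            "gene_id": sub["gene_id"].to_numpy(),
            "experiment_id": experiment_id,
            "call": CALL_WILDCARD,
            "log2fc": sub["amplitude_log2"].to_numpy(dtype=float),
            "qvalue": sub["qvalue"].to_numpy(dtype=float),
        }
    )


def de_lite(
    tpm: pd.DataFrame,
    condition_samples: list[str],
    control_samples: list[str],
    experiment_id: str,
    polarity: str,
    pseudocount: float = 1.0,
) -> DETable:
    """Simple two-sample differential expression on log2(TPM + 1).

    Per gene: log2fc is the mean log2(TPM + pseudocount) difference
    (condition minus control), p from Welch's unequal-variance t-test, and q
    by Benjamini-Hochberg over all genes. A lightweight stand-in for a full
    count-model DE fit, intended for synthetic data.
    """
    if len(condition_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs at least 2 replicates")
    a = np.log2(tpm[condition_samples].to_numpy(dtype=float) + pseudocount)
    b = np.log2(tpm[control_samples].to_numpy(dtype=float) + pseudocount)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    from .overlap import bh_adjust  # local import avoids a cycle at module load

    q = bh_adjust(p)
    table = pd.DataFrame({"gene_id": tpm.index.to_numpy(), "log2fc": lfc, "qvalue": q})
    return DETable(experiment_id=experiment_id, polarity=polarity, table=table)


def cycling_table_lite(
    tpm: pd.DataFrame,
    samples_by_timepoint: dict[float, list[str]],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Amplitude + rhythmicity q stand-in for an external cycling test.

    Amplitude is the peak-trough of per-timepoint mean log2(TPM + 1); the
    q-value comes from a one-way ANOVA across timepoints, BH-adjusted across
    genes. Real analyses supply rhythmicity q-values from a dedicated
    nonparametric test; only the amplitude gate is part of this package's
    contract, so any table with (gene_id, amplitude_log2, qvalue) works.
    """
    if len(samples_by_timepoint) < 2:
        raise ValueError("need at least two timepoints")
    groups = [
        np.log2(tpm[cols].to_numpy(dtype=float) + pseudocount)
        for _, cols in sorted(samples_by_timepoint.items())
    ]
    means = np.stack([g.mean(axis=1) for g in groups])
    amp = means.max(axis=0) - means.min(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    from .overlap import bh_adjust

    q = bh_adjust(p)
    return pd.DataFrame(
        {"gene_id": tpm.index.to_numpy(), "amplitude_log2": amp, "qvalue": q}
    )
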