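"""Cross-experiment consistent sleep/wake gene sets.

A gene joins the consistent sleep set when it is called sleep-associated in
at least ``min_support`` experiments and never wake-associated anywhere; the
wake set is defined symmetrically, so the two sets are disjoint by
construction. A baseline cycling wild-card counts one unit of support toward
either direction and never as a contradiction, but cannot by itself create
membership: at least one directional call is always required (an optional
strict mode requires all support to be directional).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .state_calls import CALL_NONE, CALL_SLEEP, CALL_WAKE, CALL_WILDCARD


@dataclass
class ConsistentSets:
    """The consistent sleep/wake gene sets with per-gene support bookkeeping.

    ``support`` has one row per gene with any call, columns: gene_id,
    n_sleep_calls, n_wake_calls, has_wildcard, set (sleep/wake/empty string),
    supporting_experiments (semicolon-joined, wildcard experiment included).
    """

    sleep_genes: set
    wake_genes: set
    support: pd.DataFrame
    min_support: int
    wildcard_counts: bool


def build_consistent_sets(
    calls: pd.DataFrame,
    min_support: int = 2,
    wildcard_counts: bool = True,
) -> ConsistentSets:
    """Aggregate per-experiment calls into consistent sleep and wake sets.

    ``calls`` is the concatenation of per-experiment call tables (columns
    gene_id, experiment_id, call, ...). Rows with call "none" mean the gene
    was tested but not regulated; they neither support nor contradict. An
    experiment contributes at most one call per gene.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    active = calls[calls["call"] != CALL_NONE]
    if active["experiment_id"].nunique() < 2 and not active.empty:
        raise ValueError("calls must come from at least two experiments")

    rows = []
    sleep_genes: set = set()
    wake_genes: set = set()
    # dedupe: one call per (gene, experiment)
    active = active.drop_duplicates(subset=["gene_id", "experiment_id", "call"])
    for gene, grp in active.groupby("gene_id", sort=True):
        sleep_exps = sorted(grp.loc[grp["call"] == CALL_SLEEP, "experiment_id"].unique())
        wake_exps = sorted(grp.loc[grp["call"] == CALL_WAKE, "experiment_id"].unique())
        wc_exps = sorted(grp.loc[grp["call"] == CALL_WILDCARD, "experiment_id"].unique())
        n_sleep, n_wake = len(sleep_exps), len(wake_exps)
        wildcard = len(wc_exps) > 0
        credit = 1 if (wildcard and wildcard_counts) else 0
        member = ""
        supporting: list = []
        if n_sleep >= 1 and n_wake == 0 and n_sleep + credit >= min_support:
            member = CALL_SLEEP
            sleep_genes.add(gene)
            supporting = sleep_exps + (wc_exps if credit else [])
        elif n_wake >= 1 and n_sleep == 0 and n_wake + credit >= min_support:
            member = CALL_WAKE
            wake_genes.add(gene)
            supporting = wake_exps + (wc_exps if credit else [])
        rows.append(
            {
                "gene_id": gene,
                "n_sleep_calls": n_sleep,
                "n_wake_calls": n_wake,
                "has_wildcard": wildcard,
                "set": member,
                "supporting_experiments": ";".join(supporting),
            }
        )
    support = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_sleep_calls",
            "n_wake_calls",
            "has_wildcard",
            "set",
            "supporting_experiments",
        ],
    )
    return ConsistentSets(
        sleep_genes=sleep_genes,
        wake_genes=wake_genes,
        support=support,
        min_support=min_support,
        wildcard_counts=wildcard_counts,
    )


def per_experiment_membership(sets: ConsistentSets, calls: pd.DataFrame) -> pd.DataFrame:
    """Gene x experiment boolean support table for the consistent genes.

    True where the experiment directionally supports the gene's set; a
    wild-card shows up under its own (baseline) experiment column. Feeds
    UpSet-style intersection counting.
    """
    members = sets.support[sets.support["set"] != ""]
    experiments = sorted(calls["experiment_id"].unique())
    if members.empty:
        return pd.DataFrame(columns=experiments, dtype=bool)
    active = calls[calls["call"] != CALL_NONE]
    table = pd.DataFrame(False, index=members["gene_id"].tolist(), columns=experiments)
    direction = dict(zip(members["gene_id"], members["set"]))
    for _, row in active.iterrows():
        gene = row["gene_id"]
        want = direction.get(gene)
        if want is None:
            continue
        if row["call"] == want or (row["call"] == CALL_WILDCARD and sets.wildcard_counts):
            table.loc[gene, row["experiment_id"]] = True
    table.index.name = "gene_id"
    return table
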