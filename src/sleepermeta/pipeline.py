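"""End-to-end orchestration: behaviour -> calls -> consistency -> overlap ->
correlation -> cluster views, from one config, with a JSON run manifest.

Every stage writes plain TSVs into the output directory; outputs contain no
timestamps, so a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_view
from .consistency import build_consistent_sets, per_experiment_membership
from .correlation import (
    condition_means,
    correlate_history,
    correlate_rebound,
    filter_low_expression,
    history_rebound_intersections,
)
from .design import StudyDesign
from .io import (
    fly_summary_frame,
    read_cycling_table,
    read_dam_dir,
    read_de_table,
    read_tpm_matrix,
    rebound_frame,
    windows_frame,
    write_tsv,
)
from .overlap import detect_background, overlap_frame, pairwise_matrix, upset_counts, upset_frame
from .state_calls import (
    CALL_SLEEP,
    CALL_WAKE,
    CALL_WILDCARD,
    DETable,
    Thresholds,
    classify_experiment,
    cycling_calls,
    cycling_table_lite,
    de_lite,
)
from .synthetic import behaviour_metrics

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and analysis switches for one pipeline run."""

    design_path: str
    dam_dir: str
    expr_path: str
    out_dir: str
    de_dir: str | None = None  # precomputed DE tables; else de_lite from TPM
    cycling_path: str | None = None  # precomputed cycling table; else ANOVA stand-in
    threshold: str = "FC1"
    bh_family: str = "per_window"
    wildcard_counts: bool = True
    min_support: int = 2
    overlap_lists: str = "calls"  # calls | consistent
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _de_tables(cfg: RunConfig, design: StudyDesign, tpm: pd.DataFrame) -> list[DETable]:
    sample_map = design.sample_ids()
    by_cond: dict[str, list[str]] = {}
    for s, c in sample_map.items():
        by_cond.setdefault(c, []).append(s)
    tables = []
    for exp in design.experiments:
        if cfg.de_dir is not None:
            path = Path(cfg.de_dir) / f"{exp.experiment_id}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing DE table {path}")
            tables.append(
                DETable(exp.experiment_id, exp.polarity, read_de_table(path))
            )
        else:
            tables.append(
                de_lite(
                    tpm,
                    by_cond[exp.condition_id],
                    by_cond[exp.control_id],
                    exp.experiment_id,
                    exp.polarity,
                )
            )
    return tables


def _cycling_table(cfg: RunConfig, design: StudyDesign, tpm: pd.DataFrame) -> pd.DataFrame:
    if cfg.cycling_path is not None:
        return read_cycling_table(cfg.cycling_path)
    sample_map = design.sample_ids()
    by_tp: dict[float, list[str]] = {}
    for cid in design.circadian_conditions:
        zt = design.condition(cid).sampling_zt_hours
        by_tp[zt] = [s for s, c in sample_map.items() if c == cid]
    if not by_tp:
        raise ValueError("design has no circadian-control conditions")
    return cycling_table_lite(tpm, by_tp)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write TSVs plus ``manifest.json``.

    Returns the manifest dict. Any stage failure raises :class:`StageError`
    naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "threshold": cfg.threshold,
        "bh_family": cfg.bh_family,
        "wildcard_counts": cfg.wildcard_counts,
        "min_support": cfg.min_support,
        "overlap_lists": cfg.overlap_lists,
        "counts": {},
    }
    counts = manifest["counts"]
    thr = Thresholds.from_name(cfg.threshold)

    # -- behaviour ---------------------------------------------------------
    try:
        design = StudyDesign.from_yaml(cfg.design_path)
        traces = read_dam_dir(cfg.dam_dir, design.dam_channel_map, design.lights_on)
        metrics = behaviour_metrics(traces, design)
        all_series = [s for ss in metrics.series.values() for s in ss]
        write_tsv(fly_summary_frame(all_series), out / "behavior" / "fly_summary.tsv")
        write_tsv(
            windows_frame(list(metrics.before.values()) + list(metrics.after.values())),
            out / "behavior" / "sleep_windows.tsv",
        )
        from .behavior import rebound_windows as _rw

        rebs = [
            _rw(metrics.after[c], metrics.baseline_after[c]) for c in metrics.after
        ]
        write_tsv(rebound_frame(rebs), out / "behavior" / "rebound_windows.tsv")
        counts["flies"] = len(all_series)
        counts["flies_dropped_dead"] = len(metrics.dropped_flies)
        counts["conditions"] = len(design.conditions)
    except Exception as e:  # noqa: BLE001 - stage contract names the stage
        raise StageError("behavior", e) from e

    # -- expression + state calls -----------------------------------------
    try:
        tpm = read_tpm_matrix(cfg.expr_path)
        de_tables = _de_tables(cfg, design, tpm)
        cyc = _cycling_table(cfg, design, tpm)
        for t in de_tables:
            write_tsv(t.table, out / "de" / f"{t.experiment_id}.tsv")
        write_tsv(cyc, out / "de" / "cycling.tsv")
        calls = pd.concat(
            [classify_experiment(t, thr) for t in de_tables]
            + [cycling_calls(cyc, thr)],
            ignore_index=True,
        )
        write_tsv(calls, out / "calls.tsv")
        counts["experiments"] = len(de_tables)
        counts["calls_directional"] = int(calls["call"].isin([CALL_SLEEP, CALL_WAKE]).sum())
        counts["calls_wildcard"] = int((calls["call"] == CALL_WILDCARD).sum())
    except Exception as e:
        raise StageError("state_calls", e) from e

    # -- consistency -------------------------------------------------------
    try:
        sets = build_consistent_sets(calls, cfg.min_support, cfg.wildcard_counts)
        write_tsv(sets.support, out / "consistent.tsv")
        membership = per_experiment_membership(sets, calls)
        write_tsv(membership.reset_index(), out / "membership.tsv")
        counts["consistent_sleep"] = len(sets.sleep_genes)
        counts["consistent_wake"] = len(sets.wake_genes)
    except Exception as e:
        raise StageError("consistency", e) from e

    # -- overlap enrichment ------------------------------------------------
    try:
        sample_map = design.sample_ids()
        backgrounds = {}
        lists_sleep: dict[str, set] = {}
        lists_wake: dict[str, set] = {}
        for t in de_tables:
            cond = next(e for e in design.experiments if e.experiment_id == t.experiment_id)
            samples = [s for s, c in sample_map.items()
                       if c in (cond.condition_id, cond.control_id)]
            backgrounds[t.experiment_id] = detect_background(tpm, samples, t.experiment_id)
            exp_calls = calls[calls["experiment_id"] == t.experiment_id]
            if cfg.overlap_lists == "consistent":
                exp_calls = exp_calls[exp_calls["gene_id"].isin(
                    sets.sleep_genes | sets.wake_genes)]
            lists_sleep[t.experiment_id] = set(
                exp_calls.loc[exp_calls["call"] == CALL_SLEEP, "gene_id"])
            lists_wake[t.experiment_id] = set(
                exp_calls.loc[exp_calls["call"] == CALL_WAKE, "gene_id"])
        # baseline cycling wild-cards enter both categories
        baseline_samples = [s for s, c in sample_map.items()
                            if c in design.circadian_conditions]
        if baseline_samples:
            backgrounds["baseline"] = detect_background(tpm, baseline_samples, "baseline")
            wc = set(calls.loc[calls["call"] == CALL_WILDCARD, "gene_id"])
            lists_sleep["baseline"] = wc
            lists_wake["baseline"] = wc
        stats = pairwise_matrix(lists_sleep, backgrounds, "sleep")
        stats += pairwise_matrix(lists_wake, backgrounds, "wake")
        write_tsv(overlap_frame(stats), out / "overlap" / "pairwise.tsv")
        write_tsv(upset_frame(upset_counts(membership)), out / "overlap" / "upset.tsv")
        counts["overlap_pairs"] = len(stats)
    except Exception as e:
        raise StageError("overlap", e) from e

    # -- correlation -------------------------------------------------------
    try:
        filtered = filter_low_expression(tpm)
        ce = condition_means(filtered, sample_map)
        hist = correlate_history(ce, metrics.history, cfg.bh_family)
        reb = correlate_rebound(
            ce, metrics.rebound, set(design.circadian_conditions), cfg.bh_family
        )
        cells = history_rebound_intersections(hist, reb)
        for res, name in ((hist, "history"), (reb, "rebound")):
            write_tsv(res.long.round(6), out / "corr" / f"{name}_long.tsv")
            write_tsv(res.summary, out / "corr" / f"{name}_summary.tsv")
        inter_rows = [
            {"cell": cell, "gene_id": g}
            for cell in ("pos_neg", "neg_pos", "pos_pos", "neg_neg")
            for g in sorted(cells[cell])
        ]
        write_tsv(
            pd.DataFrame(inter_rows, columns=["cell", "gene_id"]),
            out / "corr" / "intersections.tsv",
        )
        counts["genes_after_tpm_filter"] = int(filtered.shape[0])
        counts["history_significant"] = len(hist.significant_genes())
        counts["rebound_significant"] = len(reb.significant_genes())
        counts["intersections"] = {k: len(v) for k, v in cells.items()}
    except Exception as e:
        raise StageError("sleep_correlation", e) from e

    # -- cluster views -----------------------------------------------------
    try:
        for res, name in ((hist, "history"), (reb, "rebound")):
            genes = sorted(res.significant_genes())
            if len(genes) >= 2:
                view = cluster_view(ce.loc[genes])
                order = pd.DataFrame(
                    {
                        "gene_id": view["rows"].leaf_order,
                        "position": range(len(view["rows"].leaf_order)),
                    }
                )
                write_tsv(order, out / "cluster" / f"{name}_gene_order.tsv")
                write_tsv(
                    view["z"].round(6).reset_index(names="gene_id"),
                    out / "cluster" / f"{name}_zscores.tsv",
                )
            counts[f"cluster_{name}_genes"] = len(genes)
    except Exception as e:
        raise StageError("cluster", e) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        for stage in ("behavior", "state_calls", "consistency", "overlap",
                      "sleep_correlation", "cluster"):
            fh.write(f"stage {stage}: ok\n")
    return manifest


def simulate_to_dir(
    out_dir,
    seed: int,
    n_genes: int = 2000,
    replicates: int = 3,
    flies_per_condition: int = 16,
    **truth_kwargs,
) -> "RunConfig":
    """Run the synthetic generator and write a complete input bundle:
    DAM monitor files, design.yaml, tpm.tsv and truth.tsv. Returns a
    RunConfig pointing ``run_all`` at the bundle."""
    from .io import write_dam_files, write_tpm_matrix
    from .synthetic import simulate_study

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_study(
        seed,
        n_genes=n_genes,
        replicates=replicates,
        flies_per_condition=flies_per_condition,
        **truth_kwargs,
    )
    channel_map = write_dam_files(sim.traces, out / "dam", sim.design.lights_on)
    sim.design.dam_channel_map = channel_map
    sim.design.to_yaml(out / "design.yaml")
    write_tpm_matrix(sim.tpm, out / "tpm.tsv")
    write_tsv(sim.truth.table, out / "truth.tsv")
    return RunConfig(
        design_path=str(out / "design.yaml"),
        dam_dir=str(out / "dam"),
        expr_path=str(out / "tpm.tsv"),
        out_dir=str(out / "results"),
        seed=int(seed),
    )
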