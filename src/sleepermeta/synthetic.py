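"""Synthetic behaviour and expression with planted ground truth.

The generator emulates the study's condition panel: per-minute fly activity
from a two-state semi-Markov process with geometric bout lengths and
light/dark-modulated sleep propensity; mechanical deprivation forces
activity, thermogenetic sleep promotion forces quiescence, and the
post-perturbation half-day is regenerated with sleep propensity scaled by
the sleep actually lost (or gained), producing rebound and antirebound.

Expression is TPM with Gaussian noise on the log2 scale. Planted gene
classes: wake-induced, sleep-induced, cycling (sinusoidal in sampling ZT),
temperature-responsive, activation-responsive (tracks thermogenetic
activation regardless of its sleep polarity — a deliberate method confound),
and genes linearly coupled to a specific sleep-history or rebound window,
plus nulls. A subset of coupled genes carries opposite-signed coupling to
the other metric, populating the discordant history x rebound intersection
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import (
    MINUTES_PER_DAY,
    ActivityTrace,
    SleepSeries,
    call_sleep,
    cumulative_windows,
    exclude_dead,
    passes_sd_filter,
    rebound_windows,
    sd_efficiency,
    total_sleep,
)
from .design import FORCE_SLEEP, FORCE_WAKE, StudyDesign, default_panel

CLASS_WAKE = "wake_induced"
CLASS_SLEEP = "sleep_induced"
CLASS_CYCLING = "cycling"
CLASS_TEMP = "temperature_responsive"
CLASS_ACT = "activation_responsive"
CLASS_HISTORY = "history_coupled"
CLASS_REBOUND = "rebound_coupled"
CLASS_NULL = "null"

PLANTED_CLASSES = [
    CLASS_WAKE, CLASS_SLEEP, CLASS_CYCLING, CLASS_TEMP,
    CLASS_ACT, CLASS_HISTORY, CLASS_REBOUND,
]

# bout-length means (minutes); day = ZT0-12, night = ZT12-24
DAY_WAKE_MEAN = 60.0
DAY_SLEEP_MEAN = 12.0
NIGHT_WAKE_MEAN = 12.0
NIGHT_SLEEP_MEAN = 40.0

RECORD_DAYS = 3


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth plus the generative noise parameters."""

    table: pd.DataFrame
    effect_log2: float
    noise_sigma_log2: float
    coupling_beta: float
    seed: int

    def genes_of_class(self, gene_class: str) -> list[str]:
        t = self.table
        return t.loc[t["gene_class"] == gene_class, "gene_id"].tolist()


@dataclass
class BehaviorMetrics:
    """Condition-level sleep metrics derived from (synthetic or real) traces."""

    history: pd.DataFrame  # condition x window (1..12), minutes asleep before sampling
    rebound: pd.DataFrame  # condition x window, post minus matched baseline
    before: dict = field(default_factory=dict)  # condition -> SleepWindows
    after: dict = field(default_factory=dict)
    baseline_after: dict = field(default_factory=dict)
    series: dict = field(default_factory=dict)  # condition -> list[SleepSeries]
    sd_pass_fraction: dict = field(default_factory=dict)
    dropped_flies: list = field(default_factory=list)


def make_truth(
    n_genes: int = 2000,
    seed: int = 0,
    effect_log2: float = 2.0,
    noise_sigma_log2: float = 0.25,
    coupling_beta: float = 2.0,
    class_counts: dict[str, int] | None = None,
    n_opposite: int = 20,
) -> SyntheticTruth:
    """Assign planted classes and coupling parameters to ``n_genes`` genes.

    Default: 100 genes per planted class, the remainder null. ``n_opposite``
    history-coupled genes get an opposite-signed rebound coupling (and vice
    versa), emulating genes that track waking history and predict rebound.
    """
    if class_counts is None:
        # 100 per class at the default 2,000-gene scale; shrink proportionally
        # for smaller matrices so at least half the genes stay null
        per_class = min(100, max(1, n_genes // (2 * len(PLANTED_CLASSES))))
        class_counts = {c: per_class for c in PLANTED_CLASSES}
    n_planted = sum(class_counts.values())
    if n_planted > n_genes:
        raise ValueError("more planted genes than total genes")
    rng = np.random.default_rng([int(seed), 7])
    classes: list[str] = []
    for c in PLANTED_CLASSES:
        classes.extend([c] * class_counts.get(c, 0))
    classes.extend([CLASS_NULL] * (n_genes - n_planted))
    width = max(4, len(str(n_genes)))
    table = pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(n_genes)],
            "gene_class": classes,
            "effect_log2": np.where(np.isin(classes, PLANTED_CLASSES), effect_log2, 0.0),
            "phase_h": 0.0,
            "history_beta": 0.0,
            "history_window": 0,
            "rebound_beta": 0.0,
            "rebound_window": 0,
        }
    )
    cyc = table["gene_class"] == CLASS_CYCLING
    table.loc[cyc, "phase_h"] = rng.uniform(0, 24, int(cyc.sum()))
    # couplings are planted on 3..12 h windows only: across conditions the
    # 1-2 h windows carry almost no between-condition variance, so a coupling
    # planted there is unrecoverable by construction rather than by noise
    hist = np.flatnonzero(table["gene_class"] == CLASS_HISTORY)
    table.loc[hist, "history_beta"] = coupling_beta
    table.loc[hist, "history_window"] = rng.integers(3, 13, hist.size)
    reb = np.flatnonzero(table["gene_class"] == CLASS_REBOUND)
    table.loc[reb, "rebound_beta"] = coupling_beta
    table.loc[reb, "rebound_window"] = rng.integers(3, 13, reb.size)
    k_h = min(n_opposite, hist.size)
    table.loc[hist[:k_h], "rebound_beta"] = -coupling_beta
    table.loc[hist[:k_h], "rebound_window"] = rng.integers(3, 13, k_h)
    k_r = min(n_opposite, reb.size)
    table.loc[reb[:k_r], "history_beta"] = -coupling_beta
    table.loc[reb[:k_r], "history_window"] = rng.integers(3, 13, k_r)
    return SyntheticTruth(
        table=table,
        effect_log2=effect_log2,
        noise_sigma_log2=noise_sigma_log2,
        coupling_beta=coupling_beta,
        seed=int(seed),
    )


def _gen_bouts(rng, n: int, t0_abs: int, sleep_factor: float = 1.0) -> np.ndarray:
    """Alternating wake/sleep bouts with geometric durations; the phase at a
    bout's start picks day vs night means. ``sleep_factor`` scales sleep-bout
    length up and wake-bout length down (rebound pressure)."""
    out = np.zeros(n, dtype=bool)
    night0 = (t0_abs % MINUTES_PER_DAY) >= 720
    p_sleep0 = (
        NIGHT_SLEEP_MEAN / (NIGHT_SLEEP_MEAN + NIGHT_WAKE_MEAN)
        if night0
        else DAY_SLEEP_MEAN / (DAY_SLEEP_MEAN + DAY_WAKE_MEAN)
    )
    asleep = bool(rng.random() < p_sleep0)
    t = 0
    while t < n:
        night = ((t0_abs + t) % MINUTES_PER_DAY) >= 720
        if asleep:
            mean = (NIGHT_SLEEP_MEAN if night else DAY_SLEEP_MEAN) * sleep_factor
        else:
            mean = max(2.0, (NIGHT_WAKE_MEAN if night else DAY_WAKE_MEAN) / sleep_factor)
        dur = int(rng.geometric(1.0 / max(mean, 1.001)))
        out[t:t + dur] = asleep
        t += dur
        asleep = not asleep
    return out


def generate_behavior(
    design: StudyDesign,
    seed: int,
    days: int = RECORD_DAYS,
) -> list[ActivityTrace]:
    """Per-fly activity traces for every condition in the design.

    Deterministic for a fixed seed. Forced-wake perturbations overwrite the
    interval with activity (every minute has at least one count, so the
    efficiency filter holds for essentially all flies); forced-sleep
    perturbations impose quiescence. The 12 h after a perturbation is
    regenerated with sleep propensity scaled by the fly's own realised sleep
    loss, yielding rebound (or antirebound after sleep induction).
    """
    rng = np.random.default_rng([int(seed), 17])
    n_min = days * MINUTES_PER_DAY
    traces: list[ActivityTrace] = []
    for cond in design.conditions:
        ps, pe = cond.perturb_start_min, cond.perturb_end_min
        for i in range(design.flies_per_condition):
            asleep = _gen_bouts(rng, n_min, 0)
            if ps is not None and cond.forced_state is not None:
                base_sleep = int(asleep[ps - MINUTES_PER_DAY:pe - MINUTES_PER_DAY].sum())
                asleep[ps:pe] = cond.forced_state == FORCE_SLEEP
                lost = base_sleep - int(asleep[ps:pe].sum())
                factor = float(np.clip(1.0 + 2.5 * lost / 720.0, 0.3, 3.5))
                reb_end = min(pe + 720, n_min)
                if reb_end > pe:
                    asleep[pe:reb_end] = _gen_bouts(rng, reb_end - pe, pe, factor)
            counts = np.where(asleep, 0, 1 + rng.poisson(1.2, n_min)).astype(np.int64)
            if ps is not None and cond.forced_state == FORCE_WAKE:
                counts[ps:pe] = 1 + rng.poisson(2.0, pe - ps)
            if cond.perturb_start_min is not None and cond.temperature_c == 29.0:
                temp = np.full(n_min, 21.0)
                temp[ps:pe] = 29.0
            else:
                temp = np.full(n_min, cond.temperature_c)
            traces.append(
                ActivityTrace(
                    fly_id=f"{cond.condition_id}_f{i:02d}",
                    condition_id=cond.condition_id,
                    counts=counts,
                    t0=0,
                    temperature_c=temp,
                )
            )
    return traces


def behaviour_metrics(
    traces: list[ActivityTrace],
    design: StudyDesign,
    min_bout_minutes: int = 5,
    sd_threshold: float = 0.90,
) -> BehaviorMetrics:
    """Condition-level sleep history and rebound windows from raw traces.

    Applies dead-fly exclusion, calls sleep, applies the >90% deprivation
    (or sleep-promotion) efficiency filter to perturbed conditions, then
    averages the nested 1..12 h windows over the remaining flies. Rebound is
    the post-sampling windows minus the matched windows 24 h earlier.
    """
    kept, dropped = exclude_dead(traces)
    by_cond: dict[str, list[SleepSeries]] = {}
    for tr in kept:
        by_cond.setdefault(tr.condition_id, []).append(
            call_sleep(tr, min_bout_minutes)
        )
    metrics = BehaviorMetrics(history=None, rebound=None, dropped_flies=dropped)
    hist_rows, reb_rows = {}, {}
    for cond in design.conditions:
        series = by_cond.get(cond.condition_id, [])
        if not series:
            raise ValueError(f"no flies for condition {cond.condition_id}")
        ps, pe = cond.perturb_start_min, cond.perturb_end_min
        if ps is not None and cond.forced_state == FORCE_WAKE:
            eff = [sd_efficiency(s, s, (ps, pe)) for s in series]
            passing = [s for s, e in zip(series, eff) if passes_sd_filter(e, sd_threshold)]
            metrics.sd_pass_fraction[cond.condition_id] = len(passing) / len(series)
            series = passing or series
        elif ps is not None and cond.forced_state == FORCE_SLEEP:
            frac = [total_sleep(s, ps, pe) / (pe - ps) for s in series]
            passing = [s for s, f in zip(series, frac) if f > sd_threshold]
            metrics.sd_pass_fraction[cond.condition_id] = len(passing) / len(series)
            series = passing or series
        t = cond.sampling_time_min
        before = cumulative_windows(series, t, "before", cond.condition_id)
        after = cumulative_windows(series, t, "after", cond.condition_id)
        base_after = cumulative_windows(
            series, t - MINUTES_PER_DAY, "after", cond.condition_id
        )
        reb = rebound_windows(after, base_after)
        metrics.series[cond.condition_id] = series
        metrics.before[cond.condition_id] = before
        metrics.after[cond.condition_id] = after
        metrics.baseline_after[cond.condition_id] = base_after
        hist_rows[cond.condition_id] = before.minutes_asleep
        reb_rows[cond.condition_id] = reb.rebound_minutes
    windows = list(range(1, 13))
    metrics.history = pd.DataFrame.from_dict(hist_rows, orient="index", columns=windows)
    metrics.rebound = pd.DataFrame.from_dict(reb_rows, orient="index", columns=windows)
    return metrics


def _standardise(values: np.ndarray) -> tuple[float, float]:
    mu = float(values.mean())
    sd = float(values.std())
    return mu, (sd if sd > 0 else 1.0)


def generate_expression(
    design: StudyDesign,
    truth: SyntheticTruth,
    history: pd.DataFrame,
    rebound: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Gene x sample TPM matrix with the planted class effects.

    On the log2 scale each sample is: per-gene baseline (uniform 3..8)
    + class effect + Gaussian noise(sigma). Coupled genes add
    beta * standardised(condition metric at their window); rebound couplings
    are standardised over the non-circadian conditions the rebound analysis
    actually uses. TPM = 2^x - 1, clipped at 0.
    """
    rng = np.random.default_rng([int(seed), 29])
    conds = design.condition_ids
    n_c = len(conds)
    t = truth.table
    n_g = len(t)
    base = rng.uniform(3.0, 8.0, n_g)
    # coupled genes ride a wide linear signal (up to ~2 beta in log2 units);
    # anchor them high enough that TPM = 2^x - 1 never clips the signal away
    coupled = (t["history_beta"] != 0) | (t["rebound_beta"] != 0)
    base[coupled.to_numpy()] = 7.0 + (base[coupled.to_numpy()] - 3.0) * 0.6

    wake_score = np.zeros(n_c)
    temp_score = np.zeros(n_c)
    act_score = np.zeros(n_c)
    zt_h = np.zeros(n_c)
    for j, cid in enumerate(conds):
        cond = design.condition(cid)
        if cond.manipulation in ("mech_sd", "thermo_wake"):
            wake_score[j] = 1.0
        elif cond.manipulation == "thermo_sleep":
            wake_score[j] = -1.0
        temp_score[j] = (cond.temperature_c - 25.0) / 4.0
        act_score[j] = 1.0 if cond.manipulation in ("thermo_wake", "thermo_sleep") else 0.0
        zt_h[j] = cond.sampling_zt_hours

    signal = np.zeros((n_g, n_c))
    cls = t["gene_class"].to_numpy()
    eff = t["effect_log2"].to_numpy()
    signal[cls == CLASS_WAKE] = np.outer(eff[cls == CLASS_WAKE], wake_score)
    signal[cls == CLASS_SLEEP] = np.outer(eff[cls == CLASS_SLEEP], -wake_score)
    signal[cls == CLASS_TEMP] = np.outer(eff[cls == CLASS_TEMP], temp_score)
    signal[cls == CLASS_ACT] = np.outer(eff[cls == CLASS_ACT], act_score)
    cyc = cls == CLASS_CYCLING
    if cyc.any():
        phase = t.loc[cyc, "phase_h"].to_numpy()
        signal[cyc] = (eff[cyc] / 2.0)[:, None] * np.cos(
            2.0 * np.pi * (zt_h[None, :] - phase[:, None]) / 24.0
        )

    circadian = set(design.circadian_conditions)
    reb_conds = [c for c in conds if c not in circadian]
    hist_std = {}
    for k in history.columns:
        v = history.loc[conds, k].to_numpy(dtype=float)
        mu, sd = _standardise(v)
        hist_std[int(k)] = (v - mu) / sd
    reb_std = {}
    for k in rebound.columns:
        v_fit = rebound.loc[reb_conds, k].to_numpy(dtype=float)
        mu, sd = _standardise(v_fit)
        reb_std[int(k)] = (rebound.loc[conds, k].to_numpy(dtype=float) - mu) / sd

    hb = t["history_beta"].to_numpy()
    hw = t["history_window"].to_numpy()
    for i in np.flatnonzero(hb != 0):
        signal[i] += hb[i] * hist_std[int(hw[i])]
    rb = t["rebound_beta"].to_numpy()
    rw = t["rebound_window"].to_numpy()
    for i in np.flatnonzero(rb != 0):
        signal[i] += rb[i] * reb_std[int(rw[i])]

    sample_ids = list(design.sample_ids())
    cond_index = {c: j for j, c in enumerate(conds)}
    cols = np.array([cond_index[design.sample_ids()[s]] for s in sample_ids])
    x = base[:, None] + signal[:, cols]
    if truth.noise_sigma_log2 > 0:
        x = x + rng.normal(0.0, truth.noise_sigma_log2, x.shape)
    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    return pd.DataFrame(tpm, index=t["gene_id"].to_numpy(), columns=sample_ids)


def truth_report(
    truth: SyntheticTruth,
    consistent=None,
    history_results=None,
    rebound_results=None,
    cycling_genes: set | None = None,
) -> pd.DataFrame:
    """Recovery metrics per planted class against pipeline outputs.

    Sensitivity is the fraction of a class recovered by its stage; the false
    discovery proxy counts only null-class genes among the recoveries, and
    null_fp_rate is the fraction of all null genes falsely recovered.
    """
    t = truth.table
    nulls = set(t.loc[t["gene_class"] == CLASS_NULL, "gene_id"])
    rows = []

    def add(stage, gene_class, planted, recovered_set):
        planted = set(planted)
        hits = planted & recovered_set
        n_null_fp = len(nulls & recovered_set)
        rows.append(
            {
                "stage": stage,
                "gene_class": gene_class,
                "n_planted": len(planted),
                "n_recovered": len(hits),
                "sensitivity": len(hits) / len(planted) if planted else float("nan"),
                "set_size": len(recovered_set),
                "n_null_fp": n_null_fp,
                "fdr_null": n_null_fp / len(recovered_set) if recovered_set else 0.0,
                "null_fp_rate": n_null_fp / len(nulls) if nulls else 0.0,
            }
        )

    if consistent is not None:
        add("consistent_wake", CLASS_WAKE, truth.genes_of_class(CLASS_WAKE),
            set(consistent.wake_genes))
        add("consistent_sleep", CLASS_SLEEP, truth.genes_of_class(CLASS_SLEEP),
            set(consistent.sleep_genes))
    if history_results is not None:
        planted = t.loc[t["gene_class"] == CLASS_HISTORY, "gene_id"]
        recovered = history_results.significant_genes("positive")
        add("history", CLASS_HISTORY, planted,
            recovered | history_results.significant_genes("negative"))
        rows[-1]["n_recovered"] = len(set(planted) & recovered)
        rows[-1]["sensitivity"] = rows[-1]["n_recovered"] / max(len(planted), 1)
        rows[-1]["null_fp_rate"] = (
            len(nulls & history_results.significant_genes()) / len(nulls) if nulls else 0.0
        )
    if rebound_results is not None:
        planted = t.loc[t["gene_class"] == CLASS_REBOUND, "gene_id"]
        recovered = rebound_results.significant_genes("positive")
        add("rebound", CLASS_REBOUND, planted,
            recovered | rebound_results.significant_genes("negative"))
        rows[-1]["n_recovered"] = len(set(planted) & recovered)
        rows[-1]["sensitivity"] = rows[-1]["n_recovered"] / max(len(planted), 1)
        rows[-1]["null_fp_rate"] = (
            len(nulls & rebound_results.significant_genes()) / len(nulls) if nulls else 0.0
        )
    if cycling_genes is not None:
        add("cycling_gate", CLASS_CYCLING, truth.genes_of_class(CLASS_CYCLING),
            set(cycling_genes))
    return pd.DataFrame(rows)


@dataclass
class RecoveryRun:
    """One simulated study pushed through the full analysis, with its report."""

    sim: "SimulatedStudy"
    sets: object  # ConsistentSets
    history: object  # CorrelationResults
    rebound: object
    cells: dict
    report: pd.DataFrame


def evaluate_recovery(
    seed: int,
    threshold: str = "FC1",
    bh_family: str = "per_window",
    **sim_kwargs,
) -> RecoveryRun:
    """Simulate the default study and run every analysis stage in memory,
    returning per-class recovery metrics against the planted truth."""
    from .consistency import build_consistent_sets
    from .correlation import (
        condition_means,
        correlate_history,
        correlate_rebound,
        filter_low_expression,
        history_rebound_intersections,
    )
    from .state_calls import (
        Thresholds,
        classify_experiment,
        cycling_calls,
        cycling_table_lite,
        de_lite,
    )

    sim = simulate_study(seed, **sim_kwargs)
    design = sim.design
    sample_map = design.sample_ids()
    by_cond: dict[str, list[str]] = {}
    for s, c in sample_map.items():
        by_cond.setdefault(c, []).append(s)
    thr = Thresholds.from_name(threshold)
    frames = [
        classify_experiment(
            de_lite(sim.tpm, by_cond[e.condition_id], by_cond[e.control_id],
                    e.experiment_id, e.polarity),
            thr,
        )
        for e in design.experiments
    ]
    by_tp = {
        design.condition(c).sampling_zt_hours: by_cond[c]
        for c in design.circadian_conditions
    }
    cyc = cycling_table_lite(sim.tpm, by_tp)
    frames.append(cycling_calls(cyc, thr))
    calls = pd.concat(frames, ignore_index=True)
    sets = build_consistent_sets(calls)
    ce = condition_means(filter_low_expression(sim.tpm), sample_map)
    hist = correlate_history(ce, sim.metrics.history, bh_family)
    reb = correlate_rebound(
        ce, sim.metrics.rebound, set(design.circadian_conditions), bh_family
    )
    cells = history_rebound_intersections(hist, reb)
    gate = set(
        cyc.loc[(cyc["amplitude_log2"] > thr.min_abs_log2fc)
                & (cyc["qvalue"] < thr.max_q), "gene_id"]
    )
    report = truth_report(sim.truth, sets, hist, reb, cycling_genes=gate)
    return RecoveryRun(sim=sim, sets=sets, history=hist, rebound=reb,
                       cells=cells, report=report)


@dataclass
class SimulatedStudy:
    """An in-memory simulation bundle: design, traces, metrics, truth, TPM."""

    design: StudyDesign
    traces: list[ActivityTrace]
    metrics: BehaviorMetrics
    truth: SyntheticTruth
    tpm: pd.DataFrame
    seed: int


def simulate_study(
    seed: int,
    n_genes: int = 2000,
    replicates: int = 3,
    flies_per_condition: int = 16,
    effect_log2: float = 2.0,
    noise_sigma_log2: float = 0.25,
    coupling_beta: float = 2.0,
    class_counts: dict[str, int] | None = None,
    n_opposite: int = 20,
) -> SimulatedStudy:
    """Generate the default study end to end in memory (no files)."""
    design = default_panel(replicates=replicates, flies_per_condition=flies_per_condition)
    traces = generate_behavior(design, seed)
    metrics = behaviour_metrics(traces, design)
    truth = make_truth(
        n_genes=n_genes,
        seed=seed,
        effect_log2=effect_log2,
        noise_sigma_log2=noise_sigma_log2,
        coupling_beta=coupling_beta,
        class_counts=class_counts,
        n_opposite=n_opposite,
    )
    tpm = generate_expression(design, truth, metrics.history, metrics.rebound, seed)
    return SimulatedStudy(design, traces, metrics, truth, tpm, int(seed))
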