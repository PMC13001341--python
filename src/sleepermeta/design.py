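"""Experiment-design descriptions: conditions, contrasts, and the default panel.

A *condition* is one biological group sampled for RNA-seq (e.g. 6 h mechanical
sleep deprivation ending at ZT0), with its behavioural perturbation schedule.
An *experiment* is a differential-expression contrast between a manipulated
condition and its control, with a stated polarity (wake- or sleep-promoting).

Time is measured in minutes of *experiment time*: minute 0 is lights-on of the
first recorded day (ZT0, day 0); ZT of any minute t is ``t % 1440``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

MINUTES_PER_DAY = 1440

WAKE_PROMOTING = "wake_promoting"
SLEEP_PROMOTING = "sleep_promoting"

FORCE_WAKE = "force_wake"
FORCE_SLEEP = "force_sleep"


@dataclass
class ConditionDesign:
    """One sampled condition and its behavioural schedule.

    ``sampling_time_min`` is the collection time in experiment minutes;
    ``perturb_start_min``/``perturb_end_min`` bound the half-open perturbation
    interval, with ``forced_state`` saying what the perturbation imposes
    (mechanical stimulation forces wake; thermogenetic sleep induction forces
    quiescence). ``circadian_control`` marks baseline round-the-clock samples,
    which the rebound-correlation analysis excludes.
    """

    condition_id: str
    manipulation: str  # baseline | mech_sd | thermo_wake | thermo_sleep | control
    polarity: str  # wake_promoting | sleep_promoting | none
    sampling_time_min: int
    temperature_c: float = 25.0
    genotype: str = "iso31"
    control_id: str | None = None
    circadian_control: bool = False
    perturb_start_min: int | None = None
    perturb_end_min: int | None = None
    forced_state: str | None = None

    @property
    def sampling_zt_min(self) -> int:
        return self.sampling_time_min % MINUTES_PER_DAY

    @property
    def sampling_zt_hours(self) -> float:
        return self.sampling_zt_min / 60.0


@dataclass
class ExperimentDesign:
    """A DE contrast: manipulated condition vs its control, with polarity."""

    experiment_id: str
    condition_id: str
    control_id: str
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in (WAKE_PROMOTING, SLEEP_PROMOTING):
            raise ValueError(
                f"experiment {self.experiment_id}: unknown polarity {self.polarity!r}"
            )


@dataclass
class StudyDesign:
    """The full panel: conditions, DE contrasts, and DAM channel bookkeeping.

    ``dam_channel_map`` maps monitor file name -> channel (1-32, as str) ->
    ``{"fly": fly_id, "condition": condition_id}``.
    """

    conditions: list[ConditionDesign]
    experiments: list[ExperimentDesign]
    replicates: int = 3
    flies_per_condition: int = 16
    lights_on: str = "08:00:00"
    dam_channel_map: dict = field(default_factory=dict)

    def condition(self, condition_id: str) -> ConditionDesign:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(f"unknown condition {condition_id!r}")

    @property
    def condition_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    @property
    def circadian_conditions(self) -> list[str]:
        return [c.condition_id for c in self.conditions if c.circadian_control]

    def sample_ids(self) -> dict[str, str]:
        """Expression sample id -> condition id, in deterministic order."""
        out = {}
        for c in self.conditions:
            for r in range(1, self.replicates + 1):
                out[f"{c.condition_id}_r{r}"] = c.condition_id
        return out

    def to_yaml(self, path) -> None:
        doc = {
            "replicates": self.replicates,
            "flies_per_condition": self.flies_per_condition,
            "lights_on": self.lights_on,
            "conditions": [asdict(c) for c in self.conditions],
            "experiments": [asdict(e) for e in self.experiments],
            "dam_channel_map": self.dam_channel_map,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            conditions=[ConditionDesign(**c) for c in doc["conditions"]],
            experiments=[ExperimentDesign(**e) for e in doc["experiments"]],
            replicates=int(doc.get("replicates", 3)),
            flies_per_condition=int(doc.get("flies_per_condition", 16)),
            lights_on=doc.get("lights_on", "08:00:00"),
            dam_channel_map=doc.get("dam_channel_map", {}),
        )


def default_panel(replicates: int = 3, flies_per_condition: int = 16) -> StudyDesign:
    """The default 13-condition study panel used by the synthetic generator.

    Baseline samples every 4 h (ZT0-ZT20, 25 C), mechanical sleep deprivation
    for 3/6/12 h ending at lights-on, a thermogenetic wake-promoting line
    (3 h activation at the end of the night) and a sleep-promoting line
    (12 h daytime activation) at 29 C, with GAL4/+ 29 C and TrpA1 21 C
    controls. Recordings span three days; day 0 is undisturbed baseline and
    perturbations happen on day 1 (day 2 for deprivations ending at the
    day-1/day-2 boundary).
    """
    d = MINUTES_PER_DAY
    conds: list[ConditionDesign] = []
    for zt_h in (0, 4, 8, 12, 16, 20):
        conds.append(
            ConditionDesign(
                condition_id=f"baseline_zt{zt_h:02d}",
                manipulation="baseline",
                polarity="none",
                sampling_time_min=d + zt_h * 60,
                temperature_c=25.0,
                circadian_control=True,
            )
        )
    for hours in (3, 6, 12):
        conds.append(
            ConditionDesign(
                condition_id=f"mech_sd{hours}",
                manipulation="mech_sd",
                polarity=WAKE_PROMOTING,
                sampling_time_min=2 * d,
                temperature_c=25.0,
                control_id="baseline_zt00",
                perturb_start_min=2 * d - hours * 60,
                perturb_end_min=2 * d,
                forced_state=FORCE_WAKE,
            )
        )
    conds.append(
        ConditionDesign(
            condition_id="wake_trpa1",
            manipulation="thermo_wake",
            polarity=WAKE_PROMOTING,
            sampling_time_min=2 * d,
            temperature_c=29.0,
            genotype="HC>TrpA1",
            control_id="ctrl_gal4_29",
            perturb_start_min=2 * d - 180,
            perturb_end_min=2 * d,
            forced_state=FORCE_WAKE,
        )
    )
    conds.append(
        ConditionDesign(
            condition_id="sleep_trpa1",
            manipulation="thermo_sleep",
            polarity=SLEEP_PROMOTING,
            sampling_time_min=d + 720,
            temperature_c=29.0,
            genotype="R85C10>TrpA1",
            control_id="ctrl_gal4_29",
            perturb_start_min=d,
            perturb_end_min=d + 720,
            forced_state=FORCE_SLEEP,
        )
    )
    conds.append(
        ConditionDesign(
            condition_id="ctrl_gal4_29",
            manipulation="control",
            polarity="none",
            sampling_time_min=2 * d,
            temperature_c=29.0,
            genotype="GAL4/+",
            perturb_start_min=2 * d - 180,
            perturb_end_min=2 * d,
        )
    )
    conds.append(
        ConditionDesign(
            condition_id="ctrl_trpa1_21",
            manipulation="control",
            polarity="none",
            sampling_time_min=2 * d,
            temperature_c=21.0,
            genotype="GAL4>TrpA1",
        )
    )
    exps = [
        ExperimentDesign("mech_sd3", "mech_sd3", "baseline_zt00", WAKE_PROMOTING),
        ExperimentDesign("mech_sd6", "mech_sd6", "baseline_zt00", WAKE_PROMOTING),
        ExperimentDesign("mech_sd12", "mech_sd12", "baseline_zt00", WAKE_PROMOTING),
        ExperimentDesign("wake_trpa1", "wake_trpa1", "ctrl_gal4_29", WAKE_PROMOTING),
        ExperimentDesign("sleep_trpa1", "sleep_trpa1", "ctrl_gal4_29", SLEEP_PROMOTING),
    ]
    return StudyDesign(
        conditions=conds,
        experiments=exps,
        replicates=replicates,
        flies_per_condition=flies_per_condition,
    )
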