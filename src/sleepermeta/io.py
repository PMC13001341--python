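"""Readers and writers for the formats the pipeline consumes and emits.

Supported inputs:

* Trikinetics DAM monitor files — tab-delimited, one row per minute:
  reading index, date (``"1 Jan 26"``), time (``HH:MM:SS``), status flag,
  six auxiliary columns, then 32 channel counts. A channel-to-fly map in the
  study design assigns channels to flies/conditions.
* Long-form activity TSV with columns fly_id, condition_id, minute, count.
* Gene x sample TPM matrix TSV (first column gene_id, header row sample ids).
* Per-experiment DE tables (gene_id, log2fc, qvalue) and a cycling table
  (gene_id, amplitude_log2, qvalue).

Outputs are plain TSVs with headers.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import (
    MINUTES_PER_DAY,
    ActivityTrace,
    ReboundWindows,
    SleepSeries,
    SleepWindows,
)

DAM_N_CHANNELS = 32
DAM_META_COLUMNS = 10  # index, date, time, status + 6 auxiliary columns
_DAM_EPOCH = datetime.datetime(2026, 1, 5, 0, 0, 0)


def _parse_hms(text: str) -> int:
    h, m, s = text.split(":")
    return int(h) * 60 + int(m)


def read_dam_file(
    path,
    channel_map: dict,
    lights_on: str = "08:00:00",
) -> list[ActivityTrace]:
    """Read one DAM monitor file into per-fly activity traces.

    ``channel_map`` maps channel number (1-32, int or str) to
    ``{"fly": fly_id, "condition": condition_id}``. Only mapped channels are
    returned. The first row's clock time and ``lights_on`` fix the ZT of the
    first bin; the recording must span whole days.
    """
    rows = []
    first_minute = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < DAM_META_COLUMNS + DAM_N_CHANNELS:
                raise ValueError(f"{path}: malformed DAM row with {len(fields)} fields")
            if first_minute is None:
                first_minute = _parse_hms(fields[2])
            rows.append(fields[DAM_META_COLUMNS:DAM_META_COLUMNS + DAM_N_CHANNELS])
    if not rows:
        raise ValueError(f"{path}: empty DAM file")
    counts = np.asarray(rows, dtype=np.int64)
    t0 = (first_minute - _parse_hms(lights_on)) % MINUTES_PER_DAY
    traces = []
    for ch, info in sorted(channel_map.items(), key=lambda kv: int(kv[0])):
        ch_i = int(ch)
        if not 1 <= ch_i <= DAM_N_CHANNELS:
            raise ValueError(f"channel {ch} out of range 1..{DAM_N_CHANNELS}")
        traces.append(
            ActivityTrace(
                fly_id=info["fly"],
                condition_id=info["condition"],
                counts=counts[:, ch_i - 1],
                t0=t0,
            )
        )
    return traces


def write_dam_files(
    traces: list[ActivityTrace],
    out_dir,
    lights_on: str = "08:00:00",
) -> dict:
    """Write traces as DAM monitor files (32 channels per monitor).

    All traces must share ``t0`` and length. Returns the channel map,
    ``{monitor_name: {channel: {"fly": ..., "condition": ...}}}``, suitable
    for storing in a study design.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not traces:
        raise ValueError("no traces to write")
    n_min = traces[0].counts.size
    t0 = traces[0].t0
    for tr in traces:
        if tr.counts.size != n_min or tr.t0 != t0:
            raise ValueError("all traces in one DAM export must share span and t0")
    lights_on_min = _parse_hms(lights_on)
    start = _DAM_EPOCH + datetime.timedelta(minutes=lights_on_min + t0)
    meta_prefix = []
    for i in range(n_min):
        ts = start + datetime.timedelta(minutes=i)
        meta_prefix.append(
            "\t".join(
                [str(i + 1), ts.strftime("%-d %b %y"), ts.strftime("%H:%M:%S"),
                 "1", "0", "0", "0", "0", "0", "0"]
            )
        )
    channel_map: dict = {}
    for m0 in range(0, len(traces), DAM_N_CHANNELS):
        group = traces[m0:m0 + DAM_N_CHANNELS]
        monitor = f"Monitor{m0 // DAM_N_CHANNELS + 1}.txt"
        channel_map[monitor] = {
            str(ch + 1): {"fly": tr.fly_id, "condition": tr.condition_id}
            for ch, tr in enumerate(group)
        }
        block = np.zeros((n_min, DAM_N_CHANNELS), dtype=np.int64)
        for ch, tr in enumerate(group):
            block[:, ch] = tr.counts
        rows = ["\t".join(map(str, row)) for row in block.tolist()]
        with open(out_dir / monitor, "w") as fh:
            fh.write("\n".join(f"{m}\t{r}" for m, r in zip(meta_prefix, rows)) + "\n")
    return channel_map


def read_dam_dir(dam_dir, channel_map: dict, lights_on: str = "08:00:00") -> list[ActivityTrace]:
    """Read every monitor file named in a design's DAM channel map."""
    dam_dir = Path(dam_dir)
    traces: list[ActivityTrace] = []
    for monitor in sorted(channel_map):
        traces.extend(read_dam_file(dam_dir / monitor, channel_map[monitor], lights_on))
    return traces


def read_activity_long(path) -> list[ActivityTrace]:
    """Read a long-form activity TSV (fly_id, condition_id, minute, count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"fly_id", "condition_id", "minute", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    traces = []
    for (fly, cond), grp in df.groupby(["fly_id", "condition_id"], sort=True):
        grp = grp.sort_values("minute")
        minutes = grp["minute"].to_numpy()
        if not np.array_equal(minutes, np.arange(minutes[0], minutes[0] + len(minutes))):
            raise ValueError(f"fly {fly}: minutes are not contiguous")
        traces.append(
            ActivityTrace(
                fly_id=str(fly),
                condition_id=str(cond),
                counts=grp["count"].to_numpy(),
                t0=int(minutes[0]),
            )
        )
    return traces


# -- expression / tables ----------------------------------------------------

def read_tpm_matrix(path) -> pd.DataFrame:
    """Gene x sample TPM matrix from TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return df


def write_tpm_matrix(tpm: pd.DataFrame, path) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "qvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def read_cycling_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "amplitude_log2", "qvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


# -- behaviour summaries ----------------------------------------------------

def fly_summary_frame(series_list: list[SleepSeries]) -> pd.DataFrame:
    """Per-fly sleep summary: totals, bout counts, mean bout length."""
    rows = []
    for s in series_list:
        n_bouts = len(s.bouts)
        rows.append(
            {
                "fly_id": s.fly_id,
                "condition_id": s.condition_id,
                "minutes_recorded": s.asleep.size,
                "minutes_asleep": s.total_minutes,
                "n_bouts": n_bouts,
                "mean_bout_minutes": (
                    round(s.total_minutes / n_bouts, 3) if n_bouts else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def windows_frame(windows: list[SleepWindows]) -> pd.DataFrame:
    rows = []
    for w in windows:
        for i, k in enumerate(w.window_hours):
            rows.append(
                {
                    "condition_id": w.condition_id,
                    "direction": w.direction,
                    "window_hours": int(k),
                    "minutes_asleep": round(float(w.minutes_asleep[i]), 4),
                    "n_flies": int(w.n_flies[i]) if w.n_flies is not None else None,
                }
            )
    return pd.DataFrame(rows)


def rebound_frame(rebounds: list[ReboundWindows]) -> pd.DataFrame:
    rows = []
    for r in rebounds:
        for i, k in enumerate(r.window_hours):
            rows.append(
                {
                    "condition_id": r.condition_id,
                    "window_hours": int(k),
                    "rebound_minutes": round(float(r.rebound_minutes[i]), 4),
                }
            )
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
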