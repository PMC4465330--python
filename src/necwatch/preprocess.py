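"""Epoching, baselines, and censoring-aware group trajectories.

Raw 2-s monitor streams are averaged into 1-minute epochs (the analysis
resolution).  An epoch with under half its nominal sample count is marked
missing rather than interpolated.  Per-animal baselines are the mean of the
non-missing epochs in the first hour of recording.  Group trajectories
summarize epochs on a 3-h grid, averaging only animals still alive at each
grid time (no carry-forward of the dead).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import CHANNEL_BOUNDS, Cohort

log = logging.getLogger(__name__)

EPOCH_MIN = 1.0 / 60.0  # epoch length in hours


class OrderingError(ValueError):
    """Vitals stream not sorted in time."""


def downsample_to_epochs(vitals: pd.DataFrame,
                         sample_period_s: float = 2.0) -> pd.DataFrame:
    """Average a long-format vitals table into 1-minute epochs.

    Returns columns (piglet_id, channel, epoch_start_h, mean_value, n_samples);
    epochs covering < 50 % of the nominal per-minute sample count are retained
    with ``mean_value`` = NaN (missing).  Raises :class:`OrderingError` if any
    (piglet, channel) stream is not strictly increasing in time.
    """
    cols = ["piglet_id", "channel", "epoch_start_h", "mean_value", "n_samples"]
    if not len(vitals):
        return pd.DataFrame(columns=cols)
    pid_codes, pid_index = pd.factorize(vitals["piglet_id"], sort=True)
    ch_codes, ch_index = pd.factorize(vitals["channel"], sort=True)
    pid_index = np.array([str(x) for x in pid_index], dtype=object)
    ch_index = np.array([str(x) for x in ch_index], dtype=object)
    t = vitals["t_h"].to_numpy(float)
    val = vitals["value"].to_numpy(float)

    same = (pid_codes[1:] == pid_codes[:-1]) & (ch_codes[1:] == ch_codes[:-1])
    if (same & (np.diff(t) <= 0)).any():
        row = int(np.flatnonzero(same & (np.diff(t) <= 0))[0]) + 1
        raise OrderingError(f"vitals stream unsorted at row {row}")

    minute = np.floor(t * 60.0 + 1e-9).astype(np.int64)
    n_ch = len(ch_index)
    n_min = int(minute.max()) + 1
    key = (pid_codes.astype(np.int64) * n_ch + ch_codes) * n_min + minute
    size = len(pid_index) * n_ch * n_min
    counts = np.bincount(key, minlength=size)
    sums = np.bincount(key, weights=val, minlength=size)
    nz = np.flatnonzero(counts)

    nominal = 60.0 / sample_period_s
    n_samples = counts[nz]
    mean = sums[nz] / n_samples
    mean[n_samples < 0.5 * nominal] = np.nan

    stream = nz // n_min
    out = pd.DataFrame({
        "piglet_id": pid_index[stream // n_ch],
        "channel": ch_index[stream % n_ch],
        "epoch_start_h": (nz % n_min) / 60.0,
        "mean_value": mean,
        "n_samples": n_samples.astype(int),
    })
    return out[cols]


def compute_baseline(epochs: pd.DataFrame, window_h: float = 1.0) -> pd.DataFrame:
    """Per-(piglet, channel) baseline: mean of non-missing epoch means within
    ``window_h`` of the first recorded epoch.  Streams with no usable epoch in
    the window are excluded (and logged)."""
    rows = []
    for (pid, ch), g in epochs.groupby(["piglet_id", "channel"],
                                       observed=True, sort=True):
        t0 = g["epoch_start_h"].min()
        window = g[(g["epoch_start_h"] < t0 + window_h)
                   & g["mean_value"].notna()]
        if not len(window):
            log.warning("no usable baseline epochs for (%s, %s); excluded",
                        pid, ch)
            continue
        rows.append((pid, ch, float(window["mean_value"].mean())))
    return pd.DataFrame(rows, columns=["piglet_id", "channel", "baseline"])


def group_trajectory(epochs: pd.DataFrame, piglets: pd.DataFrame,
                     channel: str, grid_step_h: float = 3.0,
                     study_end_h: float = 96.0) -> pd.DataFrame:
    """Group mean/SEM trajectory of per-animal epoch block means on a 3-h grid.

    At grid time t an animal contributes the mean of its non-missing epochs in
    [t, t + step) — and only if it is alive at t (``death_h > t``, strictly: a
    death on the grid point excludes it).  SEM is sample-SD/sqrt(n), absent
    when fewer than two animals contribute; a group with no animal at t is
    omitted at t.
    """
    if channel not in CHANNEL_BOUNDS:
        raise ValueError(f"unknown channel {channel!r}")
    e = epochs[(epochs["channel"].astype(str) == channel)
               & epochs["mean_value"].notna()]
    death = dict(zip(piglets["piglet_id"].astype(str),
                     piglets["death_h"].to_numpy(float)))
    group_of = dict(zip(piglets["piglet_id"].astype(str), piglets["group"]))
    grid = np.arange(0.0, study_end_h + 1e-9, grid_step_h)

    rows = []
    pid_arr = e["piglet_id"].astype(str).to_numpy()
    t_arr = e["epoch_start_h"].to_numpy(float)
    v_arr = e["mean_value"].to_numpy(float)
    for t in grid:
        in_block = (t_arr >= t) & (t_arr < t + grid_step_h)
        block = pd.DataFrame({"pid": pid_arr[in_block], "v": v_arr[in_block]})
        per_animal = block.groupby("pid")["v"].mean()
        for g in sorted(set(group_of.values())):
            vals = [m for pid, m in per_animal.items()
                    if group_of.get(pid) == g
                    and (np.isnan(death.get(pid, np.nan)) or death[pid] > t)]
            n = len(vals)
            if n == 0:
                continue
            mean = float(np.mean(vals))
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            rows.append((channel, float(t), g, mean, sem, n))
    return pd.DataFrame(rows, columns=["channel", "t_h", "group",
                                       "mean", "sem", "n_alive"])


def epochs_for_cohort(cohort: Cohort, sample_period_s: float = 2.0) -> pd.DataFrame:
    return downsample_to_epochs(cohort.vitals, sample_period_s=sample_period_s)
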