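"""Peri-prandial StO2 variability: the feeding-response statistic.

For each of the first two enteral feeds, the abdominal StO2 epochs in the
15 minutes just before the feed and the 15 minutes just after are averaged,
and the variability is the unsigned percent change of the post-window mean
relative to the pre-window mean:

    pct_change = |post_mean - pre_mean| / pre_mean * 100.

The pre-feed window mean serves as the reference ("baseline") level — the
statistic probes the splanchnic response to the feed itself, not drift since
birth.  An animal's statistic is the mean over its usable feed windows; a
window with fewer than 8 of 15 non-missing epochs is skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import NEC_GROUPS

log = logging.getLogger(__name__)

WINDOW_H = 0.25       # 15-minute windows
MIN_EPOCHS = 8        # coverage floor per window (of 15)


@dataclass(frozen=True)
class WindowVariability:
    piglet_id: str
    feed_index: int     # 1-based
    pre_mean: float
    post_mean: float
    pct_change: float


def feed_window_stat(epochs: pd.DataFrame, feed_t_h: float,
                     piglet_id: str | None = None, feed_index: int = 1,
                     signed: bool = False) -> WindowVariability | None:
    """Pre/post window means around one feed for one animal's StO2 epochs.

    ``epochs`` must already be restricted to one animal's STO2 series.
    Returns None (a window-skip signal, logged) when either 15-epoch window
    has fewer than 8 non-missing epochs.
    """
    t = epochs["epoch_start_h"].to_numpy(float)
    v = epochs["mean_value"].to_numpy(float)
    ok = ~np.isnan(v)
    pre = ok & (t >= feed_t_h - WINDOW_H) & (t < feed_t_h)
    post = ok & (t >= feed_t_h) & (t < feed_t_h + WINDOW_H)
    if pre.sum() < MIN_EPOCHS or post.sum() < MIN_EPOCHS:
        log.info("feed window at %.2f h skipped for %s: coverage %d/%d",
                 feed_t_h, piglet_id, int(pre.sum()), int(post.sum()))
        return None
    pre_mean = float(v[pre].mean())
    post_mean = float(v[post].mean())
    change = (post_mean - pre_mean) / pre_mean * 100.0
    return WindowVariability(piglet_id or "", feed_index, pre_mean, post_mean,
                             change if signed else abs(change))


def cohort_variability(epochs: pd.DataFrame, piglets: pd.DataFrame,
                       feeds: pd.DataFrame, n_feeds: int = 2,
                       signed: bool = False
                       ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-animal peri-prandial statistic over the first ``n_feeds`` feeds,
    plus group summaries (3-group and pooled NEC vs No-NEC means).

    Returns (per-animal table with columns piglet_id/group/n_windows/variability,
    summary dict with keys per group plus 'NEC' and 'NO_NEC').
    """
    sto2 = epochs[epochs["channel"].astype(str) == "STO2"]
    group_of = dict(zip(piglets["piglet_id"].astype(str), piglets["group"]))

    rows = []
    for pid, g in sto2.groupby(sto2["piglet_id"].astype(str), sort=True):
        my_feeds = feeds[feeds["piglet_id"].astype(str) == pid]
        feed_ts = np.sort(my_feeds["t_h"].to_numpy(float))[:n_feeds]
        stats = []
        for k, tf in enumerate(feed_ts, start=1):
            w = feed_window_stat(g, float(tf), piglet_id=pid, feed_index=k,
                                 signed=signed)
            if w is not None:
                stats.append(w.pct_change)
        if stats:
            rows.append((pid, group_of.get(pid), len(stats),
                         float(np.mean(stats))))
    per_animal = pd.DataFrame(rows, columns=["piglet_id", "group",
                                             "n_windows", "variability"])
    summary: dict[str, float] = {}
    for g, sub in per_animal.groupby("group"):
        summary[g] = float(sub["variability"].mean())
    nec = per_animal[per_animal["group"].isin(NEC_GROUPS)]
    if len(nec):
        summary["NEC"] = float(nec["variability"].mean())
    no = per_animal[per_animal["group"] == "NO_NEC"]
    if len(no):
        summary["NO_NEC"] = float(no["variability"].mean())
    return per_animal, summary
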