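"""Normality-gated group comparisons and the baseline summary table.

The testing rule: Shapiro-Wilk per group at alpha = 0.05 on the analysis-unit
values (per-animal statistics, never raw 2-s samples).  If every group looks
normal, a parametric comparison is used (one-way ANOVA for >= 3 groups,
Welch t for two) with Tukey-HSD family-wise post-hoc pairwise comparisons
when the global test rejects; otherwise the rank-based analogue
(Kruskal-Wallis / Mann-Whitney).  All p-values two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

RM_ANOVA_POSTHOC = "RM_ANOVA_POSTHOC"
KRUSKAL_WALLIS = "KRUSKAL_WALLIS"
TWO_SAMPLE = "TWO_SAMPLE"


class InsufficientDataError(ValueError):
    pass


@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, ...]
    normality_p: dict[str, float]
    method: str
    global_p: float
    pairwise_p: pd.DataFrame | None = None
    alpha: float = ALPHA
    group_means: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.global_p < self.alpha


def _tukey_pairwise(values: dict[str, np.ndarray]) -> pd.DataFrame:
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(values)
    y = np.concatenate([values[g] for g in names])
    lab = np.concatenate([[g] * len(values[g]) for g in names])
    res = pairwise_tukeyhsd(y, lab, alpha=ALPHA)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for (g1, g2), p in zip(combinations(sorted(names), 2), res.pvalues):
        mat.loc[g1, g2] = mat.loc[g2, g1] = float(p)
    return mat


def _rank_pairwise(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Mann-Whitney with Holm family-wise adjustment."""
    names = list(values)
    pairs, raw = [], []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            p = float(sps.mannwhitneyu(values[g1], values[g2],
                                       alternative="two-sided").pvalue)
            pairs.append((g1, g2))
            raw.append(p)
    order = np.argsort(raw)
    adj = np.empty(len(raw))
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (len(raw) - rank) * raw[idx])
        adj[idx] = min(running, 1.0)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for (g1, g2), p in zip(pairs, adj):
        mat.loc[g1, g2] = mat.loc[g2, g1] = p
    return mat


def gated_group_test(values_by_group: dict[str, np.ndarray],
                     variable: str = "", paired_over_time: bool = False
                     ) -> GroupComparison:
    """Shapiro-gated group comparison.

    ``values_by_group`` maps group name -> analysis-unit values (each animal
    one value; for time-gridded variables pass per-animal time means —
    ``paired_over_time`` collapses a (animal x time) 2-D array that way).
    """
    values = {}
    for g, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        if paired_over_time and arr.ndim == 2:
            arr = np.nanmean(arr, axis=1)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 3:
            raise InsufficientDataError(
                f"group {g!r} has n={len(arr)} < 3 analysis units")
        values[g] = arr
    if len(values) < 2:
        raise InsufficientDataError("need at least two groups")
    names = tuple(values)

    normality = {g: float(sps.shapiro(v).pvalue) for g, v in values.items()}
    all_normal = all(p > ALPHA for p in normality.values())

    pairwise = None
    if len(values) == 2:
        a, b = (values[g] for g in names)
        if all_normal:
            global_p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            global_p = float(sps.mannwhitneyu(a, b,
                                              alternative="two-sided").pvalue)
        method = TWO_SAMPLE
    elif all_normal:
        global_p = float(sps.f_oneway(*values.values()).pvalue)
        method = RM_ANOVA_POSTHOC
        if global_p < ALPHA:
            pairwise = _tukey_pairwise(values)
    else:
        global_p = float(sps.kruskal(*values.values()).pvalue)
        method = KRUSKAL_WALLIS
        if global_p < ALPHA:
            pairwise = _rank_pairwise(values)
    return GroupComparison(
        variable=variable, groups=names, normality_p=normality,
        method=method, global_p=global_p, pairwise_p=pairwise,
        group_means={g: float(v.mean()) for g, v in values.items()})


def baseline_table(piglets: pd.DataFrame, baselines: pd.DataFrame
                   ) -> pd.DataFrame:
    """Severity-group baseline summary (mean ± SD cells plus the gated p).

    Rows: birth weight, hematocrit, and the first-hour HR / SpO2 / StO2
    baselines; columns: one per group present, plus ``p_value``.
    """
    group_of = dict(zip(piglets["piglet_id"].astype(str), piglets["group"]))
    groups = [g for g in ("F_NEC", "NF_NEC", "NO_NEC")
              if (piglets["group"] == g).any()]

    def scalar_values(col):
        return {g: piglets.loc[piglets["group"] == g, col].to_numpy(float)
                for g in groups}

    def baseline_values(channel):
        sub = baselines[baselines["channel"] == channel]
        out = {g: [] for g in groups}
        for pid, v in zip(sub["piglet_id"].astype(str), sub["baseline"]):
            g = group_of.get(pid)
            if g in out:
                out[g].append(float(v))
        return {g: np.asarray(v) for g, v in out.items()}

    spec_rows = [
        ("Birth weight (g)", scalar_values("birth_weight_g")),
        ("Baseline hematocrit (%)", scalar_values("baseline_hct")),
        ("Baseline HR (bpm)", baseline_values("HR")),
        ("Baseline SpO2 (%)", baseline_values("SPO2")),
        ("Baseline A-NIRS StO2 (%)", baseline_values("STO2")),
    ]
    rows = []
    for label, vals in spec_rows:
        cells = {}
        for g in groups:
            v = np.asarray(vals[g], dtype=float)
            cells[g] = (f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
                        if len(v) >= 2 else
                        (f"{v.mean():.1f} ± 0.0" if len(v) else ""))
        try:
            cmp = gated_group_test(vals, variable=label)
            cells["p_value"] = f"{cmp.global_p:.3g}"
            cells["method"] = cmp.method
        except InsufficientDataError:
            cells["p_value"] = ""
            cells["method"] = ""
        cells["variable"] = label
        rows.append(cells)
    return pd.DataFrame(rows)[["variable", *groups, "p_value", "method"]]
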