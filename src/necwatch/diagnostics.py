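"""ROC screening diagnostics for the two early markers.

Abdominal StO2 screens with orientation *lower is positive* (ischemic gut
reads low): an observation is called NEC-positive when its score falls below
the threshold.  Plasma I-FABP screens *higher is positive* (enterocyte injury
releases protein): positive when the score exceeds the threshold.

The empirical ROC sweeps every distinct observed value as a candidate
threshold (plus a degenerate all-negative end); the operating cutoff
maximizes the Youden index J = sensitivity + specificity - 1, with ties
resolved in favor of sensitivity (a screening test) and then toward the
smaller threshold magnitude.  AUC is the trapezoidal area, which equals the
normalized Mann-Whitney U statistic.

Observation units: StO2 screening is epoch-level over the pre-feed window
(hours 0-48) by default, I-FABP sample-level over post-feed draws; per-animal
aggregation is available for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import NEC_GROUPS

LOWER_IS_POSITIVE = "LOWER_IS_POSITIVE"
HIGHER_IS_POSITIVE = "HIGHER_IS_POSITIVE"


class DegenerateLabelsError(ValueError):
    """Both classes must be present to form a ROC curve."""


class EmptyInputError(ValueError):
    pass


@dataclass
class RocCurve:
    orientation: str
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    chosen_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    unit: str = "SAMPLE"
    n_pos: int = 0
    n_neg: int = 0

    def confusion_at(self, threshold: float, scores, labels) -> dict[str, int]:
        scores = np.asarray(scores, float)
        labels = np.asarray(labels, bool)
        pos = _decide(scores, threshold, self.orientation)
        return {
            "tp": int((pos & labels).sum()),
            "fp": int((pos & ~labels).sum()),
            "fn": int((~pos & labels).sum()),
            "tn": int((~pos & ~labels).sum()),
        }


def _decide(scores: np.ndarray, threshold: float, orientation: str) -> np.ndarray:
    if orientation == LOWER_IS_POSITIVE:
        return scores < threshold
    if orientation == HIGHER_IS_POSITIVE:
        return scores > threshold
    raise ValueError(f"unknown orientation {orientation!r}")


def roc_curve(scores, labels, orientation: str, unit: str = "SAMPLE") -> RocCurve:
    """Empirical ROC over all distinct thresholds with Youden cutoff selection."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) == 0:
        raise EmptyInputError("no scores")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes required")

    # Candidate thresholds: midpoints between consecutive distinct values plus
    # the two degenerate ends (everything negative / everything positive).
    # Midpoints realize every achievable confusion matrix while placing the
    # operating cutoff between the classes it separates.
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    if orientation == LOWER_IS_POSITIVE:
        # positive iff score < t
        thresholds = np.concatenate([[uniq[0]], mids, [uniq[-1] + 1.0]])
        tp = np.searchsorted(pos_sorted, thresholds, side="left")
        fp = np.searchsorted(neg_sorted, thresholds, side="left")
    else:
        # positive iff score > t
        thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1]]])
        tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="right")
        fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="right")

    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    fpr = fp / n_neg
    order = np.lexsort((sens, fpr))  # ascending fpr, ties by ascending sens
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best = np.flatnonzero(np.isclose(j, j.max(), atol=1e-12))
    # ties: favor sensitivity, then the smaller threshold magnitude
    best = best[np.isclose(sens[best], sens[best].max(), atol=1e-12)]
    pick = best[np.argmin(np.abs(thresholds[best]))]
    return RocCurve(orientation=orientation,
                    thresholds=thresholds, sens=sens, spec=spec, auc=auc,
                    chosen_cutoff=float(thresholds[pick]),
                    sens_at_cutoff=float(sens[pick]),
                    spec_at_cutoff=float(spec[pick]),
                    unit=unit, n_pos=n_pos, n_neg=n_neg)


def _sens_spec_at(scores, labels, threshold, orientation):
    pos = _decide(np.asarray(scores, float), threshold, orientation)
    labels = np.asarray(labels, bool)
    sens = float((pos & labels).sum() / labels.sum())
    spec = float((~pos & ~labels).sum() / (~labels).sum())
    return sens, spec


def screen_sto2(epochs: pd.DataFrame, piglets: pd.DataFrame,
                window_h: tuple[float, float] = (0.0, 48.0),
                threshold: float | None = None,
                unit: str = "EPOCH") -> RocCurve:
    """ROC screen on abdominal StO2, lower-is-positive.

    ``unit='EPOCH'``: every non-missing 1-min StO2 epoch starting within
    ``window_h`` is one observation, labeled by its animal's eventual NEC
    status.  ``unit='ANIMAL'``: one observation per animal (its mean epoch
    value in the window).  With ``threshold`` given, the reported operating
    point is at that cutoff instead of the Youden choice.
    """
    e = epochs[(epochs["channel"].astype(str) == "STO2")
               & epochs["mean_value"].notna()]
    t = e["epoch_start_h"].to_numpy(float)
    e = e[(t >= window_h[0]) & (t < window_h[1])]
    if not len(e):
        raise EmptyInputError(f"no StO2 epochs in window {window_h}")
    nec = dict(zip(piglets["piglet_id"].astype(str),
                   piglets["group"].isin(NEC_GROUPS)))
    pid = e["piglet_id"].astype(str)
    if unit == "ANIMAL":
        per = e.groupby(pid.to_numpy())["mean_value"].mean()
        scores = per.to_numpy(float)
        labels = np.array([nec[p] for p in per.index])
    else:
        scores = e["mean_value"].to_numpy(float)
        labels = pid.map(nec).to_numpy(bool)
    roc = roc_curve(scores, labels, LOWER_IS_POSITIVE, unit=unit)
    if threshold is not None:
        roc.chosen_cutoff = float(threshold)
        roc.sens_at_cutoff, roc.spec_at_cutoff = _sens_spec_at(
            scores, labels, threshold, LOWER_IS_POSITIVE)
    return roc


def screen_ifabp(biomarkers: pd.DataFrame, piglets: pd.DataFrame,
                 min_t_h: float = 48.0, threshold: float | None = None,
                 unit: str = "SAMPLE") -> RocCurve:
    """ROC screen on plasma I-FABP over post-feed draws, higher-is-positive.

    ``unit='SAMPLE'``: every draw at t >= ``min_t_h`` is one observation;
    ``unit='ANIMAL'``: one observation per animal (its peak post-feed draw).
    """
    b = biomarkers[biomarkers["t_h"] >= min_t_h]
    if not len(b):
        raise EmptyInputError(f"no I-FABP draws at t >= {min_t_h}")
    nec = dict(zip(piglets["piglet_id"].astype(str),
                   piglets["group"].isin(NEC_GROUPS)))
    pid = b["piglet_id"].astype(str)
    if unit == "ANIMAL":
        per = b.groupby(pid.to_numpy())["ifabp_ng_ml"].max()
        scores = per.to_numpy(float)
        labels = np.array([nec[p] for p in per.index])
    else:
        scores = b["ifabp_ng_ml"].to_numpy(float)
        labels = pid.map(nec).to_numpy(bool)
    roc = roc_curve(scores, labels, HIGHER_IS_POSITIVE, unit=unit)
    if threshold is not None:
        roc.chosen_cutoff = float(threshold)
        roc.sens_at_cutoff, roc.spec_at_cutoff = _sens_spec_at(
            scores, labels, threshold, HIGHER_IS_POSITIVE)
    return roc
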