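"""ROC construction versus brute-force confusion counting, AUC identities,
Youden selection and the screening wrappers."""

import numpy as np
import pandas as pd
import pytest

from necwatch.diagnostics import (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE,
                                  DegenerateLabelsError, EmptyInputError,
                                  roc_curve, screen_ifabp, screen_sto2)


def brute_force_point(scores, labels, t, orientation):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores < t if orientation == LOWER_IS_POSITIVE else scores > t
    sens = (pos & labels).sum() / labels.sum()
    spec = (~pos & ~labels).sum() / (~labels).sum()
    return sens, spec


@pytest.mark.parametrize("orientation", [LOWER_IS_POSITIVE, HIGHER_IS_POSITIVE])
@pytest.mark.parametrize("seed,n", [(0, 20), (1, 57), (2, 200), (3, 11)])
def test_roc_equals_brute_force_at_every_threshold(orientation, seed, n):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(70, 8, n), 1)   # force some ties
    labels = rng.uniform(size=n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    roc = roc_curve(scores, labels, orientation)
    for t, s, sp in zip(roc.thresholds, roc.sens, roc.spec):
        bs, bsp = brute_force_point(scores, labels, t, orientation)
        assert s == pytest.approx(bs)
        assert sp == pytest.approx(bsp)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_auc_equals_mann_whitney_normalization(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(0, 1, 80), 2)
    labels = rng.uniform(size=80) < 0.5
    labels[0], labels[1] = True, False
    roc = roc_curve(scores, labels, HIGHER_IS_POSITIVE)
    from scipy.stats import mannwhitneyu
    u = mannwhitneyu(scores[labels], scores[~labels]).statistic
    assert roc.auc == pytest.approx(u / (labels.sum() * (~labels).sum()))


def test_auc_equals_sklearn_cross_check():
    rng = np.random.default_rng(4)
    scores = rng.normal(0, 1, 150)
    labels = rng.uniform(size=150) < 0.3
    labels[0], labels[1] = True, False
    from sklearn.metrics import roc_auc_score
    roc = roc_curve(scores, labels, HIGHER_IS_POSITIVE)
    assert roc.auc == pytest.approx(roc_auc_score(labels, scores))
    roc_low = roc_curve(scores, labels, LOWER_IS_POSITIVE)
    assert roc_low.auc == pytest.approx(roc_auc_score(labels, -scores))


def test_perfectly_separated_classes():
    roc = roc_curve([70.0, 72.0, 78.0, 80.0], [True, True, False, False],
                    LOWER_IS_POSITIVE)
    assert roc.auc == pytest.approx(1.0)
    assert 72.0 < roc.chosen_cutoff < 78.0
    assert roc.sens_at_cutoff == 1.0
    assert roc.spec_at_cutoff == 1.0


def test_identical_scores_are_uninformative():
    roc = roc_curve([5.0] * 10, [True] * 4 + [False] * 6, LOWER_IS_POSITIVE)
    assert roc.auc == pytest.approx(0.5)


def test_label_and_input_degeneracies():
    with pytest.raises(DegenerateLabelsError):
        roc_curve([1.0, 2.0], [True, True], LOWER_IS_POSITIVE)
    with pytest.raises(EmptyInputError):
        roc_curve([], [], LOWER_IS_POSITIVE)


def test_youden_invariant_under_monotone_transform():
    rng = np.random.default_rng(7)
    scores = rng.normal(70, 10, 60)
    labels = scores + rng.normal(0, 8, 60) < 68
    a = roc_curve(scores, labels, LOWER_IS_POSITIVE)
    b = roc_curve(np.exp(scores / 20.0), labels, LOWER_IS_POSITIVE)
    assert a.sens_at_cutoff == pytest.approx(b.sens_at_cutoff)
    assert a.spec_at_cutoff == pytest.approx(b.spec_at_cutoff)
    assert a.auc == pytest.approx(b.auc)


def _epoch_frame(rows):
    return pd.DataFrame(rows, columns=["piglet_id", "channel",
                                       "epoch_start_h", "mean_value",
                                       "n_samples"])


def _piglets(groups):
    return pd.DataFrame({
        "piglet_id": [f"P{i:02d}" for i in range(1, len(groups) + 1)],
        "group": groups, "death_h": np.nan})


def test_screen_sto2_forced_boundary_threshold():
    e = _epoch_frame([("P01", "STO2", 1.0, 70.0, 30),
                      ("P02", "STO2", 1.0, 80.0, 30)])
    p = _piglets(["F_NEC", "NO_NEC"])
    roc = screen_sto2(e, p, threshold=60.0)  # below every score
    assert roc.sens_at_cutoff == 0.0
    assert roc.spec_at_cutoff == 1.0


def test_screen_sto2_uses_prefeed_window_only():
    e = _epoch_frame([("P01", "STO2", 1.0, 70.0, 30),
                      ("P01", "STO2", 50.0, 40.0, 30),   # post-feed: excluded
                      ("P02", "STO2", 1.0, 80.0, 30)])
    p = _piglets(["F_NEC", "NO_NEC"])
    roc = screen_sto2(e, p)
    assert roc.n_pos == 1 and roc.n_neg == 1
    assert 70.0 < roc.chosen_cutoff < 80.0
    with pytest.raises(EmptyInputError):
        screen_sto2(e, p, window_h=(10.0, 20.0))


def test_screen_ifabp_worked_example():
    b = pd.DataFrame({"piglet_id": ["P01", "P02", "P03"],
                      "t_h": [48.0, 54.0, 48.0],
                      "ifabp_ng_ml": [0.04, 0.3, 1.9],
                      "saa_ng_ml": [10.0, 10.0, 10.0]})
    p = _piglets(["NO_NEC", "F_NEC", "NF_NEC"])
    roc = screen_ifabp(b, p, threshold=0.25)
    assert roc.sens_at_cutoff == 1.0
    assert roc.spec_at_cutoff == 1.0
    counts = roc.confusion_at(0.25, b["ifabp_ng_ml"],
                              p["group"] != "NO_NEC")
    assert counts == {"tp": 2, "fp": 0, "fn": 0, "tn": 1}


def test_animal_level_units():
    e = _epoch_frame([("P01", "STO2", 1.0, 60.0, 30),
                      ("P01", "STO2", 2.0, 70.0, 30),
                      ("P02", "STO2", 1.0, 80.0, 30)])
    p = _piglets(["F_NEC", "NO_NEC"])
    roc = screen_sto2(e, p, unit="ANIMAL")
    assert roc.unit == "ANIMAL"
    assert roc.n_pos + roc.n_neg == 2
    assert 65.0 < roc.chosen_cutoff < 80.0
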