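"""Biomarker summaries and the rank-correlation oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from necwatch.biomarkers import (DegenerateCorrelationError, EmptyClassError,
                                 densitometry_correlation, pooled_group_mean,
                                 trajectory_summary)


def necropsy_frame(scores, aus):
    return pd.DataFrame({"piglet_id": [f"P{i}" for i in range(len(scores))],
                         "nec_score": scores, "densitometry_au": aus})


def rank_oracle_rho(x, y):
    """Spearman rho by definition: Pearson correlation of mid-ranks."""
    def midranks(v):
        v = np.asarray(v, float)
        r = np.empty(len(v))
        order = np.argsort(v, kind="mergesort")
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


@pytest.mark.parametrize("seed,n", [(0, 5), (1, 8), (2, 12), (3, 12)])
def test_spearman_matches_rank_oracle_with_ties(seed, n):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 7, n)
    aus = np.round(100 - 10 * scores + rng.normal(0, 15, n), 0)
    if len(set(scores)) < 2 or len(set(aus)) < 2:
        pytest.skip("degenerate draw")
    got = densitometry_correlation(necropsy_frame(scores, aus))["rho"]
    assert got == pytest.approx(rank_oracle_rho(aus, scores), abs=1e-12)


def test_perfect_inverse_monotone_gives_minus_one():
    assert densitometry_correlation(
        necropsy_frame([0, 2, 4, 6], [10.0, 8.0, 6.0, 4.0])
    )["rho"] == pytest.approx(-1.0)


def test_rho_invariant_under_monotone_transform():
    rng = np.random.default_rng(9)
    scores = rng.integers(0, 7, 12)
    aus = 100 - 10 * scores + rng.normal(0, 10, 12)
    a = densitometry_correlation(necropsy_frame(scores, aus))["rho"]
    b = densitometry_correlation(necropsy_frame(scores, np.exp(aus / 40)))["rho"]
    assert a == pytest.approx(b)
    assert -1.0 <= a <= 1.0


def test_degenerate_correlation_inputs_raise():
    with pytest.raises(DegenerateCorrelationError):
        densitometry_correlation(necropsy_frame([3, 3, 3], [5.0, 6.0, 7.0]))
    with pytest.raises(DegenerateCorrelationError):
        densitometry_correlation(necropsy_frame([1, 2], [5.0, 6.0]))


def _bio(rows):
    return pd.DataFrame(rows, columns=["piglet_id", "t_h", "ifabp_ng_ml",
                                       "saa_ng_ml"])


def _piglets(groups):
    return pd.DataFrame({
        "piglet_id": [f"P{i:02d}" for i in range(1, len(groups) + 1)],
        "group": groups, "death_h": np.nan})


def test_trajectory_summary_pre_and_peak_oracle():
    b = _bio([("P01", 42.0, 0.04, 10.0), ("P01", 54.0, 1.0, 10.0),
              ("P01", 60.0, 1.8, 10.0),
              ("P02", 42.0, 0.06, 10.0), ("P02", 54.0, 2.2, 10.0)])
    p = _piglets(["F_NEC", "F_NEC"])
    ts = trajectory_summary(b, p, "IFABP")
    assert ts.pre_feed_mean["F_NEC"] == pytest.approx(0.05)   # mean(.04,.06)
    assert ts.post_feed_peak_mean["F_NEC"] == pytest.approx(2.0)  # mean(1.8,2.2)
    row = ts.grid[(ts.grid["t_h"] == 54.0)].iloc[0]
    assert row["mean"] == pytest.approx(1.6)
    assert row["n"] == 2


def test_peak_statistic_is_order_invariant():
    rows = [("P01", 48.0, 0.5, 1.0), ("P01", 54.0, 2.0, 1.0),
            ("P01", 60.0, 1.0, 1.0)]
    p = _piglets(["F_NEC"])
    peaks = {trajectory_summary(_bio(list(perm)), p, "IFABP")
             .post_feed_peak_mean["F_NEC"]
             for perm in itertools.permutations(rows)}
    assert peaks == {2.0}


def test_all_zero_draws_give_zero_summaries():
    b = _bio([("P01", 42.0, 0.0, 0.0), ("P01", 54.0, 0.0, 0.0)])
    ts = trajectory_summary(b, _piglets(["NO_NEC"]), "IFABP")
    assert ts.pre_feed_mean["NO_NEC"] == 0.0
    assert ts.post_feed_peak_mean["NO_NEC"] == 0.0


def test_unknown_analyte_rejected():
    with pytest.raises(KeyError):
        trajectory_summary(_bio([]), _piglets(["NO_NEC"]), "CRP")


def test_pooled_group_mean_single_draw_identity():
    b = _bio([("P01", 54.0, 1.5, 1.0), ("P02", 54.0, 0.1, 1.0)])
    p = _piglets(["F_NEC", "NO_NEC"])
    out = pooled_group_mean(b, p)
    assert out["nec_mean"] == pytest.approx(1.5)
    assert out["no_nec_mean"] == pytest.approx(0.1)


def test_pooled_group_mean_excludes_pre_feed_draws():
    b = _bio([("P01", 0.0, 9.9, 1.0), ("P01", 54.0, 1.0, 1.0),
              ("P02", 54.0, 0.1, 1.0)])
    p = _piglets(["F_NEC", "NO_NEC"])
    assert pooled_group_mean(b, p)["nec_mean"] == pytest.approx(1.0)


def test_pooled_group_mean_per_animal_weighting():
    b = _bio([("P01", 54.0, 1.0, 1.0), ("P01", 60.0, 3.0, 1.0),
              ("P02", 54.0, 5.0, 1.0), ("P03", 54.0, 0.1, 1.0)])
    p = _piglets(["F_NEC", "NF_NEC", "NO_NEC"])
    draws = pooled_group_mean(b, p)
    animals = pooled_group_mean(b, p, per_animal=True)
    assert draws["nec_mean"] == pytest.approx(3.0)      # (1+3+5)/3
    assert animals["nec_mean"] == pytest.approx(3.5)    # (2+5)/2


def test_empty_class_raises():
    b = _bio([("P01", 54.0, 1.0, 1.0)])
    with pytest.raises(EmptyClassError):
        pooled_group_mean(b, _piglets(["F_NEC"]))
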