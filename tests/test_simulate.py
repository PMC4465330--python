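"""Simulator: determinism, noiseless degeneracy, censoring, channel noise."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from necwatch.cohort import write_cohort
from necwatch.preprocess import downsample_to_epochs
from necwatch.simulate import (BiomarkerKinetics, ChannelParams, ConfigError,
                               PlateauParams, SimConfig, default_config,
                               feed_times_for, simulate_biomarkers,
                               simulate_cohort, simulate_necropsy,
                               simulate_validation_plateaus,
                               simulate_vitals_channel, _ar1)
from necwatch.calibration import fit_calibration
from necwatch.biomarkers import densitometry_correlation


def small_config(seed=0):
    """Cheap configuration for structural tests: 1-min sampling."""
    return SimConfig(seed=seed, sample_period_s=60.0,
                     n_per_group={"F_NEC": 1, "NF_NEC": 2, "NO_NEC": 2})


def noiseless_sto2(group="NO_NEC"):
    cfg = default_config()
    p = cfg.vitals[group]["STO2"]
    return cfg, dataclasses.replace(p, noise_sd=0.0, baseline_sd=0.0,
                                    feed_dip_amplitude=0.0)


def test_default_cohort_composition(default_cohort):
    assert default_cohort.group_counts() == {"F_NEC": 7, "NF_NEC": 14,
                                             "NO_NEC": 17}
    assert len(default_cohort.piglets) == 38
    assert default_cohort.nec_incidence_pct() == 55


def test_same_seed_gives_byte_identical_csv(tmp_path):
    a = simulate_cohort(small_config(seed=7))
    b = simulate_cohort(small_config(seed=7))
    pa = write_cohort(a, str(tmp_path / "a"))
    pb = write_cohort(b, str(tmp_path / "b"))
    for name in pa:
        assert filecmp.cmp(pa[name], pb[name], shallow=False), name


def test_different_seed_differs():
    a = simulate_cohort(small_config(seed=7))
    b = simulate_cohort(small_config(seed=8))
    assert not a.equals(b)


def test_nonpositive_group_size_rejected():
    cfg = small_config()
    cfg.n_per_group["F_NEC"] = 0
    with pytest.raises(ConfigError):
        simulate_cohort(cfg)


def test_noiseless_epoch_means_follow_mean_curve():
    """With all noise off, every 1-min epoch mean equals the mean curve
    averaged over that epoch's sample times (closed-loop identity)."""
    cfg, p = noiseless_sto2("F_NEC")
    rng = np.random.default_rng(0)
    t, v = simulate_vitals_channel(p, "STO2", np.inf, np.array([]), cfg, rng)
    vit = pd.DataFrame({"piglet_id": "P01", "channel": "STO2",
                        "t_h": t, "value": v})
    epochs = downsample_to_epochs(vit)
    minute = np.floor(t * 60.0 + 1e-9).astype(int)
    oracle = pd.Series(p.mean_curve(t)).groupby(minute).mean()
    got = epochs.set_index((epochs["epoch_start_h"] * 60).round().astype(int))
    assert np.allclose(got["mean_value"].to_numpy(),
                       oracle.loc[got.index].to_numpy(), atol=1e-9)


def test_noiseless_first_hour_baseline_is_exact():
    cfg, p = noiseless_sto2("NO_NEC")
    rng = np.random.default_rng(0)
    t, v = simulate_vitals_channel(p, "STO2", np.inf, np.array([]), cfg, rng)
    first_hour = v[t < 1.0]
    assert np.allclose(first_hour, 79.5)


def test_ar1_lag1_autocorrelation_matches_phi():
    rng = np.random.default_rng(123)
    x = _ar1(100_000, phi=0.9, stationary_sd=2.0, rng=rng)
    r = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert r == pytest.approx(0.9, abs=0.01)
    assert x.std() == pytest.approx(2.0, rel=0.05)


def test_censoring_truncates_everything_at_death(default_cohort):
    p = default_cohort.piglets
    dead = p[p["death_h"].notna()]
    death = dict(zip(dead["piglet_id"], dead["death_h"]))
    for table, strict in (("vitals", True), ("feeds", True),
                          ("biomarkers", False)):
        df = getattr(default_cohort, table)
        for pid, d in death.items():
            t = df.loc[df["piglet_id"].astype(str) == pid, "t_h"]
            if len(t):
                assert (t.max() < d) if strict else (t.max() <= d), (table, pid)
    # f-NEC animals must die; No-NEC never do
    assert p.loc[p["group"] == "F_NEC", "death_h"].notna().all()
    assert p.loc[p["group"] == "NO_NEC", "death_h"].isna().all()


def test_feed_times_stop_strictly_before_death():
    cfg = default_config()
    assert feed_times_for(np.inf, cfg).tolist() == list(range(48, 94, 3))
    assert feed_times_for(54.0, cfg).tolist() == [48.0, 51.0]


def test_noiseless_biomarker_draws_follow_kinetics():
    cfg = default_config()
    kin = BiomarkerKinetics(baseline=0.04, rise_onset_h=3.0, rise_rate=0.5,
                            plateau_peak=4.0, premortem_decay_fraction=0.25,
                            noise_sigma_log=0.0)
    cfg = dataclasses.replace(cfg, ifabp={**cfg.ifabp, "F_NEC": kin},
                              saa=dataclasses.replace(cfg.saa,
                                                      noise_sigma_log=0.0))
    rng = np.random.default_rng(0)
    t, v, saa = simulate_biomarkers("F_NEC", 60.0, cfg, rng)
    assert t.max() == 60.0
    assert v[t == 42.0][0] == pytest.approx(0.04)          # pre-feed baseline
    assert v[t == 54.0][0] == pytest.approx(0.04 + 0.5 * 3)
    # final pre-mortem draw: curve capped at the plateau, then decayed by 25 %
    assert v[-1] == pytest.approx(4.0 * 0.75)
    assert np.allclose(saa[t <= 48.0], cfg.saa.baseline)


def test_saa_has_no_group_signal():
    cfg = default_config()
    cfg = dataclasses.replace(cfg, saa=dataclasses.replace(
        cfg.saa, noise_sigma_log=0.0))
    rng = np.random.default_rng(0)
    curves = [simulate_biomarkers(g, np.inf, cfg, rng)[2]
              for g in ("F_NEC", "NF_NEC", "NO_NEC")]
    assert np.allclose(curves[0], curves[1])
    assert np.allclose(curves[0], curves[2])


def test_noiseless_necropsy_is_strictly_monotone():
    cfg = dataclasses.replace(
        default_config(),
        densitometry=dataclasses.replace(default_config().densitometry,
                                         noise_sd=0.0))
    rng = np.random.default_rng(5)
    rows = []
    for g, n in (("F_NEC", 7), ("NF_NEC", 14), ("NO_NEC", 17)):
        for i in range(n):
            s, au = simulate_necropsy(g, cfg, rng)
            rows.append((f"p{len(rows)}", s, au))
            if g == "NO_NEC":
                assert s <= 1
    nec = pd.DataFrame(rows, columns=["piglet_id", "nec_score",
                                      "densitometry_au"])
    assert densitometry_correlation(nec)["rho"] == pytest.approx(-1.0)


def test_validation_plateau_table_shape_and_ordering():
    df = simulate_validation_plateaus(5, seed=3)
    assert len(df) == 20
    assert set(df["fio2"]) == {0.08, 0.21, 0.60, 1.0}
    # oxygenation consistent with FiO2: hypoxic step reads lowest
    by = df.groupby("fio2")["sao2"].mean()
    assert by[0.08] < min(by[0.21], by[0.60], by[1.0])
    assert (df["scvo2"] <= df["sao2"]).all()


def test_noiseless_plateaus_fit_exactly():
    p = PlateauParams(noise_sd=0.0, slope=1.0, intercept=0.0)
    df = simulate_validation_plateaus(5, params=p, seed=3)
    fit = fit_calibration(df)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept_for(False) == pytest.approx(0.0, abs=1e-6)
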