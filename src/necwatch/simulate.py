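"""Synthetic premature-piglet monitoring cohorts.

The generator emulates the study design the analysis pipeline assumes: 48 h of
parenteral nutrition after preterm delivery, enteral feeds every 3 h from 48 h
until 96 h or death, continuous 2-s vitals (HR, SpO2, abdominal StO2),
6-hourly plasma biomarker draws (I-FABP, SAA), necropsy scoring, and the
separate 5-animal, 4-FiO2-plateau NIRS validation experiment.

Per animal, a vitals channel is

    value(t) = m_g(t) + u + dip(t) + e(t),   clamped to channel bounds,

where ``m_g`` is a group-specific piecewise-linear mean curve over 0–96 h
(flat over the first hour so the Table-1-style baseline is exact), ``u`` is a
between-animal offset ~ N(0, baseline_sd), ``dip`` is a transient post-feed
StO2 deflection (a fraction of the pre-feed level decaying exponentially over
the 15 min after each feed), and ``e`` is AR(1) noise on the 2-s grid.

Disease phenotypes drive censoring: fulminant-NEC animals become symptomatic
within 6 h of the first feed and die by 18 h after feeds; non-fulminant-NEC
animals show signs 18–24 h after feeds and survive to 96 h with probability
5/14; No-NEC animals complete the study.  Nothing — vitals, feeds, draws — is
generated past death.

Default numeric constants are calibrated so that the *expected* pipeline
outputs reproduce the cohort-level quantities the analysis targets (group
baselines and pooled StO2 means, peri-prandial variability, I-FABP pooled and
peak levels, densitometry correlation, plateau R^2); see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cohort import CHANNEL_BOUNDS, CHANNELS, GROUPS, Cohort, validate_cohort

FIO2_STEPS = (0.21, 0.60, 0.08, 1.0)  # study order of inspired-oxygen plateaus


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ChannelParams:
    """Group-specific vitals trajectory for one channel.

    ``knots_t``/``knots_v`` define the piecewise-linear mean curve (hours,
    level).  ``baseline_sd`` is the between-animal SD of a whole-curve offset;
    ``noise_sd`` the stationary SD of AR(1) noise with coefficient ``ar1_phi``
    on the raw sampling grid; ``feed_dip_amplitude`` the post-feed StO2 dip as
    a fraction of the pre-feed level, recovering with time constant
    ``feed_dip_tau_min`` minutes.
    """

    knots_t: tuple[float, ...]
    knots_v: tuple[float, ...]
    baseline_sd: float
    ar1_phi: float = 0.995
    noise_sd: float = 4.0
    feed_dip_amplitude: float = 0.0
    feed_dip_tau_min: float = 5.0

    def mean_curve(self, t_h: np.ndarray) -> np.ndarray:
        return np.interp(t_h, self.knots_t, self.knots_v)

    def validate(self, channel: str) -> None:
        lo, hi = CHANNEL_BOUNDS[channel]
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ConfigError("ar1_phi must lie in [0, 1)")
        if min(self.knots_v) < lo or max(self.knots_v) > hi:
            raise ConfigError(f"{channel} mean curve leaves bounds [{lo}, {hi}]")
        if self.feed_dip_amplitude < 0:
            raise ConfigError("feed_dip_amplitude must be >= 0")


@dataclass(frozen=True)
class BiomarkerKinetics:
    """Plasma I-FABP kinetics for one group.

    Mean level stays at ``baseline`` until ``rise_onset_h`` hours after the
    first feed, then rises linearly at ``rise_rate`` ng/mL/h toward
    ``plateau_peak``.  When the animal dies, the final draw's mean is reduced
    by ``premortem_decay_fraction`` (circulating protein exhausted / congested
    gut shortly before death).  Multiplicative lognormal assay noise with log
    SD ``noise_sigma_log`` (mean-1 corrected, so expectations follow the
    kinetic curve); values floored at zero.
    """

    baseline: float
    rise_onset_h: float
    rise_rate: float
    plateau_peak: float
    premortem_decay_fraction: float = 0.0
    noise_sigma_log: float = 0.35

    def mean_curve(self, t_h: np.ndarray, first_feed_h: float) -> np.ndarray:
        rise = self.rise_rate * np.clip(t_h - (first_feed_h + self.rise_onset_h),
                                        0.0, None)
        return self.baseline + np.clip(rise, 0.0, max(self.plateau_peak - self.baseline, 0.0))


@dataclass(frozen=True)
class SaaKinetics:
    """Serum amyloid A: identical across groups (the marker carries no NEC signal);
    low before feeds, rising linearly afterwards."""

    baseline: float = 12.0
    slope_per_h: float = 2.5
    noise_sigma_log: float = 0.4


@dataclass(frozen=True)
class DensitometryParams:
    """Jejunal I-FABP western-blot signal: linear decrease with NEC score plus
    Gaussian noise, floored at 0 AU."""

    base_au: float = 100.0
    slope_au_per_score: float = 12.0
    noise_sd: float = 17.35


@dataclass(frozen=True)
class CensoringParams:
    """Event-time windows (hours since birth) for the disease phenotypes."""

    fnec_symptom: tuple[float, float] = (48.5, 54.0)
    fnec_death: tuple[float, float] = (54.0, 66.0)
    nfnec_symptom: tuple[float, float] = (66.0, 72.0)
    nfnec_death_delay: tuple[float, float] = (4.0, 8.0)
    nfnec_survival_p: float = 5.0 / 14.0


@dataclass(frozen=True)
class PlateauParams:
    """NIRS validation experiment: per-FiO2 oxygenation plateaus and the affine
    monitor response measured_StO2 = a*ref + b (+ meconium offset) + noise."""

    sao2_mean: dict[float, float] = field(default_factory=lambda: {
        0.08: 45.0, 0.21: 88.0, 0.60: 95.0, 1.0: 98.5})
    av_gap_mean: dict[float, float] = field(default_factory=lambda: {
        0.08: 12.0, 0.21: 18.0, 0.60: 16.0, 1.0: 13.0})
    sao2_sd: float = 4.0
    av_gap_sd: float = 3.0
    slope: float = 1.0
    intercept: float = 0.0
    meconium_offset: float = -6.0
    meconium_fraction: float = 0.0
    noise_sd: float = 12.38


def _flat_first_hour(baseline: float, knots: list[tuple[float, float]]):
    """Mean-curve knots with a flat first hour at the group baseline."""
    t = (0.0, 1.0) + tuple(k[0] for k in knots)
    v = (baseline, baseline) + tuple(k[1] for k in knots)
    return t, v


# Group StO2 curve levels solved so that pooled 1-min epoch means under the
# default censoring reproduce the whole-study group means (69 / 71.9 / 78.4 %)
# while baselines stay at the Table-1-style values (64.9 / 74.2 / 79.5 %).
_STO2_KNOTS = {
    "F_NEC": _flat_first_hour(64.9, [(15.0, 70.424), (48.0, 70.424),
                                     (51.0, 69.424), (66.0, 61.924)]),
    "NF_NEC": _flat_first_hour(74.2, [(18.0, 74.737), (36.0, 74.237),
                                      (48.0, 73.237), (72.0, 66.237),
                                      (96.0, 70.237)]),
    "NO_NEC": _flat_first_hour(79.5, [(18.0, 78.988), (96.0, 77.888)]),
}

_SPO2_KNOTS = {
    "F_NEC": _flat_first_hour(53.1, [(15.0, 85.0), (18.0, 87.0), (24.0, 88.0),
                                     (48.0, 80.0), (54.0, 70.0), (66.0, 55.0)]),
    "NF_NEC": _flat_first_hour(77.5, [(3.0, 82.0), (15.0, 88.0), (48.0, 88.0),
                                      (96.0, 85.0)]),
    "NO_NEC": _flat_first_hour(89.4, [(18.0, 91.0), (96.0, 90.0)]),
}

_HR_KNOTS = {
    "F_NEC": _flat_first_hour(163.0, [(24.0, 175.0), (48.0, 185.0),
                                      (54.0, 210.0), (66.0, 222.0)]),
    "NF_NEC": _flat_first_hour(166.0, [(24.0, 172.0), (48.0, 189.0),
                                       (72.0, 215.0), (96.0, 222.0)]),
    "NO_NEC": _flat_first_hour(135.0, [(24.0, 158.0), (48.0, 180.0),
                                       (96.0, 209.0)]),
}

_BASELINE_SD = {  # between-animal SDs, Table-1 semantics
    "STO2": {"F_NEC": 6.7, "NF_NEC": 6.8, "NO_NEC": 7.6},
    "SPO2": {"F_NEC": 9.3, "NF_NEC": 1.8, "NO_NEC": 8.0},
    "HR": {"F_NEC": 14.8, "NF_NEC": 31.6, "NO_NEC": 6.9},
}

# Post-feed dip amplitudes (fraction of pre-feed StO2) solved so the expected
# peri-prandial statistic is 10.1 % for pooled NEC and 6.3 % for No-NEC under
# the default AR(1) noise.
_FEED_DIP = {"F_NEC": 0.3176, "NF_NEC": 0.3176, "NO_NEC": 0.1867}

_BIRTH_WEIGHT = {"F_NEC": (1170.0, 266.0), "NF_NEC": (1046.0, 192.0),
                 "NO_NEC": (1031.0, 242.0)}
_HCT = {"F_NEC": (22.8, 2.5), "NF_NEC": (20.9, 2.7), "NO_NEC": (19.6, 5.6)}

_SCORE_DIST = {
    "NO_NEC": {0: 0.6, 1: 0.4},
    "NF_NEC": {2: 0.35, 3: 0.40, 4: 0.25},
    "F_NEC": {4: 0.30, 5: 0.40, 6: 0.30},
}


def default_vitals_params() -> dict[str, dict[str, ChannelParams]]:
    params: dict[str, dict[str, ChannelParams]] = {}
    for g in GROUPS:
        params[g] = {
            "STO2": ChannelParams(*_STO2_KNOTS[g], baseline_sd=_BASELINE_SD["STO2"][g],
                                  ar1_phi=0.995, noise_sd=4.0,
                                  feed_dip_amplitude=_FEED_DIP[g]),
            "SPO2": ChannelParams(*_SPO2_KNOTS[g], baseline_sd=_BASELINE_SD["SPO2"][g],
                                  ar1_phi=0.99, noise_sd=3.0),
            "HR": ChannelParams(*_HR_KNOTS[g], baseline_sd=_BASELINE_SD["HR"][g],
                                ar1_phi=0.99, noise_sd=8.0),
        }
    return params


def default_ifabp_kinetics() -> dict[str, BiomarkerKinetics]:
    # Rates solved so that E[max post-feed draw] for f-NEC is 1.87 ng/mL, the
    # nf-NEC mean approaches 3.03 ng/mL by 96 h, and the pooled post-feed NEC
    # mean is 0.66 ng/mL; baselines are the printed pre-feed levels.
    return {
        "F_NEC": BiomarkerKinetics(baseline=0.04, rise_onset_h=3.0,
                                   rise_rate=0.4097, plateau_peak=4.0,
                                   premortem_decay_fraction=0.25,
                                   noise_sigma_log=0.35),
        "NF_NEC": BiomarkerKinetics(baseline=0.01, rise_onset_h=17.35,
                                    rise_rate=0.0985, plateau_peak=3.03,
                                    premortem_decay_fraction=0.25,
                                    noise_sigma_log=0.35),
        "NO_NEC": BiomarkerKinetics(baseline=0.09, rise_onset_h=0.0,
                                    rise_rate=0.0, plateau_peak=0.09,
                                    noise_sigma_log=0.35),
    }


@dataclass
class SimConfig:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"F_NEC": 7, "NF_NEC": 14, "NO_NEC": 17})
    seed: int = 0
    sample_period_s: float = 2.0
    study_end_h: float = 96.0
    first_feed_h: float = 48.0
    feed_interval_h: float = 3.0
    last_feed_h: float = 93.0
    draw_interval_h: float = 6.0
    feed_volume_ml_per_kg: float = 12.0
    vitals: dict[str, dict[str, ChannelParams]] = field(
        default_factory=default_vitals_params)
    ifabp: dict[str, BiomarkerKinetics] = field(
        default_factory=default_ifabp_kinetics)
    saa: SaaKinetics = field(default_factory=SaaKinetics)
    densitometry: DensitometryParams = field(default_factory=DensitometryParams)
    score_dist: dict[str, dict[int, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in _SCORE_DIST.items()})
    censoring: CensoringParams = field(default_factory=CensoringParams)
    plateaus: PlateauParams = field(default_factory=PlateauParams)

    def validate(self) -> None:
        for g in GROUPS:
            if self.n_per_group.get(g, 0) < 1:
                raise ConfigError(f"n_per_group[{g}] must be >= 1")
            for ch in CHANNELS:
                self.vitals[g][ch].validate(ch)
        if self.sample_period_s <= 0:
            raise ConfigError("sample_period_s must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=str, indent=2,
                          sort_keys=True)


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def _ar1(n: int, phi: float, stationary_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series of length n with the given marginal SD."""
    if n == 0:
        return np.zeros(0)
    x0 = rng.standard_normal() * stationary_sd
    if stationary_sd == 0.0:
        return np.zeros(n)
    eps = rng.standard_normal(n) * stationary_sd * np.sqrt(1.0 - phi ** 2)
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def _event_times(group: str, cen: CensoringParams, study_end: float,
                 rng: np.random.Generator) -> tuple[float, float]:
    """(symptom_onset_h, death_h); NaN when the event never occurs."""
    if group == "F_NEC":
        sym = rng.uniform(*cen.fnec_symptom)
        death = rng.uniform(*cen.fnec_death)
        return sym, max(death, sym)
    if group == "NF_NEC":
        sym = rng.uniform(*cen.nfnec_symptom)
        survives = rng.uniform() < cen.nfnec_survival_p
        if survives:
            return sym, np.nan
        death = min(sym + rng.uniform(*cen.nfnec_death_delay), study_end)
        return sym, death
    return np.nan, np.nan


def feed_times_for(death_h: float, cfg: SimConfig) -> np.ndarray:
    """Feed times for an animal: the 3-h grid from 48 h, strictly before death."""
    t = np.arange(cfg.first_feed_h, cfg.last_feed_h + 1e-9, cfg.feed_interval_h)
    limit = min(death_h, cfg.study_end_h) if np.isfinite(death_h) else cfg.study_end_h
    return t[t < limit]


def simulate_vitals_channel(params: ChannelParams, channel: str, death_h: float,
                            feed_times: np.ndarray, cfg: SimConfig,
                            rng: np.random.Generator,
                            animal_offset: float | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """2-s samples (t_h, value) for one animal/channel, truncated at death."""
    params.validate(channel)
    end = min(death_h, cfg.study_end_h) if np.isfinite(death_h) else cfg.study_end_h
    per_h = 3600.0 / cfg.sample_period_s
    n = int(np.ceil(end * per_h)) - 1 if np.isclose(end * per_h, round(end * per_h)) \
        else int(np.floor(end * per_h))
    n = max(n, 0)
    t = np.arange(1, n + 1) / per_h
    if animal_offset is None:
        animal_offset = rng.standard_normal() * params.baseline_sd
    mean = params.mean_curve(t) + animal_offset
    if channel == "STO2" and params.feed_dip_amplitude > 0:
        tau_h = params.feed_dip_tau_min / 60.0
        for tf in feed_times:
            lo = np.searchsorted(t, tf, side="right")
            hi = np.searchsorted(t, tf + 0.25, side="right")
            if hi > lo:
                pre_level = float(np.interp(tf, params.knots_t, params.knots_v)) \
                    + animal_offset
                mean[lo:hi] -= (params.feed_dip_amplitude * pre_level
                                * np.exp(-(t[lo:hi] - tf) / tau_h))
    values = mean + _ar1(n, params.ar1_phi, params.noise_sd, rng)
    lo_b, hi_b = CHANNEL_BOUNDS[channel]
    np.clip(values, lo_b + (1e-9 if channel == "HR" else 0.0), hi_b, out=values)
    return t, values


def simulate_biomarkers(group: str, death_h: float, cfg: SimConfig,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """6-hourly (t_h, ifabp, saa) draws up to and including death."""
    end = min(death_h, cfg.study_end_h) if np.isfinite(death_h) else cfg.study_end_h
    t = np.arange(0.0, cfg.study_end_h + 1e-9, cfg.draw_interval_h)
    t = t[t <= end + 1e-9]
    kin = cfg.ifabp[group]
    mean = kin.mean_curve(t, cfg.first_feed_h)
    if np.isfinite(death_h) and len(t) >= 2 and kin.premortem_decay_fraction > 0:
        mean = mean.copy()
        mean[-1] *= (1.0 - kin.premortem_decay_fraction)
    ifabp = mean * _lognoise(len(t), kin.noise_sigma_log, rng)
    saa_mean = cfg.saa.baseline + cfg.saa.slope_per_h * np.clip(
        t - cfg.first_feed_h, 0.0, None)
    saa = saa_mean * _lognoise(len(t), cfg.saa.noise_sigma_log, rng)
    return t, np.maximum(ifabp, 0.0), np.maximum(saa, 0.0)


def _lognoise(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        rng.standard_normal(n)  # keep the draw count stable across configs
        return np.ones(n)
    return np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma ** 2)


def simulate_necropsy(group: str, cfg: SimConfig,
                      rng: np.random.Generator) -> tuple[int, float]:
    dist = cfg.score_dist[group]
    scores = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[s] for s in scores], dtype=float)
    score = int(rng.choice(scores, p=probs / probs.sum()))
    au = (cfg.densitometry.base_au
          - cfg.densitometry.slope_au_per_score * score
          + rng.standard_normal() * cfg.densitometry.noise_sd)
    return score, max(au, 0.0)


def simulate_validation_plateaus(n_piglets: int = 5,
                                 params: PlateauParams | None = None,
                                 rng: np.random.Generator | None = None,
                                 seed: int | None = None) -> pd.DataFrame:
    """Calibration-plateau table: per animal, 4 FiO2 steps with CO-oximetry
    SaO2/ScvO2 and the monitor's raw StO2 reading."""
    if n_piglets < 1:
        raise ConfigError("n_piglets must be >= 1")
    params = params or PlateauParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_piglets):
        pid = f"V{i + 1:02d}"
        meconium = rng.uniform() < params.meconium_fraction
        for fio2 in FIO2_STEPS:
            sao2 = np.clip(params.sao2_mean[fio2]
                           + rng.standard_normal() * params.sao2_sd, 0.0, 100.0)
            gap = max(params.av_gap_mean[fio2]
                      + rng.standard_normal() * params.av_gap_sd, 0.0)
            scvo2 = np.clip(sao2 - gap, 0.0, sao2)
            ref = 0.3 * sao2 + 0.7 * scvo2
            measured = (params.slope * ref + params.intercept
                        + (params.meconium_offset if meconium else 0.0)
                        + rng.standard_normal() * params.noise_sd)
            rows.append((pid, fio2, sao2, scvo2,
                         float(np.clip(measured, 0.0, 100.0)), meconium))
    return pd.DataFrame(rows, columns=["piglet_id", "fio2", "sao2", "scvo2",
                                       "measured_sto2", "meconium_present"])


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None,
                    validate: bool = True) -> Cohort:
    """Draw a full cohort bundle under ``config`` (deterministic given the seed)."""
    cfg = config or default_config()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    piglet_rows, vit_parts, feed_rows, bio_rows, nec_rows = [], [], [], [], []
    idx = 0
    for group in GROUPS:
        for _ in range(cfg.n_per_group[group]):
            idx += 1
            pid = f"P{idx:02d}"
            litter = f"L{(idx - 1) % 4 + 1}"
            w_mu, w_sd = _BIRTH_WEIGHT[group]
            weight = max(float(rng.normal(w_mu, w_sd)), 400.0)
            h_mu, h_sd = _HCT[group]
            hct = float(np.clip(rng.normal(h_mu, h_sd), 5.0, 60.0))
            sym, death = _event_times(group, cfg.censoring, cfg.study_end_h, rng)
            piglet_rows.append((pid, litter, weight, hct, group, sym, death))

            feeds = feed_times_for(death if np.isfinite(death) else np.inf, cfg)
            for tf in feeds:
                feed_rows.append((pid, float(tf), cfg.feed_volume_ml_per_kg))

            for ch in CHANNELS:
                t, v = simulate_vitals_channel(cfg.vitals[group][ch], ch,
                                               death if np.isfinite(death) else np.inf,
                                               feeds, cfg, rng)
                vit_parts.append((pid, ch, t, v))

            tb, ifabp, saa = simulate_biomarkers(
                group, death if np.isfinite(death) else np.inf, cfg, rng)
            for k in range(len(tb)):
                bio_rows.append((pid, float(tb[k]), float(ifabp[k]), float(saa[k])))

            score, au = simulate_necropsy(group, cfg, rng)
            nec_rows.append((pid, score, au))

    piglets = pd.DataFrame(piglet_rows, columns=[
        "piglet_id", "litter_id", "birth_weight_g", "baseline_hct",
        "group", "symptom_onset_h", "death_h"])
    pids = sorted({pid for pid, _, _, _ in vit_parts})
    pid_code = {p: i for i, p in enumerate(pids)}
    ch_code = {c: i for i, c in enumerate(CHANNELS)}
    lengths = np.array([len(t) for _, _, t, _ in vit_parts])
    pid_codes = np.repeat([pid_code[p] for p, _, _, _ in vit_parts], lengths)
    ch_codes = np.repeat([ch_code[c] for _, c, _, _ in vit_parts], lengths)
    vitals = pd.DataFrame({
        "piglet_id": pd.Categorical.from_codes(pid_codes, categories=pids),
        "channel": pd.Categorical.from_codes(ch_codes,
                                             categories=list(CHANNELS)),
        "t_h": np.concatenate([t for _, _, t, _ in vit_parts]),
        "value": np.concatenate([v for _, _, _, v in vit_parts])})
    feeds = pd.DataFrame(feed_rows, columns=["piglet_id", "t_h", "volume_ml_per_kg"])
    biomarkers = pd.DataFrame(bio_rows, columns=["piglet_id", "t_h",
                                                 "ifabp_ng_ml", "saa_ng_ml"])
    necropsy = pd.DataFrame(nec_rows, columns=["piglet_id", "nec_score",
                                               "densitometry_au"])
    cohort = Cohort(piglets, vitals, feeds, biomarkers, necropsy)
    if validate:
        validate_cohort(cohort)
    return cohort
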