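"""Canonical data model and long-format CSV I/O for the premature-piglet NEC cohort.

A cohort bundle is five cross-referenced tables:

* ``piglets``    — one row per animal: litter, birth weight, baseline hematocrit,
  NEC severity group (``F_NEC`` fulminant, ``NF_NEC`` non-fulminant, ``NO_NEC``),
  and the censoring times (symptom onset and death, hours since birth; empty when
  the event never occurred).
* ``vitals``     — continuous monitor streams (heart rate, systemic SpO2,
  abdominal tissue StO2) sampled nominally every 2 s.
* ``feeds``      — the enteral feeding schedule (every 3 h from 48 h).
* ``biomarkers`` — 6-hourly plasma I-FABP and SAA draws.
* ``necropsy``   — one row per animal: ordinal histologic NEC score (0–6) and
  jejunal I-FABP western-blot densitometry (arbitrary units).

Time is fractional hours since birth throughout, so feeds fall on exact 3-h
marks and window arithmetic is exact.  Missing values are empty CSV cells,
never numeric sentinels.  ``read_cohort(write_cohort(b)) == b`` field for field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

GROUPS = ("F_NEC", "NF_NEC", "NO_NEC")
NEC_GROUPS = ("F_NEC", "NF_NEC")
CHANNELS = ("HR", "SPO2", "STO2")

#: Physiological bounds per channel: HR in bpm, saturations in percent.
CHANNEL_BOUNDS = {"HR": (0.0, 400.0), "SPO2": (0.0, 100.0), "STO2": (0.0, 100.0)}

FILE_NAMES = {
    "piglets": "piglets.csv",
    "vitals": "vitals.csv",
    "feeds": "feeds.csv",
    "biomarkers": "biomarkers.csv",
    "necropsy": "necropsy.csv",
}

COLUMNS = {
    "piglets": ["piglet_id", "litter_id", "birth_weight_g", "baseline_hct",
                "group", "symptom_onset_h", "death_h"],
    "vitals": ["piglet_id", "channel", "t_h", "value"],
    "feeds": ["piglet_id", "t_h", "volume_ml_per_kg"],
    "biomarkers": ["piglet_id", "t_h", "ifabp_ng_ml", "saa_ng_ml"],
    "necropsy": ["piglet_id", "nec_score", "densitometry_au"],
}


class CohortError(ValueError):
    """Base class for cohort I/O and validation failures."""


class SchemaError(CohortError):
    """A table is missing a declared column."""


class ReferentialError(CohortError):
    """A piglet_id does not resolve against the piglets table."""


class ValidationError(CohortError):
    """A row violates a stated invariant."""


@dataclass
class Cohort:
    piglets: pd.DataFrame
    vitals: pd.DataFrame
    feeds: pd.DataFrame
    biomarkers: pd.DataFrame
    necropsy: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def group_counts(self) -> dict[str, int]:
        counts = self.piglets["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def nec_incidence_pct(self) -> int:
        """Percent of animals developing NEC, rounded to integer percent."""
        n = len(self.piglets)
        if n == 0:
            raise ValidationError("empty cohort has no incidence")
        n_nec = int(self.piglets["group"].isin(NEC_GROUPS).sum())
        return round(100 * n_nec / n)

    def equals(self, other: "Cohort") -> bool:
        for name, tab in self.tables().items():
            if not _normalize(tab).equals(_normalize(getattr(other, name))):
                return False
        return True


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.reset_index(drop=True).copy()
    for c in out.columns:
        if isinstance(out[c].dtype, pd.CategoricalDtype):
            out[c] = out[c].astype(str)
    return out


def _require_columns(df: pd.DataFrame, table: str) -> None:
    for col in COLUMNS[table]:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing column {col!r}")


def _sort(c: Cohort) -> Cohort:
    kind = "mergesort"  # stable, deterministic
    c.piglets = c.piglets.sort_values("piglet_id", kind=kind).reset_index(drop=True)
    c.vitals = c.vitals.sort_values(["piglet_id", "channel", "t_h"],
                                    kind=kind).reset_index(drop=True)
    c.feeds = c.feeds.sort_values(["piglet_id", "t_h"], kind=kind).reset_index(drop=True)
    c.biomarkers = c.biomarkers.sort_values(["piglet_id", "t_h"],
                                            kind=kind).reset_index(drop=True)
    c.necropsy = c.necropsy.sort_values("piglet_id", kind=kind).reset_index(drop=True)
    return c


def validate_cohort(c: Cohort) -> None:
    """Enforce every schema, referential and row-level invariant; raise on breach."""
    for name, tab in c.tables().items():
        _require_columns(tab, name)

    p = c.piglets
    if p["piglet_id"].duplicated().any():
        dup = p.loc[p["piglet_id"].duplicated(), "piglet_id"].iloc[0]
        raise ValidationError(f"piglets: duplicate piglet_id {dup!r}")
    ids = set(p["piglet_id"].astype(str))

    bad = ~p["group"].isin(GROUPS)
    if bad.any():
        raise ValidationError(f"piglets: unknown group {p.loc[bad, 'group'].iloc[0]!r}")
    if (p["birth_weight_g"] <= 0).any():
        raise ValidationError("piglets: birth_weight_g must be > 0")
    if ((p["baseline_hct"] <= 0) | (p["baseline_hct"] > 100)).any():
        raise ValidationError("piglets: baseline_hct must lie in (0, 100]")

    sym, death = p["symptom_onset_h"], p["death_h"]
    if ((p["group"] == "NO_NEC") & sym.notna()).any():
        raise ValidationError("piglets: NO_NEC animal has symptom_onset_h")
    both = sym.notna() & death.notna()
    if (death[both] < sym[both]).any():
        raise ValidationError("piglets: death_h earlier than symptom_onset_h")
    if ((p["group"] == "F_NEC") & death.isna()).any():
        raise ValidationError("piglets: F_NEC animal lacks death_h")
    if (death.dropna() <= 0).any() or (death.dropna() > 96).any():
        raise ValidationError("piglets: death_h outside (0, 96]")
    death_by_id = dict(zip(p["piglet_id"].astype(str), death.to_numpy()))

    v = c.vitals
    ch_codes, ch_index = _factorize(v["channel"])
    unknown = [c_ for c_ in ch_index if c_ not in CHANNELS]
    if unknown:
        raise ValidationError(f"vitals: unknown channel {unknown[0]!r}")
    _check_ids(v, ids, "vitals")
    vals = v["value"].to_numpy(float)
    for k, ch in enumerate(ch_index):
        lo, hi = CHANNEL_BOUNDS[ch]
        sel = vals[ch_codes == k]
        if ((sel <= lo) if ch == "HR" else (sel < lo)).any() or (sel > hi).any():
            raise ValidationError(f"vitals: {ch} value out of bounds ({lo}, {hi}]")
    _check_strictly_increasing(v)
    _check_before_death(v, death_by_id, "vitals", strict=True)

    f = c.feeds
    _check_ids(f, ids, "feeds")
    if (f["volume_ml_per_kg"] < 0).any():
        raise ValidationError("feeds: negative volume_ml_per_kg")
    t = f["t_h"].to_numpy(float)
    on_grid = np.isclose((t - 48.0) % 3.0, 0.0) | np.isclose((t - 48.0) % 3.0, 3.0)
    if len(t) and ((t < 48) | (t > 93) | ~on_grid).any():
        row = int(np.flatnonzero((t < 48) | (t > 93) | ~on_grid)[0])
        raise ValidationError(f"feeds: row {row} not on the 48..93 h 3-h grid")
    _check_before_death(f, death_by_id, "feeds", strict=True)

    b = c.biomarkers
    _check_ids(b, ids, "biomarkers")
    tb = b["t_h"].to_numpy(float)
    if len(tb) and ((tb < 0) | (tb > 96) | ~np.isclose(tb % 6.0, 0.0)).any():
        raise ValidationError("biomarkers: t_h must be a multiple of 6 in [0, 96]")
    if b.duplicated(subset=["piglet_id", "t_h"]).any():
        raise ValidationError("biomarkers: duplicate draw for a (piglet, t_h)")
    if (b["ifabp_ng_ml"] < 0).any() or (b["saa_ng_ml"] < 0).any():
        raise ValidationError("biomarkers: negative concentration")
    _check_before_death(b, death_by_id, "biomarkers", strict=False)

    n = c.necropsy
    _check_ids(n, ids, "necropsy")
    if set(n["piglet_id"].astype(str)) != ids or len(n) != len(ids):
        raise ValidationError("necropsy: exactly one record per piglet required")
    score = n["nec_score"].to_numpy()
    if ((score < 0) | (score > 6) | (score != score.astype(int))).any():
        raise ValidationError("necropsy: nec_score must be an integer in 0..6")
    if (n["densitometry_au"] < 0).any():
        raise ValidationError("necropsy: negative densitometry_au")
    grp = dict(zip(p["piglet_id"].astype(str), p["group"]))
    no_nec = n["piglet_id"].astype(str).map(grp) == "NO_NEC"
    if (n.loc[no_nec, "nec_score"] > 1).any():
        raise ValidationError("necropsy: NO_NEC animal with nec_score > 1")


def _factorize(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    """(codes, labels) without materializing per-row Python strings."""
    codes, index = pd.factorize(series, sort=False)
    return codes, [str(x) for x in index]


def _check_ids(df: pd.DataFrame, ids: set, table: str) -> None:
    _, labels = _factorize(df["piglet_id"])
    for lab in labels:
        if lab not in ids:
            raise ReferentialError(f"{table}: unknown piglet_id {lab!r}")


def _check_strictly_increasing(v: pd.DataFrame) -> None:
    if len(v) < 2:
        return
    pid_codes, pid_labels = _factorize(v["piglet_id"])
    ch_codes, ch_labels = _factorize(v["channel"])
    t = v["t_h"].to_numpy(float)
    same = (pid_codes[1:] == pid_codes[:-1]) & (ch_codes[1:] == ch_codes[:-1])
    bad = same & (np.diff(t) <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(
            f"vitals: row {row} — t_h not strictly increasing for "
            f"({pid_labels[pid_codes[row]]}, {ch_labels[ch_codes[row]]})")


def _check_before_death(df: pd.DataFrame, death_by_id: dict, table: str,
                        strict: bool) -> None:
    if not len(df):
        return
    codes, labels = _factorize(df["piglet_id"])
    per_label = np.array([death_by_id.get(lab, np.nan) for lab in labels])
    limit = per_label[codes]
    t = df["t_h"].to_numpy(float)
    has = ~np.isnan(limit)
    bad = (t[has] >= limit[has]) if strict else (t[has] > limit[has])
    if bad.any():
        raise ValidationError(f"{table}: sample recorded after death_h")


def read_cohort(in_dir: str, validate: bool = True) -> Cohort:
    """Read the five-table bundle from ``in_dir`` and cross-validate it."""
    frames = {}
    for name, fname in FILE_NAMES.items():
        path = os.path.join(in_dir, fname)
        if not os.path.exists(path):
            raise CohortError(f"missing cohort file: {path}")
        df = pd.read_csv(path, dtype={"piglet_id": str},
                         float_precision="round_trip")
        _require_columns(df, name)
        frames[name] = df[COLUMNS[name]]
    if "nec_score" in frames["necropsy"] and len(frames["necropsy"]):
        frames["necropsy"]["nec_score"] = frames["necropsy"]["nec_score"].astype(int)
    cohort = _sort(Cohort(**frames))
    if validate:
        validate_cohort(cohort)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str, validate: bool = True) -> dict[str, str]:
    """Write the bundle as five CSV files; returns the written paths.

    Floats are written at full repr precision so that a read-back reproduces
    the bundle exactly; missing events are empty cells.
    """
    if validate:
        validate_cohort(cohort)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, tab in _sort(cohort).tables().items():
        path = os.path.join(out_dir, FILE_NAMES[name])
        tab.to_csv(path, index=False, na_rep="")
        paths[name] = path
    return paths
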