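import os
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("ci")

# make scripts/acceptance.py importable for the acceptance tests
sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "scripts"))

from necwatch.cohort import Cohort  # noqa: E402
from necwatch.preprocess import epochs_for_cohort  # noqa: E402
from necwatch.simulate import default_config, simulate_cohort  # noqa: E402


def make_bundle(death_f: float = 60.0) -> Cohort:
    """Small hand-built, valid cohort bundle (one animal per group)."""
    piglets = pd.DataFrame({
        "piglet_id": ["P01", "P02", "P03"],
        "litter_id": ["L1", "L1", "L2"],
        "birth_weight_g": [1170.0, 1046.0, 1031.0],
        "baseline_hct": [22.8, 20.9, 19.6],
        "group": ["F_NEC", "NF_NEC", "NO_NEC"],
        "symptom_onset_h": [50.0, 68.0, np.nan],
        "death_h": [death_f, np.nan, np.nan],
    })
    t = np.arange(1, 61) * (2.0 / 3600.0)
    vitals = pd.concat([
        pd.DataFrame({"piglet_id": pid, "channel": ch, "t_h": t,
                      "value": v})
        for pid, ch, v in [("P01", "STO2", 64.9), ("P02", "STO2", 74.2),
                           ("P03", "STO2", 79.5), ("P03", "HR", 135.0)]
    ], ignore_index=True)
    feeds = pd.DataFrame({
        "piglet_id": ["P01", "P02", "P03"],
        "t_h": [48.0, 48.0, 51.0],
        "volume_ml_per_kg": [12.0, 12.0, 12.0]})
    biomarkers = pd.DataFrame({
        "piglet_id": ["P01", "P01", "P02", "P03"],
        "t_h": [0.0, 54.0, 48.0, 96.0],
        "ifabp_ng_ml": [0.04, 1.9, 0.01, 0.08],
        "saa_ng_ml": [10.0, 40.0, 12.0, 80.0]})
    necropsy = pd.DataFrame({
        "piglet_id": ["P01", "P02", "P03"],
        "nec_score": [6, 3, 0],
        "densitometry_au": [30.0, 60.0, 100.0]})
    return Cohort(piglets, vitals, feeds, biomarkers, necropsy)


@pytest.fixture
def bundle() -> Cohort:
    return make_bundle()


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """One full default cohort (38 animals, 2-s streams), shared per session."""
    return simulate_cohort(default_config(seed=42))


@pytest.fixture(scope="session")
def default_epochs(default_cohort):
    return epochs_for_cohort(default_cohort)


def make_epochs(piglet_id, channel, start_h, values, n_samples=30):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({
        "piglet_id": piglet_id,
        "channel": channel,
        "epoch_start_h": start_h + np.arange(len(values)) / 60.0,
        "mean_value": values,
        "n_samples": n_samples,
    })
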