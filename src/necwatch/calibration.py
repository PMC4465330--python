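"""NIRS validation-study calibration.

The monitor's StO2 reading is validated against a weighted arterio-venous
composite of CO-oximetry saturations,

    REF = 0.3 * SaO2 + 0.7 * ScvO2,

reflecting the ~30 % arterial / 70 % venous blood-volume mix the optical
signal interrogates.  Across stepped-FiO2 oxygenation plateaus, measured StO2
is regressed on REF with a shared slope and a stratum-specific intercept for
meconium presence (meconium is an optical chromophore that offsets the
absorbance but has no stated functional form beyond that).  The Pearson
correlation (and its square) over all plateaus is the validation diagnostic;
the inverse affine map converts raw readings to corrected StO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ARTERIAL_WEIGHT = 0.3
VENOUS_WEIGHT = 0.7


class CalibrationError(ValueError):
    pass


def composite_reference(sao2, scvo2):
    """Weighted arterio-venous reference saturation, 0.3*SaO2 + 0.7*ScvO2 (%)."""
    sao2 = np.asarray(sao2, dtype=float)
    scvo2 = np.asarray(scvo2, dtype=float)
    if ((sao2 < 0) | (sao2 > 100) | (scvo2 < 0) | (scvo2 > 100)).any():
        raise CalibrationError("saturations must lie in [0, 100]")
    out = ARTERIAL_WEIGHT * sao2 + VENOUS_WEIGHT * scvo2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercepts: dict[bool, float]  # keyed by meconium_present
    pearson_r: float
    r_squared: float
    n_points: int
    strata: tuple[bool, ...] = field(default=(False,))

    def intercept_for(self, meconium: bool = False) -> float:
        if meconium in self.intercepts:
            return self.intercepts[meconium]
        return next(iter(self.intercepts.values()))


def fit_calibration(plateaus: pd.DataFrame) -> CalibrationFit:
    """Least-squares calibration of measured StO2 on the composite reference.

    Shared slope; one intercept per meconium stratum (when both strata are
    present).  Requires >= 3 plateaus per stratum and a non-degenerate
    reference.  Pearson r / r^2 are computed over all points jointly.
    """
    ref = composite_reference(plateaus["sao2"], plateaus["scvo2"])
    y = plateaus["measured_sto2"].to_numpy(float)
    mec = (plateaus["meconium_present"].to_numpy(bool)
           if "meconium_present" in plateaus else np.zeros(len(y), bool))
    strata = tuple(sorted(set(mec.tolist())))
    for s in strata:
        if (mec == s).sum() < 3:
            raise CalibrationError(
                f"need >= 3 plateaus in meconium stratum {s}")
    if np.isclose(np.var(ref), 0.0):
        raise CalibrationError("zero-variance reference: singular fit")

    # design: [ref, 1{stratum}] -> shared slope, per-stratum intercept
    X = np.column_stack([ref] + [(mec == s).astype(float) for s in strata])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = float(beta[0])
    intercepts = {bool(s): float(beta[1 + i]) for i, s in enumerate(strata)}

    r = float(stats.pearsonr(ref, y).statistic)
    return CalibrationFit(slope=slope, intercepts=intercepts, pearson_r=r,
                          r_squared=r * r, n_points=len(y), strata=strata)


def apply_calibration(fit: CalibrationFit, raw_sto2,
                      meconium: bool = False):
    """Invert the fitted affine response: corrected = (raw - b) / a, clamped
    to [0, 100] %."""
    if np.isclose(fit.slope, 0.0):
        raise CalibrationError("zero slope: singular fit cannot be inverted")
    raw = np.asarray(raw_sto2, dtype=float)
    out = np.clip((raw - fit.intercept_for(meconium)) / fit.slope, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out
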