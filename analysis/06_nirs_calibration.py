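"""NIRS validation: calibrate monitor StO2 against the arterio-venous composite.

Five instrumented piglets are stepped through four FiO2 plateaus (0.21, 0.60,
0.08, 1.0); at each plateau CO-oximetry gives SaO2 and ScvO2, and the monitor
reading is regressed on the composite reference 0.3*SaO2 + 0.7*ScvO2.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from necwatch.calibration import apply_calibration, fit_calibration
from necwatch.simulate import simulate_validation_plateaus

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 42


def main():
    plateaus = simulate_validation_plateaus(5, seed=SEED)
    plateaus.to_csv(os.path.join(BASE, "plateaus.csv"), index=False)
    fit = fit_calibration(plateaus)
    with open(os.path.join(BASE, "calibration_fit.json"), "w") as fh:
        json.dump({"slope": fit.slope,
                   "intercepts": {str(k): v for k, v in fit.intercepts.items()},
                   "pearson_r": fit.pearson_r, "r_squared": fit.r_squared,
                   "n_points": fit.n_points, "seed": SEED}, fh, indent=2)

    print(f"calibration over {fit.n_points} plateaus "
          f"({len(set(plateaus['piglet_id']))} piglets x 4 FiO2 steps):")
    print(f"  measured = {fit.slope:.3f} * ref + "
          f"{fit.intercept_for(False):.2f}")
    print(f"  Pearson r = {fit.pearson_r:.3f}, R^2 = {fit.r_squared:.3f}")
    print(f"  raw 75 % reads back as corrected "
          f"{apply_calibration(fit, 75.0):.1f} %")


if __name__ == "__main__":
    main()
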