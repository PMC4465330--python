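"""ROC screening: where do the decision boundaries fall?

Abdominal StO2 is screened at the 1-min epoch level over the pre-feed window
(hours 0-48, lower-is-positive); plasma I-FABP at the draw level over the
feeding period (t >= 48 h, higher-is-positive).  Cutoffs are chosen by the
Youden index.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from necwatch import read_cohort
from necwatch.diagnostics import screen_ifabp, screen_sto2

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    cohort = read_cohort(os.path.join(BASE, "cohort"))
    epochs = pd.read_csv(os.path.join(BASE, "epochs.csv"))

    roc_s = screen_sto2(epochs, cohort.piglets)
    roc_i = screen_ifabp(cohort.biomarkers, cohort.piglets)
    for roc, name in ((roc_s, "roc_sto2"), (roc_i, "roc_ifabp")):
        pd.DataFrame({"threshold": roc.thresholds, "sens": roc.sens,
                      "spec": roc.spec}).to_csv(
            os.path.join(BASE, f"{name}.csv"), index=False)

    print(f"abdominal StO2 (epoch-level, 0-48 h, lower is positive):")
    print(f"  Youden cutoff {roc_s.chosen_cutoff:5.1f} %  "
          f"sens {roc_s.sens_at_cutoff:.2f}  spec {roc_s.spec_at_cutoff:.2f}  "
          f"AUC {roc_s.auc:.3f}  ({roc_s.n_pos + roc_s.n_neg} epochs)")
    print(f"plasma I-FABP (draw-level, t >= 48 h, higher is positive):")
    print(f"  Youden cutoff {roc_i.chosen_cutoff:5.3f} ng/mL  "
          f"sens {roc_i.sens_at_cutoff:.2f}  spec {roc_i.spec_at_cutoff:.2f}  "
          f"AUC {roc_i.auc:.3f}  ({roc_i.n_pos + roc_i.n_neg} draws)")


if __name__ == "__main__":
    main()
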