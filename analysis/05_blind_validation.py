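"""Stage 5: blind classification of the validation cohort + concordance.

The classifier sees only the feature matrix; truth labels enter at the
scoring step.
"""

import dataclasses

import pandas as pd

from serumpep import classify as clf
from serumpep.clinical import confusion_summary
from serumpep.pipeline import classify_cohort

from common import RESULTS, load_feature_matrix

if __name__ == "__main__":
    model = clf.load_model(RESULTS / "best_model.json")
    fm = load_feature_matrix("validation")
    preds = classify_cohort(model, fm)
    preds.to_csv(RESULTS / "validation_predictions.csv", index=False)

    truth = pd.read_csv(RESULTS / "validation_cohort.csv")
    records = preds.merge(truth.rename(columns={"true_class": "truth"}),
                          on="sample_id")
    s = confusion_summary(records)
    pd.DataFrame([dataclasses.asdict(s)]).to_csv(
        RESULTS / "confusion_summary.csv", index=False)
    print(f"confusion: tp={s.tp} fn={s.fn} fp={s.fp} tn={s.tn} "
          f"invalid={s.invalid_mutant + s.invalid_wild}")
    print(f"sensitivity {s.sensitivity_pct:.1f}% / "
          f"specificity {s.specificity_pct:.1f}% / "
          f"accuracy {s.accuracy_pct:.1f}%")
    print(f"kappa {s.kappa:.3f} (p = {s.kappa_p:.2e})")
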