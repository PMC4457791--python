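"""Stage 1: simulate the training and validation cohorts.

Writes the per-patient metadata tables (class, validity flag, treatment and
outcome fields for the validation arm) to results/; spectra are regenerated
on demand by later stages from the same seed.
"""

import pandas as pd

from serumpep.simulate import OutcomeParams, simulate_cohort, simulate_outcomes

from common import RESULTS, STUDY

if __name__ == "__main__":
    RESULTS.mkdir(parents=True, exist_ok=True)
    for stem, sim in (("training", STUDY.training_sim()),
                      ("validation", STUDY.validation_sim())):
        spectra, meta = simulate_cohort(sim)
        if stem == "validation":
            meta = simulate_outcomes(
                meta, OutcomeParams(seed=STUDY.seed * 2 + 3,
                                    **STUDY.outcome_params))
        meta.to_csv(RESULTS / f"{stem}_cohort.csv", index=False)
        counts = meta["true_class"].value_counts()
        print(f"{stem}: {len(spectra)} spectra "
              f"({counts.get('mutant', 0)} mutant / {counts.get('wild', 0)} wild), "
              f"{int(meta['invalid_flag'].sum())} invalid acquisitions")
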