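"""Stage 2: preprocess both cohorts into feature matrices.

Peak definitions come from the training cohort only and are pinned when
integrating the validation cohort, exactly as the blinded design requires.
"""

from serumpep.pipeline import preprocess_cohort
from serumpep.simulate import simulate_cohort

from common import STUDY, save_feature_matrix

if __name__ == "__main__":
    train_sim, val_sim = STUDY.training_sim(), STUDY.validation_sim()
    train_spectra, _ = simulate_cohort(train_sim)
    train_fm = preprocess_cohort(train_spectra, train_sim)
    save_feature_matrix(train_fm, "training")
    print(f"training: {len(train_fm.sample_ids)} spectra -> "
          f"{len(train_fm.peak_definitions)} consensus peaks")

    val_spectra, _ = simulate_cohort(val_sim)
    val_fm = preprocess_cohort(val_spectra, val_sim,
                               peak_definitions=train_fm.peak_definitions)
    save_feature_matrix(val_fm, "validation")
    n_bad = sum(f != "ok" for f in val_fm.qc_flags)
    print(f"validation: {len(val_fm.sample_ids)} spectra integrated at the "
          f"training peak definitions; {n_bad} failed QC")
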