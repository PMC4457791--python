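"""Stage 4: train GA-kNN (k = 3/5/7), SNN and QC models; pick the best."""

from serumpep import classify as clf
from serumpep.pipeline import select_best, train_candidates

from common import RESULTS, STUDY, load_feature_matrix, load_labels

if __name__ == "__main__":
    fm = load_feature_matrix("training")
    labels = load_labels("training", fm.sample_ids)
    models, cv_table = train_candidates(fm, labels, STUDY)
    cv_table.to_csv(RESULTS / "model_cv_table.csv", index=False)
    print(cv_table.to_string(index=False))
    best = select_best(cv_table)
    model = models[best][0]
    clf.save_model(model, RESULTS / "best_model.json")
    peaks = ", ".join(f"{p:.2f}" for p in sorted(model.selected_peaks))
    print(f"best model: {best}; selected peaks (m/z): {peaks}")
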