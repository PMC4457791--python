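"""End-to-end study orchestration with reproducibility controls.

:func:`run_full_study` replays the whole design: simulate a 50/50 training
cohort and a 52/71 validation cohort, preprocess each into feature matrices,
rank differential peaks on the training cohort only, train the candidate
models (GA-kNN at k = 3/5/7, the prototype network, the quick classifier) on
the training cohort only, pick the best by cross-validation percentage (ties
to the model with fewer peaks), classify the validation spectra blind — the
validation truth labels flow only into the final evaluation step — and score
concordance, response and survival.

Every run writes its outputs plus a manifest (config echo, seeds, SHA-256
digest of every artifact); identical configs and seeds reproduce identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from serumpep import io as spio
from serumpep.simulate import (MUTANT, WILD, OutcomeParams, SimulationConfig,
                               simulate_cohort, simulate_outcomes)
from serumpep.preprocess import build_feature_matrix, FeatureMatrix
from serumpep.stats import differential_peaks
from serumpep import classify as clf
from serumpep import clinical


@dataclass
class StudyConfig:
    """One knob set for the full synthetic study."""

    seed: int = 0
    n_train_mutant: int = 50
    n_train_wild: int = 50
    n_val_mutant: int = 52
    n_val_wild: int = 71
    val_invalid_rate: float = 0.024
    sim_overrides: dict = field(default_factory=dict)
    ga_ks: tuple = (3, 5, 7)
    ga_params: clf.GAParams = field(default_factory=clf.GAParams)
    train_snn_qc: bool = True
    outcome_params: dict = field(default_factory=dict)

    def training_sim(self) -> SimulationConfig:
        # both cohorts share catalog_seed: one study assays one serum matrix
        return SimulationConfig(n_mutant=self.n_train_mutant,
                                n_wild=self.n_train_wild,
                                invalid_rate=0.0,
                                seed=self.seed * 2 + 1,
                                catalog_seed=self.seed, **self.sim_overrides)

    def validation_sim(self) -> SimulationConfig:
        return SimulationConfig(n_mutant=self.n_val_mutant,
                                n_wild=self.n_val_wild,
                                invalid_rate=self.val_invalid_rate,
                                seed=self.seed * 2 + 2,
                                catalog_seed=self.seed, **self.sim_overrides)


def preprocess_cohort(spectra, sim: SimulationConfig,
                      peak_definitions=None) -> FeatureMatrix:
    """Preprocess one cohort on the generator's normalization scale."""
    return build_feature_matrix(
        spectra, mz_min=sim.mz_min, mz_max=sim.mz_max,
        target_tic=sim.nominal_tic(), peak_definitions=peak_definitions)


def train_candidates(fm: FeatureMatrix, labels, config: StudyConfig):
    """Train every candidate model on the training feature matrix.

    Returns ``(models, cv_table)`` where ``cv_table`` reproduces the
    cross-validation / recognition-capability layout of the study report.
    """
    valid = fm.valid_mask()
    X = fm.areas[valid]
    y = np.asarray(labels)[valid]
    centroids = fm.centroids
    models, rows = {}, []
    for k in config.ga_ks:
        model, cv = clf.train_ga_knn(X, centroids, y, k=k,
                                     ga_params=config.ga_params,
                                     seed=config.seed)
        name = f"GA-{k}"
        models[name] = (model, cv)
        rows.append({"model": name,
                     "cross_validation_pct": cv.cross_validation_pct,
                     "recognition_capability_pct": cv.recognition_capability_pct,
                     "n_peaks": len(model.selected_peaks)})
    if config.train_snn_qc:
        for name, trainer in (
                ("SNN", lambda Xt, ct, yt: clf.train_snn(
                    Xt, ct, yt, seed=config.seed)),
                ("QC", lambda Xt, ct, yt: clf.train_qc(Xt, ct, yt))):
            cv = clf.cross_validate(trainer, X, centroids, y, seed=config.seed)
            model = trainer(X, centroids, y)
            models[name] = (model, cv)
            rows.append({"model": name,
                         "cross_validation_pct": cv.cross_validation_pct,
                         "recognition_capability_pct": cv.recognition_capability_pct,
                         "n_peaks": len(model.selected_peaks)})
    return models, pd.DataFrame(rows)


def select_best(cv_table: pd.DataFrame) -> str:
    """Highest cross-validation percentage; ties go to fewer peaks."""
    ranked = cv_table.sort_values(["cross_validation_pct", "n_peaks"],
                                  ascending=[False, True], kind="mergesort")
    return str(ranked.iloc[0]["model"])


def classify_cohort(model: clf.ClassifierModel, fm: FeatureMatrix) -> pd.DataFrame:
    """Blind per-sample labels for a preprocessed cohort."""
    preds = []
    for i, sid in enumerate(fm.sample_ids):
        preds.append({"sample_id": sid,
                      "predicted": clf.classify(model, fm.areas[i], fm.centroids,
                                                qc_flag=fm.qc_flags[i])})
    return pd.DataFrame(preds)


def evaluate_validation(predictions: pd.DataFrame,
                        truth_meta: pd.DataFrame) -> dict:
    """Join blind predictions with the withheld truth and score everything."""
    records = predictions.merge(
        truth_meta.rename(columns={"true_class": "truth"}), on="sample_id")
    summary = clinical.confusion_summary(records)
    resp = clinical.response_table(records)
    out = {"confusion": summary, "response": resp, "records": records}
    surv = {}
    evaluable = records[records["predicted"].isin([MUTANT, WILD])
                        & records["tki_treated"].astype(bool)]
    for endpoint in ("pfs", "os"):
        gm = evaluable[evaluable["predicted"] == MUTANT]
        gw = evaluable[evaluable["predicted"] == WILD]
        if len(gm) == 0 or len(gw) == 0:
            continue
        km_m = clinical.km_estimate(gm[f"{endpoint}_months"], gm[f"{endpoint}_event"])
        km_w = clinical.km_estimate(gw[f"{endpoint}_months"], gw[f"{endpoint}_event"])
        chi2, p = clinical.logrank(gm[f"{endpoint}_months"], gm[f"{endpoint}_event"],
                                   gw[f"{endpoint}_months"], gw[f"{endpoint}_event"])
        surv[endpoint] = {"median_mutant": km_m.median, "ci_mutant": km_m.median_ci,
                          "median_wild": km_w.median, "ci_wild": km_w.median_ci,
                          "logrank_chi2": chi2, "logrank_p": p,
                          "km_mutant": km_m, "km_wild": km_w}
    out["survival"] = surv
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_study(config: StudyConfig, outdir) -> dict:
    """Run the whole study; write artifacts and a manifest under ``outdir``.

    Returns a dict with the in-memory results (models, tables, evaluation)
    plus the manifest. Raises a configuration error before any stage runs if
    the config is invalid.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    train_sim = config.training_sim()
    val_sim = config.validation_sim()

    # --- simulate + preprocess training cohort
    train_spectra, train_meta = simulate_cohort(train_sim)
    train_fm = preprocess_cohort(train_spectra, train_sim)
    labels = train_meta.set_index("sample_id").loc[train_fm.sample_ids,
                                                   "true_class"].to_numpy()

    diff = differential_peaks(train_fm, labels)
    spio.write_table(diff, outdir / "differential_peaks.csv")

    # --- train candidates on training data only
    models, cv_table = train_candidates(train_fm, labels, config)
    spio.write_table(cv_table, outdir / "model_cv_table.csv")
    best_name = select_best(cv_table)
    best_model = models[best_name][0]
    clf.save_model(best_model, outdir / "best_model.json")

    # --- blind classification of the validation cohort (no truth in scope)
    val_spectra, val_truth = simulate_cohort(val_sim)
    val_fm = preprocess_cohort(val_spectra, val_sim,
                               peak_definitions=train_fm.peak_definitions)
    predictions = classify_cohort(best_model, val_fm)
    spio.write_table(predictions, outdir / "validation_predictions.csv")

    # --- unblind: attach truth + outcomes, evaluate
    outcome_params = OutcomeParams(seed=config.seed * 2 + 3,
                                   **config.outcome_params)
    val_truth = simulate_outcomes(val_truth, outcome_params)
    spio.write_table(val_truth, outdir / "validation_cohort.csv")
    evaluation = evaluate_validation(predictions, val_truth)

    summary = evaluation["confusion"]
    spio.write_table(pd.DataFrame([dataclasses.asdict(summary)]),
                     outdir / "confusion_summary.csv")
    spio.write_table(evaluation["response"].table, outdir / "response_table.csv")

    manifest = {
        "config": {**dataclasses.asdict(config),
                   "ga_params": dataclasses.asdict(config.ga_params)},
        "best_model": best_name,
        "n_training_peaks": len(train_fm.peak_definitions),
        "outputs": {p.name: _digest(p)
                    for p in sorted(set(outdir.glob("*.csv"))
                                    | {outdir / "best_model.json"})},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return {"manifest": manifest, "models": models, "cv_table": cv_table,
            "best_model_name": best_name, "best_model": best_model,
            "train_features": train_fm, "train_labels": labels,
            "differential": diff, "predictions": predictions,
            "validation_truth": val_truth, "evaluation": evaluation}
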