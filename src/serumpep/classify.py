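"""Classification models over the peak-area feature matrix.

Three model families mirror the profiling software this pipeline
reimplements:

* **GA-kNN** — a genetic algorithm searches peak subsets (chromosome = subset,
  fitness = internal stratified 5-fold cross-validated accuracy of a
  k-nearest-neighbor classifier on standardized areas) and the best subset's
  k-NN becomes the model.
* **SNN** — a prototype ("supervised neural network") classifier realized as
  LVQ1: per-class prototypes initialized at the class means are iteratively
  attracted to same-class samples and repelled from other-class samples;
  classification is by nearest prototype.
* **QC** — a quick univariate classifier: peaks ranked by Welch p, each
  retained peak votes for the class whose training mean is nearer, with
  weight -log10(p).

Model evaluation follows the repeated-random-split convention: 20% of
samples left out, 10 iterations, stratified ("cross-validation"), plus
resubstitution accuracy on the full training set ("recognition capability").
All randomness flows from explicit integer seeds. Distance ties and vote
ties break toward "wild" — the conservative call, since a "mutant" label
recommends TKI therapy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from serumpep.simulate import MUTANT, WILD

MODEL_FORMAT_VERSION = 1
UNCLASSIFIABLE = "unclassifiable"


class ModelPersistenceError(ValueError):
    """Raised when a persisted model fails to load intact."""


@dataclass
class ClassifierModel:
    """A trained model: selected peaks, training scaling, and decision data."""

    kind: str  # "GA" | "SNN" | "QC"
    selected_peaks: list  # centroids, Da
    decision_data: dict
    scaling: dict  # {"center": [...], "scale": [...]} per selected peak
    class_labels: tuple = (MUTANT, WILD)

    def __post_init__(self) -> None:
        if self.kind == "GA":
            k = self.decision_data.get("k", 0)
            if k < 1 or k % 2 == 0:
                raise ValueError("GA-kNN requires odd k >= 1")


@dataclass
class CVResult:
    """Repeated-random-split evaluation of one model/trainer."""

    cross_validation_pct: float
    recognition_capability_pct: float
    per_iteration: list
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.cross_validation_pct <= 100.0:
            raise ValueError("cross_validation_pct outside [0, 100]")
        if not 0.0 <= self.recognition_capability_pct <= 100.0:
            raise ValueError("recognition_capability_pct outside [0, 100]")


@dataclass
class GAParams:
    """Genetic-algorithm search settings."""

    population: int = 64
    generations: int = 40
    crossover_rate: float = 0.7
    mutation_rate: float = 0.05
    elitism: int = 1
    subset_min: int = 3
    subset_max: int = 8
    tournament: int = 2
    inner_folds: int = 5
    #: weight of the mean k-NN vote margin in the fitness; kept below the
    #: accuracy quantum (1/n) so it only breaks ties between subsets of equal
    #: CV accuracy, pushing the search toward confidently separating peaks.
    margin_weight: float = 0.005
    #: weight of the subset's aggregate univariate evidence (normalized sum of
    #: -log10 p over its genes); the lowest fitness tier, it resolves ties the
    #: margin leaves — evicting genes with no marginal signal and filling the
    #: subset with strongly discriminating peaks (a filter-wrapper hybrid).
    filter_weight: float = 0.001


# ---------------------------------------------------------------------------
# shared helpers

def _standardize_fit(X: np.ndarray) -> dict:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return {"center": center.tolist(), "scale": scale.tolist()}


def _standardize_apply(X: np.ndarray, scaling: dict) -> np.ndarray:
    return (X - np.asarray(scaling["center"])) / np.asarray(scaling["scale"])


def _match_columns(model_peaks, centroids, tol: float = 1.5) -> np.ndarray:
    """Map each model peak to a column of the feature matrix (within ``tol`` Da)."""
    centroids = np.asarray(centroids, dtype=float)
    cols = []
    for p in model_peaks:
        j = int(np.argmin(np.abs(centroids - p)))
        if abs(centroids[j] - p) > tol:
            raise KeyError(f"feature matrix lacks a column for model peak {p:.2f} Da")
        cols.append(j)
    return np.asarray(cols)


def _knn_votes(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, k: int) -> np.ndarray:
    """Fraction of the k nearest training samples voting 'mutant' per test row."""
    d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2)
    # stable argsort makes neighbor choice deterministic under distance ties
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return (ytr[nn] == MUTANT).sum(axis=1) / k


def _knn_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, k: int) -> np.ndarray:
    """k-NN majority vote with Euclidean distance; ties break toward wild."""
    frac_mut = _knn_votes(Xtr, ytr, Xte, k)
    return np.where(frac_mut > 0.5, MUTANT, WILD)


# ---------------------------------------------------------------------------
# trainers

def _check_two_classes(labels: np.ndarray) -> None:
    for cls in (MUTANT, WILD):
        if (labels == cls).sum() < 3:
            raise ValueError(f"need >= 3 samples of class {cls!r}")
    extra = set(labels) - {MUTANT, WILD}
    if extra:
        raise ValueError(f"unknown labels {extra}")


def train_qc(X: np.ndarray, centroids, labels, max_peaks: int = 10) -> ClassifierModel:
    """Quick classifier: univariate -log10(p)-weighted nearest-class-mean votes."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    centroids = np.asarray(centroids, dtype=float)
    mut, wild = X[labels == MUTANT], X[labels == WILD]
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if np.std(mut[:, j]) == 0 and np.std(wild[:, j]) == 0:
            continue  # constant peak carries no information; weight stays 0
        pvals[j] = sp_stats.ttest_ind(mut[:, j], wild[:, j], equal_var=False).pvalue
    order = np.argsort(pvals, kind="stable")[:max_peaks]
    scaling = _standardize_fit(X[:, order])
    Z = _standardize_apply(X[:, order], scaling)
    zm = Z[labels == MUTANT].mean(axis=0)
    zw = Z[labels == WILD].mean(axis=0)
    weights = -np.log10(np.maximum(pvals[order], 1e-300))
    return ClassifierModel(
        kind="QC",
        selected_peaks=centroids[order].tolist(),
        decision_data={"weights": weights.tolist(), "mean_mutant": zm.tolist(),
                       "mean_wild": zw.tolist()},
        scaling=scaling,
    )


def train_snn(X: np.ndarray, centroids, labels, prototypes_per_class: int = 3,
              epochs: int = 40, lr: float = 0.05, seed: int = 0) -> ClassifierModel:
    """Prototype (LVQ1) classifier on standardized areas."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    scaling = _standardize_fit(X)
    Z = _standardize_apply(X, scaling)
    rng = np.random.default_rng(seed)

    protos, proto_labels = [], []
    for cls in (MUTANT, WILD):
        mean = Z[labels == cls].mean(axis=0)
        spread = Z[labels == cls].std(axis=0, ddof=0)
        for _ in range(prototypes_per_class):
            protos.append(mean + 0.1 * spread * rng.standard_normal(Z.shape[1]))
            proto_labels.append(cls)
    P = np.array(protos)
    proto_labels = np.array(proto_labels)

    n = len(Z)
    for epoch in range(epochs):
        rate = lr * (1.0 - epoch / epochs)
        for i in rng.permutation(n):
            d2 = ((P - Z[i]) ** 2).sum(axis=1)
            j = int(np.argmin(d2))
            sign = 1.0 if proto_labels[j] == labels[i] else -1.0
            P[j] += sign * rate * (Z[i] - P[j])

    return ClassifierModel(
        kind="SNN",
        selected_peaks=list(np.asarray(centroids, dtype=float)),
        decision_data={"prototypes": P.tolist(),
                       "prototype_labels": proto_labels.tolist()},
        scaling=scaling,
    )


def _subset_fitness(X: np.ndarray, labels: np.ndarray, subset: tuple, k: int,
                    folds: int, seed: int, margin_weight: float) -> float:
    """Internal stratified k-fold CV fitness of k-NN on one peak subset.

    Fitness is holdout accuracy plus ``margin_weight`` times the mean vote
    margin for the true class; the margin term is smaller than one sample of
    accuracy, so it only orders subsets that classify equally well.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xs = X[:, list(subset)]
    correct = 0
    margin = 0.0
    for tr, te in skf.split(Xs, labels):
        scaling = _standardize_fit(Xs[tr])
        frac_mut = _knn_votes(_standardize_apply(Xs[tr], scaling), labels[tr],
                              _standardize_apply(Xs[te], scaling), k)
        pred = np.where(frac_mut > 0.5, MUTANT, WILD)
        correct += int((pred == labels[te]).sum())
        true_frac = np.where(labels[te] == MUTANT, frac_mut, 1.0 - frac_mut)
        margin += float(true_frac.sum())
    n = len(labels)
    return correct / n + margin_weight * (margin / n)


def train_ga_knn(X: np.ndarray, centroids, labels, k: int = 7,
                 ga_params: GAParams | None = None, seed: int = 0,
                 leave_out_pct: float = 20.0, iterations: int = 10,
                 ) -> tuple[ClassifierModel, CVResult]:
    """Genetic-algorithm peak-subset search wrapped around k-NN.

    Fitness is internal stratified 5-fold CV accuracy; the reported
    :class:`CVResult` instead comes from the outer 20%-holdout x 10-iteration
    protocol applied to the winning subset, so selection optimism does not
    leak into the headline numbers.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be odd and >= 1")
    params = ga_params or GAParams()
    n_feat = X.shape[1]
    if params.subset_min > n_feat:
        raise ValueError("subset size range exceeds available peak count")
    sub_max = min(params.subset_max, n_feat)
    rng = np.random.default_rng(seed)
    fitness_cache: dict[tuple, float] = {}

    # univariate evidence per peak guides initialization and gene insertion:
    # the search still explores freely, but new genes enter in proportion to
    # their marginal -log10 p, so the population is not dominated by peaks
    # that carry no class signal at all.
    mut_rows, wild_rows = X[labels == MUTANT], X[labels == WILD]
    uni_p = np.ones(n_feat)
    for j in range(n_feat):
        if np.std(mut_rows[:, j]) > 0 or np.std(wild_rows[:, j]) > 0:
            uni_p[j] = sp_stats.ttest_ind(mut_rows[:, j], wild_rows[:, j],
                                          equal_var=False).pvalue
    # evidence credits only genes with real marginal signal (p < 0.1), so the
    # filter tier never rewards padding a subset with uninformative peaks
    gene_evidence = np.maximum(-np.log10(np.maximum(uni_p, 1e-300)) - 1.0, 0.0)
    gene_weight = gene_evidence + 0.5  # exploration floor for operator sampling

    def weighted_pick(candidates) -> int:
        w = gene_weight[candidates]
        return int(rng.choice(candidates, p=w / w.sum()))

    filter_norm = sub_max * max(float(gene_evidence.max()), 1e-12)

    def fitness(subset: tuple) -> float:
        if subset not in fitness_cache:
            base = _subset_fitness(X, labels, subset, k, params.inner_folds,
                                   seed, params.margin_weight)
            evidence = float(gene_evidence[list(subset)].sum()) / filter_norm
            fitness_cache[subset] = base + params.filter_weight * evidence
        return fitness_cache[subset]

    def random_subset() -> tuple:
        size = int(rng.integers(params.subset_min, sub_max + 1))
        genes: set[int] = set()
        while len(genes) < size:
            genes.add(weighted_pick(np.array(
                [g for g in range(n_feat) if g not in genes])))
        return tuple(sorted(genes))

    def repair(genes: set) -> tuple:
        genes = set(genes)
        while len(genes) > sub_max:
            genes.remove(int(rng.choice(sorted(genes))))
        while len(genes) < params.subset_min:
            genes.add(weighted_pick(np.array(
                [g for g in range(n_feat) if g not in genes])))
        return tuple(sorted(genes))

    def crossover(a: tuple, b: tuple) -> tuple:
        union = sorted(set(a) | set(b))
        child = {g for g in union
                 if (g in a and g in b) or rng.random() < 0.5}
        return repair(child)

    def mutate(subset: tuple) -> tuple:
        genes = set(subset)
        for g in list(genes):
            if rng.random() < params.mutation_rate:
                genes.discard(g)
                genes.add(weighted_pick(np.array(
                    [c for c in range(n_feat) if c not in genes])))
        if rng.random() < params.mutation_rate:
            if rng.random() < 0.5 and len(genes) < sub_max:
                genes.add(weighted_pick(np.array(
                    [c for c in range(n_feat) if c not in genes])))
            elif len(genes) > params.subset_min:
                genes.discard(int(rng.choice(sorted(genes))))
        return repair(genes)

    population = [random_subset() for _ in range(params.population)]
    best = max(population, key=fitness)
    for _ in range(params.generations):
        scored = sorted(population, key=fitness, reverse=True)
        if fitness(scored[0]) > fitness(best):
            best = scored[0]
        next_gen = scored[:params.elitism]
        while len(next_gen) < params.population:
            contenders = [population[int(i)] for i in
                          rng.integers(0, len(population), size=params.tournament)]
            pa = max(contenders, key=fitness)
            contenders = [population[int(i)] for i in
                          rng.integers(0, len(population), size=params.tournament)]
            pb = max(contenders, key=fitness)
            child = crossover(pa, pb) if rng.random() < params.crossover_rate \
                else (pa if fitness(pa) >= fitness(pb) else pb)
            next_gen.append(mutate(child))
        population = next_gen
    best = max([best] + population, key=fitness)

    # memetic refinement: hill-climb the winner against the strongest
    # univariate candidates (swap / add / drop, accept only improvements)
    shortlist = np.argsort(-gene_weight, kind="stable")[:24]
    improved = True
    passes = 0
    while improved and passes < 3:
        improved = False
        passes += 1
        for g in list(best):
            for cand in shortlist:
                if int(cand) in best or g not in best:
                    continue
                trial = tuple(sorted((set(best) - {g}) | {int(cand)}))
                if fitness(trial) > fitness(best):
                    best = trial
                    improved = True
        for cand in shortlist:
            if len(best) >= sub_max:
                break
            if int(cand) in best:
                continue
            trial = tuple(sorted(set(best) | {int(cand)}))
            if fitness(trial) > fitness(best):
                best = trial
                improved = True
        for g in list(best):
            if g not in best or len(best) <= params.subset_min:
                continue
            trial = tuple(sorted(set(best) - {g}))
            if fitness(trial) > fitness(best):
                best = trial
                improved = True

    centroids = np.asarray(centroids, dtype=float)
    scaling = _standardize_fit(X[:, list(best)])
    model = ClassifierModel(
        kind="GA",
        selected_peaks=centroids[list(best)].tolist(),
        decision_data={"k": k,
                       "exemplars": _standardize_apply(X[:, list(best)],
                                                       scaling).tolist(),
                       "exemplar_labels": labels.tolist()},
        scaling=scaling,
    )

    def fixed_subset_trainer(Xtr, ctr, ytr):
        sc = _standardize_fit(Xtr)
        return ClassifierModel(
            kind="GA", selected_peaks=list(ctr),
            decision_data={"k": k,
                           "exemplars": _standardize_apply(Xtr, sc).tolist(),
                           "exemplar_labels": list(ytr)},
            scaling=sc)

    cv = cross_validate(fixed_subset_trainer, X[:, list(best)], centroids[list(best)],
                        labels, leave_out_pct=leave_out_pct, iterations=iterations,
                        seed=seed)
    cv.settings.update({"kind": "GA", "k": k, "ga": asdict(params),
                        "selected_peaks": model.selected_peaks,
                        "internal_fitness": fitness(best)})
    return model, cv


# ---------------------------------------------------------------------------
# evaluation and prediction

def predict_features(model: ClassifierModel, X: np.ndarray, centroids) -> np.ndarray:
    """Predict labels for rows of a feature matrix aligned by centroid matching."""
    X = np.asarray(X, dtype=float)
    cols = _match_columns(model.selected_peaks, centroids)
    Z = _standardize_apply(X[:, cols], model.scaling)
    dd = model.decision_data
    if model.kind == "GA":
        return _knn_predict(np.asarray(dd["exemplars"]),
                            np.asarray(dd["exemplar_labels"]), Z, dd["k"])
    if model.kind == "SNN":
        P = np.asarray(dd["prototypes"])
        plab = np.asarray(dd["prototype_labels"])
        d2 = ((Z[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
        return plab[np.argmin(d2, axis=1)]
    if model.kind == "QC":
        w = np.asarray(dd["weights"])
        dm = np.abs(Z - np.asarray(dd["mean_mutant"]))
        dw = np.abs(Z - np.asarray(dd["mean_wild"]))
        votes = np.where(dm < dw, 1.0, -1.0) * w
        return np.where(votes.sum(axis=1) > 0, MUTANT, WILD)
    raise ValueError(f"unknown model kind {model.kind!r}")


def classify(model: ClassifierModel, feature_vector, centroids,
             qc_flag: str = "ok") -> str:
    """Label one sample: ``mutant``, ``wild`` or ``unclassifiable``.

    A sample whose spectrum failed the quality check, or whose areas are
    missing, is unclassifiable; a feature vector lacking a model peak column
    is an error (a data problem, not a sample-quality problem).
    """
    x = np.asarray(feature_vector, dtype=float)
    _match_columns(model.selected_peaks, centroids)  # raises if a column is absent
    if qc_flag != "ok" or np.any(~np.isfinite(x)):
        return UNCLASSIFIABLE
    return str(predict_features(model, x[None, :], centroids)[0])


def cross_validate(trainer, X: np.ndarray, centroids, labels,
                   leave_out_pct: float = 20.0, iterations: int = 10,
                   seed: int = 0, stratified: bool = True) -> CVResult:
    """Repeated stratified random-split evaluation.

    ``trainer(X_train, centroids, y_train) -> ClassifierModel`` is refit on
    every split; ``cross_validation_pct`` is the mean holdout accuracy over
    ``iterations`` splits leaving out ``leave_out_pct`` percent, and
    ``recognition_capability_pct`` is the resubstitution accuracy of the model
    refit on all samples.
    """
    if not stratified:
        raise ValueError("only stratified splitting is supported")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    splitter = StratifiedShuffleSplit(n_splits=iterations,
                                      test_size=leave_out_pct / 100.0,
                                      random_state=seed)
    accs = []
    for tr, te in splitter.split(X, labels):
        model = trainer(X[tr], centroids, labels[tr])
        pred = predict_features(model, X[te], centroids)
        accs.append(float((pred == labels[te]).mean()))
    full = trainer(X, centroids, labels)
    recog = float((predict_features(full, X, centroids) == labels).mean())
    return CVResult(
        cross_validation_pct=100.0 * float(np.mean(accs)),
        recognition_capability_pct=100.0 * recog,
        per_iteration=[100.0 * a for a in accs],
        settings={"leave_out_pct": leave_out_pct, "iterations": iterations,
                  "seed": seed})


# ---------------------------------------------------------------------------
# persistence

def _payload_digest(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def save_model(model: ClassifierModel, path) -> Path:
    """Persist a model as structured text (JSON with an integrity checksum)."""
    path = Path(path)
    payload = asdict(model)
    payload["class_labels"] = list(payload["class_labels"])
    doc = {"format_version": MODEL_FORMAT_VERSION,
           "sha256": _payload_digest(payload), "model": payload}
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_model(path) -> ClassifierModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelPersistenceError(f"{path}: unreadable model file") from exc
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelPersistenceError(
            f"{path}: unsupported format version {doc.get('format_version')!r}")
    payload = doc.get("model")
    if payload is None or _payload_digest(payload) != doc.get("sha256"):
        raise ModelPersistenceError(f"{path}: checksum mismatch")
    payload = dict(payload)
    payload["class_labels"] = tuple(payload["class_labels"])
    return ClassifierModel(**payload)
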