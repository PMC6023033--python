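"""Model building: PCA descriptor filtering and GA-driven SVM feature selection.

The training pipeline is a wrapper feature-selection scheme:

1. **PCA filter** — principal components of the (column-centered) descriptor
   matrix are retained up to a cumulative-variance cutoff; each signature's
   importance is the sum over retained components of |loading| weighted by the
   component's variance fraction, and signatures passing the importance rule
   (>= mean importance by default) survive to the search stage.
2. **GA search** — bit-vector chromosomes over the surviving signatures are
   evolved with elitism / single-point crossover / bit-flip mutation; the
   fitness of a subset is its 10-fold cross-validated SVM performance,
   maximized over a grid of cost values (accuracy for classification,
   negative RMSE for regression on log10 IC50).
3. **Tie retention** — every distinct feature subset in the final population
   tied on (cross-validation error, training error) with the best one is kept;
   without a non-arbitrary way to pick a representative, screening later
   requires unanimity across all of them.

Classification uses a soft-margin linear SVM (active = +1, inactive = -1, so a
larger decision value means greater confidence of activity); regression uses a
linear-kernel nu-SVR with nu = 0.2 on log10(IC50/µM).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, NuSVR

from .chem_io import ActivityClass, Library
from .signature import AtomicSignature, DescriptorMatrix

DEFAULT_COST_GRID = tuple(round(c, 2) for c in np.arange(0.01, 1.0001, 0.01))


@dataclass
class PcaSelection:
    """Outcome of the PCA importance filter over descriptor columns."""

    selected: list[int]  # column indices into the source matrix
    importance: np.ndarray  # per-column, non-negative
    variance_cutoff: float
    importance_rule: str

    def signatures(self, matrix: DescriptorMatrix) -> list[AtomicSignature]:
        return [matrix.signatures[j] for j in self.selected]


def pca_filter(
    matrix: DescriptorMatrix,
    variance_cutoff: float = 0.95,
    importance_rule: str = "mean",
) -> PcaSelection:
    """Keep the signatures that contribute most to the observed variance.

    Columns are centered, the covariance eigendecomposition taken (via SVD),
    components retained up to ``variance_cutoff`` cumulative variance, and
    importance(column) = sum over retained PCs of |loading| x variance
    fraction.  Rules: ``"mean"`` keeps columns with importance >= the mean
    importance; ``"nonzero"`` keeps every column with nonzero importance
    (i.e., every non-constant column).
    """
    X = np.asarray(matrix.X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA filter needs at least 2 compounds")
    if not 0.0 < variance_cutoff <= 1.0:
        raise ValueError("variance_cutoff must be in (0, 1]")
    Xc = X - X.mean(axis=0)
    # economy SVD: rows of Vt are the PC loadings
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("degenerate descriptor matrix (zero variance)")
    frac = var / total
    cum = np.cumsum(frac)
    n_keep = int(np.searchsorted(cum, variance_cutoff - 1e-12) + 1)
    n_keep = min(n_keep, len(frac))
    importance = (np.abs(Vt[:n_keep]) * frac[:n_keep, None]).sum(axis=0)

    if importance_rule == "mean":
        mask = importance >= importance.mean()
    elif importance_rule == "nonzero":
        mask = importance > 1e-12
    else:
        raise ValueError(f"unknown importance rule {importance_rule!r}")
    selected = [int(j) for j in np.flatnonzero(mask)]
    if not selected:
        raise ValueError("PCA filter selected no descriptors")
    return PcaSelection(selected, importance, variance_cutoff, importance_rule)


@dataclass(frozen=True)
class SvmSpec:
    task: str  # "classification" | "regression"
    kernel: str = "linear"
    cost: float = 1.0
    nu: float = 0.2
    folds: int = 10

    def __post_init__(self) -> None:
        if not 0.01 - 1e-9 <= self.cost <= 1.0 + 1e-9:
            raise ValueError(f"cost outside [0.01, 1]: {self.cost}")


@dataclass
class GaConfig:
    """Genetic-algorithm settings; the defaults are the screening-scale values."""

    elitism: float = 0.7
    crossover: float = 0.8
    mutation: float = 0.1
    population: int = 1000
    max_iter: int = 1000
    stall_stop: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("elitism", "crossover", "mutation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TrainedModel:
    spec: SvmSpec
    feature_subset: tuple[AtomicSignature, ...]
    weights: dict[AtomicSignature, float]
    intercept: float
    training_error: float
    cv_error: float
    target_transform: str = ""  # "log10"|"linear" for regression, "" otherwise

    def decision_values(self, counts: Mapping[AtomicSignature, int]) -> float:
        """Linear decision value; signatures outside the subset contribute 0."""
        return sum(w * counts.get(s, 0) for s, w in self.weights.items()) + self.intercept

    def decision_matrix(self, matrix: DescriptorMatrix) -> np.ndarray:
        col = {s: j for j, s in enumerate(matrix.signatures)}
        v = np.zeros(matrix.X.shape[0])
        for s, w in self.weights.items():
            j = col.get(s)
            if j is not None:
                v += w * matrix.X[:, j]
        return v + self.intercept

    def predict_ic50_um(self, counts: Mapping[AtomicSignature, int]) -> float:
        if self.spec.task != "regression":
            raise ValueError("IC50 prediction requires a regression model")
        y = self.decision_values(counts)
        return float(10.0**y) if self.target_transform == "log10" else float(y)


@dataclass
class ModelEnsemble:
    """All cross-validation-tied classifiers plus the QSAR regressor.

    ``train_stats`` is the training descriptor matrix's per-signature
    (min, max) occurrence windows — the fingerprint the overlap metric
    screens candidates against.
    """

    classifiers: list[TrainedModel]
    regressor: Optional[TrainedModel]
    train_stats: dict[AtomicSignature, tuple[int, int]]
    heights: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.classifiers:
            key = (self.classifiers[0].cv_error, self.classifiers[0].training_error)
            for m in self.classifiers:
                if (m.cv_error, m.training_error) != key:
                    raise ValueError("ensemble classifiers are not tied on the selection metrics")


# ---------------------------------------------------------------------------
# fitness evaluation


def _class_cv_error(X: np.ndarray, y: np.ndarray, cost: float, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    wrong = 0
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="linear", C=cost)
        clf.fit(X[tr], y[tr])
        wrong += int((clf.predict(X[te]) != y[te]).sum())
    return wrong / len(y)


def _regr_cv_error(X: np.ndarray, y: np.ndarray, cost: float, nu: float, folds: int, seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq = 0.0
    for tr, te in kf.split(X):
        reg = NuSVR(kernel="linear", nu=nu, C=cost)
        reg.fit(X[tr], y[tr])
        sq += float(((reg.predict(X[te]) - y[te]) ** 2).sum())
    return math.sqrt(sq / len(y))


def _evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    task: str,
    cost_grid: Sequence[float],
    nu: float,
    folds: int,
    seed: int,
) -> tuple[float, float, float]:
    """Best (cv_error, training_error, cost) over the cost grid for a subset."""
    Xs = X[:, cols]
    best = None
    for cost in cost_grid:
        if task == "classification":
            cv = _class_cv_error(Xs, y, cost, folds, seed)
        else:
            cv = _regr_cv_error(Xs, y, cost, nu, folds, seed)
        if best is None or cv < best[0] - 1e-12:
            best = (cv, cost)
    cv_err, cost = best
    if task == "classification":
        model = SVC(kernel="linear", C=cost).fit(Xs, y)
        train_err = float((model.predict(Xs) != y).mean())
    else:
        model = NuSVR(kernel="linear", nu=nu, C=cost).fit(Xs, y)
        train_err = math.sqrt(float(((model.predict(Xs) - y) ** 2).mean()))
    return cv_err, train_err, cost


def _fit_final(
    X: np.ndarray, y: np.ndarray, cols: np.ndarray, sigs: Sequence[AtomicSignature],
    task: str, cost: float, nu: float, folds: int,
    cv_err: float, train_err: float, target_transform: str,
) -> TrainedModel:
    Xs = X[:, cols]
    if task == "classification":
        est = SVC(kernel="linear", C=cost).fit(Xs, y)
    else:
        est = NuSVR(kernel="linear", nu=nu, C=cost).fit(Xs, y)
    w = np.asarray(est.coef_).ravel()
    subset = tuple(sigs[j] for j in cols)
    return TrainedModel(
        spec=SvmSpec(task=task, cost=float(cost), nu=nu, folds=folds),
        feature_subset=subset,
        weights={s: float(wj) for s, wj in zip(subset, w)},
        intercept=float(np.asarray(est.intercept_).ravel()[0]),
        training_error=train_err,
        cv_error=cv_err,
        target_transform=target_transform if task == "regression" else "",
    )


# ---------------------------------------------------------------------------
# GA search


def _linear_rank_probs(n: int) -> np.ndarray:
    # rank 0 = best; linear rank selection as in binary-GA practice
    ranks = np.arange(n, 0, -1, dtype=float)
    return ranks / ranks.sum()


def ga_svm_search(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    pca: PcaSelection,
    task: str = "classification",
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    nu: float = 0.2,
    folds: int = 10,
    ga: Optional[GaConfig] = None,
    target_transform: str = "log10",
    history: Optional[list] = None,
) -> list[TrainedModel]:
    """Evolve signature subsets and return all tie-best trained models.

    Chromosomes are bit vectors over the PCA-selected columns.  A subset's
    fitness is its best cross-validated performance over the cost grid; the
    all-zero chromosome is penalized and never returned.  The returned models
    are every distinct final-population subset tied with the best on
    (cv_error, training_error), each refit on the full data at its best cost.
    """
    ga = ga or GaConfig()
    rng = np.random.default_rng(ga.seed)
    y = np.asarray(y, dtype=float)
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("classification requires >= 2 classes")
    elif task == "regression":
        if len(y) < folds:
            raise ValueError("regression requires at least `folds` samples")
    else:
        raise ValueError(f"unknown task {task!r}")

    X = np.asarray(matrix.X, dtype=float)[:, pca.selected]
    sigs = pca.signatures(matrix)
    n_bits = X.shape[1]

    cache: dict[bytes, tuple[float, float, float]] = {}

    def fitness(chrom: np.ndarray) -> tuple[float, float, float]:
        """Returns (cv_error, training_error, cost); lower errors are fitter."""
        key = chrom.tobytes()
        if key not in cache:
            cols = np.flatnonzero(chrom)
            if len(cols) == 0:
                cache[key] = (np.inf, np.inf, np.nan)  # infeasible, penalized
            else:
                cache[key] = _evaluate_subset(
                    np.asarray(matrix.X, dtype=float), y,
                    np.asarray(pca.selected)[cols], task, cost_grid, nu, folds, ga.seed
                )
        return cache[key]

    pop = rng.integers(0, 2, size=(ga.population, n_bits), dtype=np.int8)
    # make sure at least one feasible chromosome exists at start
    if not pop.any():
        pop[0, rng.integers(n_bits)] = 1

    def sort_key(i: int, fits: list) -> tuple:
        cv, tr, _ = fits[i]
        return (cv, tr, pop[i].tobytes())

    best_so_far: Optional[tuple[float, float]] = None
    stall = 0
    for _generation in range(ga.max_iter):
        fits = [fitness(pop[i]) for i in range(len(pop))]
        order = sorted(range(len(pop)), key=lambda i: sort_key(i, fits))
        pop = pop[order]
        fits = [fits[i] for i in order]

        gen_best = (fits[0][0], fits[0][1])
        if history is not None:
            history.append(gen_best)
        if best_so_far is None or gen_best < best_so_far:
            best_so_far = gen_best
            stall = 0
        else:
            stall += 1
            if stall >= ga.stall_stop:
                break

        n_elite = max(1, math.ceil(ga.elitism * len(pop)))
        children = []
        probs = _linear_rank_probs(len(pop))
        while n_elite + len(children) < len(pop):
            i, j = rng.choice(len(pop), size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < ga.crossover and n_bits > 1:
                point = int(rng.integers(1, n_bits))
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            for child in (a, b):
                if rng.random() < ga.mutation:
                    flip = int(rng.integers(n_bits))
                    child[flip] ^= 1
                if n_elite + len(children) < len(pop):
                    children.append(child)
        pop = np.vstack([pop[:n_elite]] + [c[None, :] for c in children]) if children else pop[:n_elite]

    # final evaluation and tie collection
    fits = [fitness(pop[i]) for i in range(len(pop))]
    finite = [i for i in range(len(pop)) if np.isfinite(fits[i][0])]
    if not finite:
        raise RuntimeError("GA produced no feasible subset")
    best_key = min((fits[i][0], fits[i][1]) for i in finite)
    models = []
    seen: set[bytes] = set()
    for i in finite:
        if (fits[i][0], fits[i][1]) != best_key:
            continue
        key = pop[i].tobytes()
        if key in seen:
            continue
        seen.add(key)
        cols = np.flatnonzero(pop[i])
        cv, tr, cost = fits[i]
        models.append(
            _fit_final(
                np.asarray(matrix.X, dtype=float), y,
                np.asarray(pca.selected)[cols], matrix.signatures,
                task, cost, nu, folds, cv, tr, target_transform,
            )
        )
    # deterministic order: by subset
    models.sort(key=lambda m: tuple(str(s) for s in m.feature_subset))
    return models


# ---------------------------------------------------------------------------
# a-priori evaluation


def evaluate(model: TrainedModel, matrix: DescriptorMatrix, truth: np.ndarray) -> dict:
    """Training accuracy plus ROC curve / AUC from decision-score sweeping.

    ``truth`` is +1/-1 aligned with the matrix rows.  Raises if the truth is
    single-class (AUC undefined).
    """
    truth = np.asarray(truth, dtype=float)
    if len(truth) != matrix.X.shape[0]:
        raise ValueError("truth not aligned with matrix rows")
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC undefined for single-class truth")
    scores = model.decision_matrix(matrix)
    pred = np.where(scores > 0, 1.0, -1.0)
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == -1) & (truth == -1)).sum())
    acc = (tp + tn) / len(truth)
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores)
    return {
        "training_error": 1.0 - acc,
        "cv_error": model.cv_error,
        "accuracy": acc,
        "roc_points": list(zip(fpr.tolist(), tpr.tolist())),
        "auc": float(_sk_auc(fpr, tpr)),
    }


def labels_from_library(lib: Library) -> np.ndarray:
    """Class coding for SVM-C: active = +1, inactive = -1."""
    y = []
    for r in lib:
        if r.activity_class is ActivityClass.ACTIVE:
            y.append(1.0)
        elif r.activity_class is ActivityClass.INACTIVE:
            y.append(-1.0)
        else:
            raise ValueError(f"{r.id}: unknown class cannot enter training")
    return np.array(y)


# ---------------------------------------------------------------------------
# serialization


def ensemble_to_json(ensemble: ModelEnsemble, path) -> None:
    def model_payload(m: TrainedModel) -> dict:
        return {
            "spec": asdict(m.spec),
            "features": [str(s) for s in m.feature_subset],
            "weights": {str(s): w for s, w in m.weights.items()},
            "intercept": m.intercept,
            "training_error": m.training_error,
            "cv_error": m.cv_error,
            "target_transform": m.target_transform,
        }

    payload = {
        "heights": list(ensemble.heights),
        "classifiers": [model_payload(m) for m in ensemble.classifiers],
        "regressor": model_payload(ensemble.regressor) if ensemble.regressor else None,
        "train_stats": {str(s): list(v) for s, v in ensemble.train_stats.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def ensemble_from_json(path) -> ModelEnsemble:
    with open(path) as fh:
        payload = json.load(fh)

    def model_from(d: dict) -> TrainedModel:
        feats = tuple(AtomicSignature.parse(s) for s in d["features"])
        return TrainedModel(
            spec=SvmSpec(**d["spec"]),
            feature_subset=feats,
            weights={AtomicSignature.parse(s): w for s, w in d["weights"].items()},
            intercept=d["intercept"],
            training_error=d["training_error"],
            cv_error=d["cv_error"],
            target_transform=d.get("target_transform", ""),
        )

    return ModelEnsemble(
        classifiers=[model_from(d) for d in payload["classifiers"]],
        regressor=model_from(payload["regressor"]) if payload["regressor"] else None,
        train_stats={
            AtomicSignature.parse(s): (int(v[0]), int(v[1]))
            for s, v in payload["train_stats"].items()
        },
        heights=tuple(payload["heights"]),
    )
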