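"""L1-regularized logistic regression on motif features and model simplification.

The feature matrix (top-4-sum PFM scores under all seven alphabets) is
z-scored with training-split statistics and fitted with an L1-penalized
logistic regression. The penalty strength is chosen by maximizing
cross-validated AUROC over a log-spaced grid, the initial AUROC is taken on
a separate validation split, and the model is then iteratively simplified:
the L1 strength is multiplied by 1.25 and the model refitted until the
validation AUROC drops below 90% of the initial predictive power
(AUROC - 0.5); the last model still satisfying the retention bound is kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .discover import PFM
from .scan import FeatureMatrix

L1_SCALING = 1.25
RETENTION = 0.9
DEFAULT_GRID = np.logspace(-4, 4, 33)


class ModelError(ValueError):
    pass


def compute_auroc(scores_pos, scores_neg) -> float:
    """Rank-based (Mann-Whitney) AUROC; ties contribute 1/2."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ModelError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([scores_pos, scores_neg]))
    n_pos, n_neg = scores_pos.size, scores_neg.size
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc_from_labels(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    return compute_auroc(scores[labels == 1], scores[labels == 0])


@dataclass
class Standardizer:
    """Column z-scoring with statistics frozen from the training split."""

    means: np.ndarray
    stds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        means = X.mean(axis=0)
        stds = X.std(axis=0)
        stds = np.where(stds > 0, stds, 1.0)  # constant columns stay constant
        return cls(means, stds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.stds


def fit_l1_logreg(
    X: np.ndarray,
    y: np.ndarray,
    l1_strength: float,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 2000,
    warm: LogisticRegression | None = None,
) -> tuple[np.ndarray, float]:
    """Fit an L1-penalized logistic regression; returns (coefficients, intercept).

    The objective is sum of log-losses + l1_strength * ||w||_1 with an
    unpenalized intercept (saga solver, C = 1 / l1_strength). Features are
    expected to be standardized already. With no features the fit reduces to
    the intercept-only model (class-balance log-odds).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ModelError("need both classes present to fit")
    if l1_strength <= 0:
        raise ModelError("l1_strength must be positive")
    if X.shape[1] == 0:
        p = float(np.mean(y == 1))
        return np.empty(0), float(np.log(p / (1 - p)))
    if warm is not None:
        clf = warm
        clf.C = 1.0 / l1_strength
        clf.warm_start = True
    else:
        clf = LogisticRegression(
            penalty="l1",
            C=1.0 / l1_strength,
            solver="saga",
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
            warm_start=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    coef = clf.coef_[0].copy()
    intercept = float(clf.intercept_[0])
    if not coef.any():
        # fully shrunk model: the unpenalized-intercept optimum is exactly
        # the class-balance log-odds (the solver is unreliable here)
        p = float(np.mean(y == clf.classes_[1]))
        intercept = float(np.log(p / (1 - p)))
    return coef, intercept


def _cv_folds(n: int, y: np.ndarray, k: int, seed: int):
    """Stratified k-fold index pairs, seeded."""
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    folds = [np.sort(np.array(f)) for f in folds]
    for i in range(k):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        yield np.sort(train), test


def optimize_l1(
    X: np.ndarray,
    y: np.ndarray,
    grid=None,
    cv: int = 3,
    seed: int = 0,
    tol: float = 1e-4,
) -> float:
    """Strength maximizing mean cross-validated AUROC over a log-spaced grid.

    Ties are broken toward the stronger penalty (sparser model). Fits are
    warm-started along the path within each fold for speed.
    """
    grid = np.sort(np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float))
    if grid.size == 1:
        return float(grid[0])
    scores = np.zeros(grid.size)
    for train, test in _cv_folds(len(y), np.asarray(y), cv, seed):
        std = Standardizer.fit(X[train])
        Xtr, Xte = std.transform(X[train]), std.transform(X[test])
        clf = LogisticRegression(
            penalty="l1", C=1.0, solver="saga", tol=tol, max_iter=2000,
            random_state=seed, warm_start=True,
        )
        # strongest penalty first: the path grows from the sparse end
        for gi in range(grid.size - 1, -1, -1):
            coef, intercept = fit_l1_logreg(
                Xtr, y[train], grid[gi], seed=seed, tol=tol, warm=clf
            )
            pred = Xte @ coef + intercept
            try:
                scores[gi] += auroc_from_labels(pred, y[test])
            except ModelError:
                scores[gi] += 0.5
    best = np.flatnonzero(scores >= scores.max() - 1e-12)
    return float(grid[best[-1]])


@dataclass
class MotifModel:
    """Simplified weighted-motif model of one RBP's binding specificity."""

    pfms: list[PFM]
    coefficients: np.ndarray
    intercept: float
    l1_strength: float
    initial_auroc: float
    final_auroc: float
    standardizer: Standardizer
    feature_names: list[str]
    trace: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def retained(self) -> list[PFM]:
        return [p for p, c in zip(self.pfms, self.coefficients) if c != 0.0]

    @property
    def retained_coefficients(self) -> np.ndarray:
        return self.coefficients[self.coefficients != 0.0]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.standardizer.transform(X) @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "pfms": [p.to_dict() for p in self.pfms],
            "coefficients": np.asarray(self.coefficients).tolist(),
            "intercept": self.intercept,
            "l1_strength": self.l1_strength,
            "initial_auroc": self.initial_auroc,
            "final_auroc": self.final_auroc,
            "feature_means": self.standardizer.means.tolist(),
            "feature_stds": self.standardizer.stds.tolist(),
            "feature_names": list(self.feature_names),
            "trace": self.trace,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MotifModel":
        return cls(
            pfms=[PFM.from_dict(p) for p in d["pfms"]],
            coefficients=np.asarray(d["coefficients"]),
            intercept=d["intercept"],
            l1_strength=d["l1_strength"],
            initial_auroc=d["initial_auroc"],
            final_auroc=d["final_auroc"],
            standardizer=Standardizer(
                np.asarray(d["feature_means"]), np.asarray(d["feature_stds"])
            ),
            feature_names=list(d["feature_names"]),
            trace=d.get("trace", []),
            seed=d.get("seed", 0),
        )

    @classmethod
    def load(cls, path) -> "MotifModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def simplify_model(
    train: FeatureMatrix,
    validation: FeatureMatrix,
    l1_strength: float,
    seed: int = 0,
    tol: float = 1e-5,
    max_rounds: int = 200,
) -> MotifModel:
    """Fit at the optimized strength, then iteratively shrink the model.

    Each round multiplies the L1 strength by 1.25 and refits; the loop stops
    when validation AUROC falls below 0.5 + 0.9 * (initial AUROC - 0.5), and
    the last model that still met the bound is returned.
    """
    Xtr_raw, ytr = train.X, train.y
    std = Standardizer.fit(Xtr_raw)
    Xtr = std.transform(Xtr_raw)
    Xval = std.transform(validation.X)
    yval = validation.y
    names = list(train.values.columns)

    def fit_eval(strength):
        coef, intercept = fit_l1_logreg(Xtr, ytr, strength, seed=seed, tol=tol)
        pred = Xval @ coef + intercept if coef.size else np.full(len(yval), intercept)
        try:
            auroc = auroc_from_labels(pred, yval)
        except ModelError:
            auroc = 0.5
        return coef, intercept, auroc

    coef, intercept, initial_auroc = fit_eval(l1_strength)
    trace = [
        {
            "l1_strength": l1_strength,
            "auroc": initial_auroc,
            "n_nonzero": int(np.count_nonzero(coef)),
            "accepted": True,
        }
    ]
    model = MotifModel(
        pfms=list(train.pfms),
        coefficients=coef,
        intercept=intercept,
        l1_strength=l1_strength,
        initial_auroc=initial_auroc,
        final_auroc=initial_auroc,
        standardizer=std,
        feature_names=names,
        trace=trace,
        seed=seed,
    )
    if initial_auroc <= 0.5:
        warnings.warn(
            "initial validation AUROC <= 0.5; skipping simplification",
            stacklevel=2,
        )
        return model
    threshold = 0.5 + RETENTION * (initial_auroc - 0.5)
    strength = l1_strength
    for _ in range(max_rounds):
        strength *= L1_SCALING
        coef, intercept, auroc = fit_eval(strength)
        accepted = auroc >= threshold
        trace.append(
            {
                "l1_strength": strength,
                "auroc": auroc,
                "n_nonzero": int(np.count_nonzero(coef)),
                "accepted": bool(accepted),
            }
        )
        if not accepted:
            break
        model.coefficients = coef
        model.intercept = intercept
        model.l1_strength = strength
        model.final_auroc = auroc
        if np.count_nonzero(coef) == 0:
            break
    return model


def apply_model(
    model: MotifModel,
    records: list,
    variable_region: tuple[int, int] | None = None,
):
    """Score probes with a fitted model, end to end.

    ``records`` are ``(name, sequence, dotbracket)`` triples; each probe is
    annotated, its retained PFMs scanned, features standardized with the
    stored training statistics, and the logistic probability returned.
    Probes that fail annotation get a NaN score and an error record instead
    of aborting the run.

    Returns ``(probabilities, errors)`` where ``errors`` is a list of
    ``(probe name, message)`` pairs.
    """
    from .annotate import annotate_probe
    from .scan import build_feature_matrix

    # restrict scanning to features that can move the score
    active = np.flatnonzero(model.coefficients != 0.0)
    probes = []
    ok_idx = []
    errors = []
    for i, (name, seq, db) in enumerate(records):
        try:
            probes.append(
                annotate_probe(seq, db, variable_region=variable_region, name=name)
            )
            ok_idx.append(i)
        except Exception as exc:  # noqa: BLE001 - per-probe error record
            errors.append((name, str(exc)))
    out = np.full(len(records), np.nan)
    if not probes:
        return out, errors
    if active.size == 0:
        out[ok_idx] = 1.0 / (1.0 + np.exp(-model.intercept))
        return out, errors
    pfms = [model.pfms[j] for j in active]
    fm = build_feature_matrix(pfms, probes, np.zeros(len(probes), dtype=int))
    X = fm.values[[model.pfms[j].name for j in active]].to_numpy()
    z = (
        (X - model.standardizer.means[active]) / model.standardizer.stds[active]
    ) @ model.coefficients[active] + model.intercept
    out[ok_idx] = 1.0 / (1.0 + np.exp(-z))
    return out, errors
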