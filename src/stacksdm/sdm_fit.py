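"""Per-species suitability modelling.

Algorithm adapters wrap scikit-learn estimators behind one contract:
``fit(X, y, seed)`` then ``predict(X) -> suitability in [0, 1]``. The rest
of the module supplies the evaluation machinery shared by every model:
confusion-matrix metrics, rank-based AUC, TSS-optimal thresholding,
stratified k-fold cross-validation and permutation variable importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .envgrid import EnvStack
from .occurrences import PresenceAbsenceSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table for a binarised prediction."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("confusion table is empty")


@dataclass
class EvalMetrics:
    """Standard presence-absence evaluation metrics.

    ``tss = sensitivity + specificity - 1`` and
    ``omission_rate = 1 - sensitivity`` hold by construction.
    """

    auc: float = float("nan")
    omission_rate: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    prop_correct: float = float("nan")
    kappa: float = float("nan")
    tss: float = float("nan")
    jaccard: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "omission_rate": self.omission_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "prop_correct": self.prop_correct,
            "kappa": self.kappa,
            "tss": self.tss,
            "jaccard": self.jaccard,
        }


def confusion_metrics(c: ConfusionCounts) -> EvalMetrics:
    """All threshold-dependent metrics from a confusion table.

    Kappa uses the usual chance-expected agreement from the marginal
    products: ``p_e = (P_pred+ * P_obs+) + (P_pred- * P_obs-)``.
    """
    n = c.TP + c.FP + c.TN + c.FN
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise ValueError("metrics undefined: one observed class is empty")
    sens = c.TP / (c.TP + c.FN)
    spec = c.TN / (c.TN + c.FP)
    prop_correct = (c.TP + c.TN) / n
    p_pred_pos = (c.TP + c.FP) / n
    p_obs_pos = (c.TP + c.FN) / n
    p_e = p_pred_pos * p_obs_pos + (1 - p_pred_pos) * (1 - p_obs_pos)
    kappa = 0.0 if p_e == 1 else (prop_correct - p_e) / (1 - p_e)
    jaccard = c.TP / (c.TP + c.FP + c.FN) if (c.TP + c.FP + c.FN) else 0.0
    return EvalMetrics(
        omission_rate=1 - sens,
        sensitivity=sens,
        specificity=spec,
        prop_correct=prop_correct,
        kappa=kappa,
        tss=sens + spec - 1,
        jaccard=jaccard,
    )


def auc_rank(pred_pos: np.ndarray, pred_neg: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = np.asarray(pred_pos, dtype=float)
    neg = np.asarray(pred_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both prediction lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return (r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)


def select_threshold(predictions: np.ndarray, labels: np.ndarray) -> float:
    """TSS-optimal binarisation threshold.

    Scans the sorted unique prediction values as candidates; a cell is
    presence iff ``prediction >= threshold``. Returns the smallest
    candidate maximising sensitivity + specificity.
    """
    preds = np.asarray(predictions, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present to select a threshold")
    candidates = np.unique(preds)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    # exact integer score over the common denominator n_pos * n_neg so
    # that mathematically tied thresholds compare equal (float TSS can
    # differ by one ulp between tied candidates)
    best_t, best_score = candidates[0], -1
    for t in candidates:
        pred_pos = preds >= t
        tp = int((pred_pos & (y == 1)).sum())
        tn = int((~pred_pos & (y == 0)).sum())
        score = tp * n_neg + tn * n_pos
        if score > best_score:  # strict: ties keep the smallest threshold
            best_score, best_t = score, t
    return float(best_t)


def metrics_at_threshold(predictions: np.ndarray, labels: np.ndarray, threshold: float) -> EvalMetrics:
    """Confusion metrics of ``predictions >= threshold`` plus rank AUC."""
    preds = np.asarray(predictions, dtype=float)
    y = np.asarray(labels).astype(int)
    pred_pos = preds >= threshold
    c = ConfusionCounts(
        TP=int((pred_pos & (y == 1)).sum()),
        FP=int((pred_pos & (y == 0)).sum()),
        TN=int((~pred_pos & (y == 0)).sum()),
        FN=int((~pred_pos & (y == 1)).sum()),
    )
    m = confusion_metrics(c)
    m.auc = auc_rank(preds[y == 1], preds[y == 0])
    return m


# ---------------------------------------------------------------------------
# algorithm adapters
# ---------------------------------------------------------------------------


class _SigmoidSVC:
    """SVC whose suitability is the logistic of the decision margin."""

    def __init__(self, pipeline: Pipeline) -> None:
        self._pipe = pipeline

    def fit(self, X, y):
        self._pipe.fit(X, y)
        return self

    @property
    def classes_(self):
        return self._pipe.named_steps["svc"].classes_

    def predict_proba(self, X):
        from scipy.special import expit

        margin = self._pipe.decision_function(X)
        p1 = expit(margin)
        return np.column_stack([1 - p1, p1])


@dataclass
class AlgorithmAdapter:
    """A fit/predict contract over one modelling algorithm.

    ``fit(X, y, seed)`` returns a fitted predictor whose ``predict``
    yields suitabilities in [0, 1]; deterministic under a fixed seed.
    """

    name: str
    hyperparams: dict = field(default_factory=dict)

    def build(self, seed: int):
        hp = self.hyperparams
        balanced = {"class_weight": "balanced"}
        if self.name == "CTA":
            return DecisionTreeClassifier(
                criterion="gini", random_state=seed, **balanced, **hp
            )
        if self.name == "RF":
            return RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 500),
                random_state=seed,
                class_weight="balanced",
                n_jobs=1,
            )
        if self.name == "GBM":
            return GradientBoostingClassifier(
                n_estimators=hp.get("n_estimators", 1000),
                learning_rate=hp.get("learning_rate", 0.01),
                max_depth=hp.get("max_depth", 3),
                random_state=seed,
            )
        if self.name == "SVM":
            # RBF margin mapped to [0, 1] through a logistic link; the map
            # is monotone, so AUC and TSS-threshold scans are unaffected
            return _SigmoidSVC(
                Pipeline(
                    [
                        ("scale", StandardScaler()),
                        ("svc", SVC(kernel="rbf", class_weight="balanced", random_state=seed, **hp)),
                    ]
                )
            )
        if self.name == "GLM":
            # logistic regression with quadratic response curves
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("poly", PolynomialFeatures(degree=hp.get("degree", 2), include_bias=False)),
                    ("logit", LogisticRegression(max_iter=2000, class_weight="balanced")),
                ]
            )
        if self.name == "ANN":
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPClassifier(
                            hidden_layer_sizes=hp.get("hidden_layer_sizes", (16,)),
                            max_iter=hp.get("max_iter", 1000),
                            random_state=seed,
                        ),
                    ),
                ]
            )
        raise NotImplementedError(
            f"algorithm '{self.name}' has no built-in adapter; register one "
            "via the same fit/predict contract"
        )

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "FittedPredictor":
        est = self.build(seed)
        est.fit(X, y)
        return FittedPredictor(name=self.name, estimator=est)


@dataclass
class FittedPredictor:
    name: str
    estimator: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        out = proba[:, classes.index(1)]
        return np.clip(out, 0.0, 1.0)


#: algorithms with built-in adapters
BUILTIN_ALGORITHMS = ("CTA", "GLM", "GBM", "RF", "SVM", "ANN")


def get_adapter(name: str, hyperparams: dict | None = None) -> AlgorithmAdapter:
    return AlgorithmAdapter(name=name, hyperparams=hyperparams or {})


# ---------------------------------------------------------------------------
# cross-validation, importance, full fit
# ---------------------------------------------------------------------------


def crossvalidate(
    pa: PresenceAbsenceSet,
    algo: AlgorithmAdapter,
    k: int = 20,
    n_reps: int = 10,
    seed: int = 0,
    return_pooled: bool = False,
):
    """Stratified k-fold cross-validation, averaged over replicates.

    Folds preserve the presence/absence ratio. Per-fold metrics are
    computed on the held-out predictions at the fold-specific TSS-optimal
    threshold, then averaged over folds and replicates. When a species has
    fewer presences (or absences) than ``k``, ``k`` is lowered to that
    class count and the reduction is logged.

    With ``return_pooled=True`` also returns the pooled out-of-fold
    predictions as an (n_reps, n_cells) array aligned with ``pa.y`` —
    the basis for resubstitution-free threshold selection.
    """
    y = pa.y
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("cross-validation needs at least 2 cells per class")
    k_eff = min(k, n_pos, n_neg)
    if k_eff < k:
        logger.info(
            "crossvalidate(%s/%s): k reduced %d -> %d (class sizes %d/%d)",
            pa.species, algo.name, k, k_eff, n_pos, n_neg,
        )
    fold_metrics: list[EvalMetrics] = []
    pooled = np.full((n_reps, len(y)), np.nan)
    for rep in range(n_reps):
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed + rep)
        for fold_i, (train, test) in enumerate(skf.split(pa.X, y)):
            model = algo.fit(pa.X[train], y[train], seed=seed + 1000 * rep + fold_i)
            preds = model.predict(pa.X[test])
            pooled[rep, test] = preds
            t = select_threshold(preds, y[test])
            fold_metrics.append(metrics_at_threshold(preds, y[test], t))
    arr = pd.DataFrame([m.as_dict() for m in fold_metrics])
    metrics = EvalMetrics(**arr.mean().to_dict())
    return (metrics, pooled) if return_pooled else metrics


def permutation_importance(
    model: FittedPredictor,
    pa: PresenceAbsenceSet,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Permutation variable importance as percentages summing to 100.

    The raw importance of a variable is the mean, over repeats, of
    ``1 - r`` where r is the Pearson correlation between the model's
    predictions on the intact design matrix and on a copy with that
    variable's column randomly permuted. Negative raw values are clipped
    to zero and the vector is normalised to percentages. A model whose
    output ignores the inputs gets all-zero importances.
    """
    rng = np.random.default_rng(seed)
    base = model.predict(pa.X)
    n_vars = pa.X.shape[1]
    raw = np.zeros(n_vars)
    base_sd = float(np.std(base))
    for v in range(n_vars):
        losses = []
        for _ in range(n_reps):
            Xp = pa.X.copy()
            Xp[:, v] = rng.permutation(Xp[:, v])
            perm = model.predict(Xp)
            if base_sd == 0:
                losses.append(0.0)
            elif np.std(perm) == 0:
                losses.append(1.0)  # prediction collapsed: total loss
            else:
                losses.append(1.0 - float(np.corrcoef(base, perm)[0, 1]))
        raw[v] = np.mean(losses)
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    pct = np.zeros(n_vars) if total == 0 else 100.0 * raw / total
    return pd.Series(pct, index=pa.layer_names, name=model.name)


@dataclass
class FittedSDM:
    """One species x one algorithm: suitability surface and its evaluation."""

    species: str
    algorithm: str
    suitability: np.ndarray  # grid in [0, 1], NaN outside valid mask
    cv_metrics: EvalMetrics
    threshold: float
    importance: pd.Series  # percent per layer, sums to 100 (or all zero)
    train_cells: list[tuple[int, int]]
    train_predictions: np.ndarray  # in-sample predictions at training cells
    cv_predictions: np.ndarray  # pooled out-of-fold predictions (threshold basis)
    y: np.ndarray

    @property
    def binary(self) -> np.ndarray:
        """Presence map: suitability >= threshold (False where nodata)."""
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(self.suitability), self.suitability >= self.threshold, False)


def predict_surface(model: FittedPredictor, stack: EnvStack, layer_names: list[str]) -> np.ndarray:
    """Predict suitability for every valid cell of the stack."""
    spec = stack.spec
    sub = stack.select(layer_names)
    rows, cols = np.where(spec.valid_mask)
    X = sub.extract(rows, cols)
    surface = np.full(spec.shape, np.nan)
    surface[rows, cols] = model.predict(X)
    return surface


def fit_species(
    pa: PresenceAbsenceSet,
    algo: AlgorithmAdapter,
    stack: EnvStack,
    k: int = 20,
    n_reps: int = 10,
    seed: int = 0,
) -> FittedSDM:
    """Full per-species fit: CV metrics, final refit, surface, threshold,
    permutation importance.

    The binarisation threshold is selected on pooled out-of-fold
    predictions rather than on in-sample predictions of the final model:
    flexible learners reproduce their training labels almost perfectly,
    and resubstitution thresholds are therefore biased high, shrinking
    predicted ranges. One threshold is selected per cross-validation
    replicate and the replicate thresholds are averaged.
    """
    if len(np.unique(pa.y)) < 2:
        raise ValueError(f"species '{pa.species}': need both presences and absences")
    cv, pooled = crossvalidate(pa, algo, k=k, n_reps=n_reps, seed=seed, return_pooled=True)
    model = algo.fit(pa.X, pa.y, seed=seed)
    in_sample = model.predict(pa.X)
    threshold = float(np.mean([select_threshold(row, pa.y) for row in pooled]))
    surface = predict_surface(model, stack, pa.layer_names)
    importance = permutation_importance(model, pa, n_reps=n_reps, seed=seed)
    return FittedSDM(
        species=pa.species,
        algorithm=algo.name,
        suitability=surface,
        cv_metrics=cv,
        threshold=threshold,
        importance=importance,
        train_cells=pa.cells,
        train_predictions=in_sample,
        cv_predictions=pooled,
        y=pa.y.copy(),
    )
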