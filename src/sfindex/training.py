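"""Logistic-regression training pipeline for the binary sperm-quality score.

The training target is the high-resolution sperm-head morphology score,
binarized (0 = score 0, 1 = score 6). Predictors are the three Δ[RNA]
values. The pipeline is: stratified train/test split → per-feature
z-scoring (training statistics only, applied unchanged to test data) →
class-weighted logistic regression fitted by iteratively reweighted
least squares (IRLS, i.e. Newton's method on the penalized
log-likelihood) → odds ratios per predictor → decision-threshold
optimization on the precision–recall curve (F1 by default, optionally
restricted to a probability band).

Conventions fixed here so tests can be exact:

* z-scores use the population (divide-by-n) standard deviation
  (``ddof=0``); a flag switches to the sample convention.
* precision is defined as 1 when no positives are predicted, which keeps
  the PR curve total at its high-threshold endpoint.
* a sample is predicted positive when its score >= threshold.
* all stochastic operations take an explicit integer seed; there is no
  module-level random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import (
    DegenerateFeatureError,
    EmptyBandError,
    PerfectSeparationError,
    StratificationError,
)

FEATURE_COLUMNS = ("delta_aurka", "delta_hdac4", "delta_carhsp1")

# |coefficient| on the z-score scale beyond which an unpenalized fit is
# treated as diverging on separable data (odds ratio ~ e^30)
_SEPARATION_BOUND = 30.0


@dataclass
class TrainingDataset:
    """Feature table (Δ[RNA] per gene) plus binary quality labels."""

    features: pd.DataFrame
    target: np.ndarray

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=int)
        if len(self.features) != len(self.target):
            raise ValueError("features and target differ in length")
        if len(self.target) and not set(np.unique(self.target)) <= {0, 1}:
            raise ValueError("target labels must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.target)

    def validate_for_fit(self) -> None:
        if self.n < 4:
            raise ValueError(f"need at least 4 samples, got {self.n}")
        if len(np.unique(self.target)) < 2:
            raise ValueError("both classes must be present")
        if self.features.isna().any().any():
            raise ValueError("features contain missing values")


@dataclass(frozen=True)
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    data: TrainingDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[TrainingDataset, TrainingDataset]:
    """Stratified random split, deterministic for a fixed seed.

    Per class, the training set receives round-half-up(n_class · fraction)
    samples; the remainder goes to the test set, so totals are conserved
    and both splits keep the class ratio up to rounding.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(np.unique(data.target)):
        idx = np.flatnonzero(data.target == label)
        if len(idx) < 2:
            raise StratificationError(
                f"class {label} has {len(idx)} member(s); cannot stratify"
            )
        n_train = _round_half_up(len(idx) * train_fraction)
        if n_train == 0 or n_train == len(idx):
            raise StratificationError(
                f"fraction {train_fraction} leaves class {label} absent from one split"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    f = data.features.reset_index(drop=True)
    return (
        TrainingDataset(f.iloc[train_idx].reset_index(drop=True), data.target[train_idx]),
        TrainingDataset(f.iloc[test_idx].reset_index(drop=True), data.target[test_idx]),
    )


def standardize(
    features: pd.DataFrame | np.ndarray,
    params: StandardizationParams | None = None,
    ddof: int = 0,
) -> tuple[pd.DataFrame | np.ndarray, StandardizationParams]:
    """z-score features; estimate parameters when none are supplied.

    Training mode (``params=None``): means and standard deviations are
    estimated from the input. Test mode: the supplied training parameters
    are applied as-is — never re-estimated, so no information leaks from
    the test set.
    """
    is_df = isinstance(features, pd.DataFrame)
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2:
        raise ValueError("features must be 2-dimensional")
    columns = tuple(features.columns) if is_df else tuple(
        f"x{i}" for i in range(arr.shape[1])
    )
    if params is None:
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=ddof)
        if np.any(sd <= 0):
            bad = [columns[i] for i in np.flatnonzero(sd <= 0)]
            raise DegenerateFeatureError(f"zero-variance feature(s): {bad}")
        params = StandardizationParams(mean=mean, sd=sd, columns=columns)
    z = (arr - params.mean) / params.sd
    if is_df:
        z = pd.DataFrame(z, columns=features.columns, index=features.index)
    return z, params


@dataclass(frozen=True)
class LogisticFit:
    """IRLS solution on the z-score scale."""

    coefficients: np.ndarray
    intercept: float
    odds_ratios: np.ndarray
    n_iter: int
    converged: bool


def _sample_weights(
    y: np.ndarray, class_weights: Mapping[int, float] | str | None
) -> np.ndarray:
    if class_weights is None:
        return np.ones_like(y, dtype=float)
    if class_weights == "balanced":
        n = len(y)
        counts = {c: int((y == c).sum()) for c in (0, 1)}
        class_weights = {c: n / (2.0 * counts[c]) for c in (0, 1)}
    w = np.array([class_weights[int(label)] for label in y], dtype=float)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    return w


def fit_logistic(
    features: pd.DataFrame | np.ndarray,
    target: Sequence[int],
    class_weights: Mapping[int, float] | str | None = None,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Class-weighted logistic regression by IRLS with optional L2 ridge.

    Maximizes sum_i w_i [y_i log p_i + (1−y_i) log(1−p_i)] − ridge·‖β‖²/2
    (the intercept is never penalized). Convergence is declared when the
    gradient norm drops below ``tol``; on (quasi-)separable data with
    ridge = 0 the coefficients diverge and a
    :class:`PerfectSeparationError` is raised advising ridge > 0.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    w = _sample_weights(y.astype(int), class_weights)

    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen_mask = np.ones(p + 1)
    pen_mask[0] = 0.0  # intercept unpenalized

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        prob = expit(eta)
        if ridge == 0.0 and np.max(np.abs(beta[1:])) > 8.0:
            # complete separation along the fitted direction → the MLE
            # does not exist and the coefficients are diverging
            if eta[y == 1].min() > eta[y == 0].max():
                raise PerfectSeparationError(
                    "classes are perfectly separated along the fitted direction; "
                    "the unpenalized MLE diverges — refit with ridge > 0"
                )
        grad = Xd.T @ (w * (y - prob)) - ridge * pen_mask * beta
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        irls_w = w * prob * (1.0 - prob)
        H = Xd.T @ (Xd * irls_w[:, None]) + ridge * np.diag(pen_mask)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                raise PerfectSeparationError(
                    "IRLS Hessian singular; classes appear perfectly separated — "
                    "refit with ridge > 0"
                ) from None
            raise
        beta = beta + step
        if ridge == 0.0 and np.max(np.abs(beta[1:])) > _SEPARATION_BOUND:
            raise PerfectSeparationError(
                "logistic coefficients diverging; classes appear perfectly "
                "separated — refit with ridge > 0"
            )
    if not converged and ridge == 0.0:
        raise PerfectSeparationError(
            f"IRLS did not converge in {max_iter} iterations with ridge = 0; "
            "if the classes are separable, refit with ridge > 0"
        )
    return LogisticFit(
        coefficients=beta[1:].copy(),
        intercept=float(beta[0]),
        odds_ratios=np.exp(beta[1:]),
        n_iter=it,
        converged=converged,
    )


@dataclass(frozen=True)
class PrCurve:
    """Precision and recall over every candidate decision threshold.

    Thresholds are the distinct predicted scores plus the endpoints 0 and
    1, in ascending order; a sample is predicted positive when its score
    >= threshold, and precision at an empty positive set is 1 by
    convention.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def triples(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.precision, self.recall))


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> PrCurve:
    """Exhaustive precision–recall curve over all candidate thresholds."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    thresholds = np.unique(np.concatenate([s, [0.0, 1.0]]))
    n_pos = int((y == 1).sum())
    precision = np.empty_like(thresholds)
    recall = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        precision[i] = tp / (tp + fp) if (tp + fp) > 0 else 1.0
        recall[i] = tp / n_pos
    return PrCurve(thresholds=thresholds, precision=precision, recall=recall)


def select_threshold(
    curve: PrCurve,
    band: tuple[float, float] | None = None,
    criterion: str = "f1",
) -> float:
    """Decision threshold maximizing the selection criterion (F1 by default).

    ``band`` restricts the search to an inclusive probability interval;
    ties are broken toward the lowest threshold.
    """
    if criterion != "f1":
        raise ValueError(f"unknown criterion {criterion!r}")
    t = curve.thresholds
    mask = np.ones_like(t, dtype=bool)
    if band is not None:
        lo, hi = band
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise EmptyBandError(f"no candidate thresholds inside band [{lo}, {hi}]")
    p, r = curve.precision[mask], curve.recall[mask]
    denom = p + r
    f1 = np.where(denom > 0, 2 * p * r / np.where(denom > 0, denom, 1.0), 0.0)
    # F1 values equal in exact arithmetic can differ by one ulp here; treat
    # anything within 1e-12 of the maximum as tied and take the lowest threshold
    tied = f1 >= f1.max() - 1e-12
    return float(t[mask][int(np.argmax(tied))])


@dataclass(frozen=True)
class EvalReport:
    split: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    accuracy: float


def _confusion_report(y: np.ndarray, pred: np.ndarray, split: str) -> EvalReport:
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return EvalReport(
        split=split,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=tp / (tp + fp) if (tp + fp) > 0 else 1.0,
        recall=tp / (tp + fn) if (tp + fn) > 0 else 1.0,
        accuracy=(tp + tn) / len(y),
    )


class ExpressionClassifier(BaseEstimator, ClassifierMixin):
    """Standardize → class-weighted logistic regression → thresholded calls.

    A scikit-learn-style estimator wrapping the whole fit pipeline: the
    training data's per-feature mean/sd are stored and reused verbatim at
    prediction time (no leakage), coefficients live on the z-score scale
    and ``odds_ratios_`` = exp(coefficients). When
    ``optimize_threshold=True`` the decision threshold is chosen on the
    training PR curve (F1, optionally inside ``threshold_band``);
    otherwise ``decision_threshold`` is used as-is.

    Parameters
    ----------
    class_weight : "balanced", mapping label→weight, or None
    ridge : float, L2 penalty on coefficients (intercept unpenalized)
    decision_threshold : float in (0, 1), used when not optimizing
    optimize_threshold : bool
    threshold_band : optional (lo, hi) inclusive probability interval
    ddof : 0 for population-sd z-scores (default), 1 for sample sd
    """

    def __init__(
        self,
        class_weight: Mapping[int, float] | str | None = "balanced",
        ridge: float = 0.0,
        decision_threshold: float = 0.5,
        optimize_threshold: bool = False,
        threshold_band: tuple[float, float] | None = None,
        max_iter: int = 100,
        tol: float = 1e-8,
        ddof: int = 0,
    ) -> None:
        self.class_weight = class_weight
        self.ridge = ridge
        self.decision_threshold = decision_threshold
        self.optimize_threshold = optimize_threshold
        self.threshold_band = threshold_band
        self.max_iter = max_iter
        self.tol = tol
        self.ddof = ddof

    def fit(self, X, y) -> "ExpressionClassifier":
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        TrainingDataset(X_df, y).validate_for_fit()
        z, self.standardization_ = standardize(X_df, ddof=self.ddof)
        fit = fit_logistic(
            z, y, class_weights=self.class_weight, ridge=self.ridge,
            max_iter=self.max_iter, tol=self.tol,
        )
        self.coef_ = fit.coefficients
        self.intercept_ = fit.intercept
        self.odds_ratios_ = fit.odds_ratios
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X_df.columns, dtype=object)
        if self.optimize_threshold:
            curve = pr_curve(self._proba1(X_df), y)
            self.decision_threshold_ = select_threshold(curve, band=self.threshold_band)
        else:
            self.decision_threshold_ = float(self.decision_threshold)
        return self

    def _proba1(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        z = (arr - self.standardization_.mean) / self.standardization_.sd
        return expit(z @ self.coef_ + self.intercept_)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self._proba1(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self._proba1(X) >= self.decision_threshold_).astype(int)

    def to_artifact(self) -> dict:
        """JSON-serializable model artifact."""
        return {
            "coefficients": self.coef_.tolist(),
            "intercept": self.intercept_,
            "odds_ratios": self.odds_ratios_.tolist(),
            "decision_threshold": self.decision_threshold_,
            "standardization": {
                "mean": self.standardization_.mean.tolist(),
                "sd": self.standardization_.sd.tolist(),
                "columns": list(self.standardization_.columns),
            },
            "params": {
                "class_weight": self.class_weight
                if not isinstance(self.class_weight, Mapping)
                else {str(k): v for k, v in self.class_weight.items()},
                "ridge": self.ridge,
                "ddof": self.ddof,
            },
        }

    @classmethod
    def from_artifact(cls, artifact: dict) -> "ExpressionClassifier":
        clf = cls(ridge=artifact["params"]["ridge"], ddof=artifact["params"]["ddof"])
        clf.coef_ = np.asarray(artifact["coefficients"], dtype=float)
        clf.intercept_ = float(artifact["intercept"])
        clf.odds_ratios_ = np.asarray(artifact["odds_ratios"], dtype=float)
        clf.decision_threshold_ = float(artifact["decision_threshold"])
        std = artifact["standardization"]
        clf.standardization_ = StandardizationParams(
            mean=np.asarray(std["mean"], dtype=float),
            sd=np.asarray(std["sd"], dtype=float),
            columns=tuple(std["columns"]),
        )
        clf.classes_ = np.array([0, 1])
        return clf


def evaluate(
    classifier: ExpressionClassifier, data: TrainingDataset, split: str = "test"
) -> EvalReport:
    """Confusion counts and precision/recall/accuracy at the stored threshold."""
    if data.n == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    pred = classifier.predict(data.features).astype(bool)
    return _confusion_report(data.target, pred, split)


def cross_validate(
    data: TrainingDataset,
    k: int = 5,
    seed: int = 0,
    **classifier_params,
) -> list[EvalReport]:
    """Stratified k-fold CV; each fold evaluated with its own fitted model.

    Folds are disjoint, cover the data, and per class their sizes differ
    by at most one. A class smaller than k cannot be spread over every
    fold, which raises :class:`StratificationError`.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = data.target
    for label in (0, 1):
        if int((y == label).sum()) < k:
            raise StratificationError(
                f"class {label} has fewer than k={k} members; cannot stratify"
            )
    rng = np.random.default_rng(seed)
    fold_of = np.empty(data.n, dtype=int)
    for label in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == label))
        fold_of[idx] = np.arange(len(idx)) % k
    features = data.features.reset_index(drop=True)
    reports = []
    for j in range(k):
        test_mask = fold_of == j
        train = TrainingDataset(features[~test_mask].reset_index(drop=True), y[~test_mask])
        test = TrainingDataset(features[test_mask].reset_index(drop=True), y[test_mask])
        clf = ExpressionClassifier(**classifier_params).fit(train.features, train.target)
        reports.append(evaluate(clf, test, split=f"fold{j}"))
    return reports
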