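"""Logistic-regression occlusion inference and the repeated-split evaluation.

The classifier estimates P(occlusion | x) = sigmoid(b0 + b·x̃) from the three
dynamic features, with x̃ the z-scored features (standardization constants are
learned on the training fold and stored in the model so that weight
magnitudes are comparable across features of different scales).  The fit
maximizes the log-likelihood; an infinitesimal ridge (1e-8) guards against
divergence on separable folds.

Evaluation mirrors the repeated random-split protocol: shuffle the cohort,
split into a 40-subject training set and 13-subject test set, fit, classify
at a 0.50 probability threshold, and repeat 20 times with fresh shuffles;
per-trial accuracy / precision / recall / NPV and the standardized weights
are aggregated as mean ± SD, and the accuracies are tested one-sided against
the cohort's chance level (the majority-class / all-positive baseline).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .core_types import CohortTable, FeatureVector, PulseScreenError

logger = logging.getLogger(__name__)

__all__ = [
    "FittingError",
    "LogrModel",
    "TrialResult",
    "EvalReport",
    "fit_logr",
    "predict_proba",
    "classify",
    "compute_metrics",
    "chance_level",
    "evaluate_repeated",
]

FEATURE_NAMES = ("MCC", "DNP", "DPA")


class FittingError(PulseScreenError):
    """Training set unusable (single class) or optimizer failed."""


@dataclass
class LogrModel:
    """Fitted logistic classifier with its standardization constants.

    ``b0`` and ``b = [b1, b2, b3]`` act on z-scored features; ``center`` and
    ``scale`` are the per-feature training-fold mean and SD used for the
    z-scoring.  ``threshold`` is the probability cutoff for the Positive
    call (strictly greater than).
    """

    b0: float
    b: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    threshold: float = 0.50

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.b.shape != (3,):
            raise ValueError(f"weight vector must have length 3, got {self.b.shape}")
        if np.any(self.scale <= 0):
            raise ValueError("standardization scales must be > 0")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], FeatureVector):
        return np.array([f.as_array() for f in X])
    return np.asarray(X, dtype=float)


def fit_logr(X, y, threshold: float = 0.50, max_iter: int = 1000) -> LogrModel:
    """Maximum-likelihood logistic regression on z-scored features.

    ``X`` is an (n, 3) feature matrix (or a list of FeatureVectors); ``y``
    holds binary labels (1/0 or Positive/Negative).  A tiny ridge (1e-8) is
    applied solely for numerical rank safety on separable folds.
    """
    X = _as_matrix(X)
    y = np.asarray([1 if str(v) in ("1", "Positive", "True") else 0 for v in y])
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"X must be (n, 3), got {X.shape}")
    classes = np.unique(y)
    if classes.size < 2:
        raise FittingError("training set contains a single class")

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant feature -> weight 0 anyway
    Xz = (X - center) / scale

    clf = LogisticRegression(C=1e8, solver="lbfgs", max_iter=max_iter)
    clf.fit(Xz, y)
    if clf.n_iter_[0] >= max_iter:
        raise FittingError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(coef={clf.coef_.ravel()})"
        )
    return LogrModel(
        b0=float(clf.intercept_[0]),
        b=clf.coef_.ravel(),
        center=center,
        scale=scale,
        threshold=threshold,
    )


def predict_proba(model: LogrModel, x: FeatureVector | np.ndarray) -> float | np.ndarray:
    """P(Positive | x) = sigmoid(b0 + b · x̃) with x̃ the z-scored features."""
    arr = x.as_array() if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    z = (arr - model.center) / model.scale
    logit = model.b0 + z @ model.b
    p = expit(logit)  # overflow-safe sigmoid
    return float(p[0]) if single else p


def classify(model: LogrModel, x: FeatureVector | np.ndarray) -> str:
    """Positive iff P(Positive | x) strictly exceeds the threshold.

    An exact tie at the threshold is Negative: the Positive call requires
    the probability to be *greater than* the preset cutoff.
    """
    return "Positive" if predict_proba(model, x) > model.threshold else "Negative"


def compute_metrics(TP: int, FP: int, TN: int, FN: int) -> dict[str, float | None]:
    """Accuracy, precision, recall and NPV from confusion counts.

    accuracy = (TP+TN)/(TP+FP+TN+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); npv = TN/(TN+FN).  A metric with a zero
    denominator is returned as None (undefined) rather than 0.
    """
    counts = (TP, FP, TN, FN)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative counts: {counts}")
    total = sum(counts)
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return {
        "accuracy": (TP + TN) / total,
        "precision": TP / (TP + FP) if TP + FP > 0 else None,
        "recall": TP / (TP + FN) if TP + FN > 0 else None,
        "npv": TN / (TN + FN) if TN + FN > 0 else None,
    }


def chance_level(labels) -> float:
    """Accuracy of the trivial all-positive classifier.

    Occlusion screening must not miss positives, so the baseline against
    which the method is judged is the classifier that calls every subject
    Positive; its accuracy is the positive-class ratio (23/53 ≈ 0.43 for
    the reference cohort).
    """
    labels = [str(lab) for lab in labels]
    if not labels:
        raise ValueError("empty labels")
    n_pos = sum(lab in ("Positive", "1", "True") for lab in labels)
    return n_pos / len(labels)


# --------------------------------------------------------------------------
# Repeated random-split evaluation
# --------------------------------------------------------------------------


@dataclass
class TrialResult:
    seed: int
    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    precision: float | None
    recall: float | None
    npv: float | None
    weights: np.ndarray
    intercept: float

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "npv": self.npv,
            "weights": [float(w) for w in self.weights],
            "intercept": self.intercept,
        }


@dataclass
class EvalReport:
    """Aggregate of the repeated-split evaluation.

    ``metric_means`` / ``metric_sds`` aggregate over trials where the metric
    was defined; ``n_undefined`` counts exclusions per metric.  The t-test
    is one-sided, one-sample over the per-trial accuracies against the
    cohort chance level, with significance assessed at alpha = 0.01.
    """

    trials: list[TrialResult]
    chance_level: float
    metric_means: dict[str, float]
    metric_sds: dict[str, float]
    n_undefined: dict[str, int]
    weight_means: np.ndarray
    weight_sds: np.ndarray
    t_statistic: float
    p_value: float
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "n_trials": len(self.trials),
            "chance_level": self.chance_level,
            "metrics": {
                name: {
                    "mean": self.metric_means[name],
                    "sd": self.metric_sds[name],
                    "n_undefined": self.n_undefined[name],
                }
                for name in self.metric_means
            },
            "weights": {
                name: {"mean": float(m), "sd": float(s)}
                for name, m, s in zip(FEATURE_NAMES, self.weight_means, self.weight_sds)
            },
            "t_test": {
                "statistic": self.t_statistic,
                "p_value": self.p_value,
                "alpha": self.alpha,
                "significant": self.significant,
            },
            "trials": [t.to_dict() for t in self.trials],
        }

    def to_json(self, path: str | Path | None = None, **meta) -> str:
        payload = {**meta, **self.to_dict()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_repeated(
    cohort: CohortTable,
    n_trials: int = 20,
    train_size: int = 40,
    base_seed: int = 0,
    threshold: float = 0.50,
) -> EvalReport:
    """Run the repeated shuffled-split protocol and aggregate the results.

    Trial *i* shuffles the cohort with seed ``base_seed + i``, takes the
    first ``train_size`` subjects for training and the rest for testing,
    fits the classifier and scores the test set.  A trial whose training
    split is single-class is re-drawn with the next seed (more than 10
    consecutive re-draws abort).  With the reference composition (53
    subjects, train 40) every test set has exactly 13 subjects.
    """
    X, y, _ = cohort.feature_matrix()
    n = X.shape[0]
    if n <= train_size:
        raise ValueError(f"cohort size {n} must exceed train_size {train_size}")
    if np.unique(y).size < 2:
        raise FittingError("cohort contains a single class")

    trials: list[TrialResult] = []
    seed = int(base_seed)
    for _trial in range(n_trials):
        redraws = 0
        while True:
            rng = np.random.default_rng(seed)
            perm = rng.permutation(n)
            tr, te = perm[:train_size], perm[train_size:]
            if np.unique(y[tr]).size == 2:
                break
            logger.warning("trial seed %d: single-class training split, re-drawing", seed)
            seed += 1
            redraws += 1
            if redraws > 10:
                raise FittingError("more than 10 consecutive single-class splits")
        model = fit_logr(X[tr], y[tr], threshold=threshold)
        proba = predict_proba(model, X[te])
        pred = (proba > threshold).astype(int)
        truth = y[te]
        TP = int(np.sum((pred == 1) & (truth == 1)))
        FP = int(np.sum((pred == 1) & (truth == 0)))
        TN = int(np.sum((pred == 0) & (truth == 0)))
        FN = int(np.sum((pred == 0) & (truth == 1)))
        m = compute_metrics(TP, FP, TN, FN)
        trials.append(
            TrialResult(
                seed=seed, TP=TP, FP=FP, TN=TN, FN=FN,
                accuracy=m["accuracy"], precision=m["precision"],
                recall=m["recall"], npv=m["npv"],
                weights=model.b.copy(), intercept=model.b0,
            )
        )
        seed += 1

    metric_means, metric_sds, n_undef = {}, {}, {}
    for name in ("accuracy", "precision", "recall", "npv"):
        vals = [getattr(t, name) for t in trials]
        defined = np.array([v for v in vals if v is not None], dtype=float)
        n_undef[name] = len(vals) - defined.size
        metric_means[name] = float(defined.mean()) if defined.size else float("nan")
        metric_sds[name] = float(defined.std(ddof=1)) if defined.size > 1 else float("nan")

    W = np.vstack([t.weights for t in trials])
    chance = chance_level(cohort.labels)
    accs = np.array([t.accuracy for t in trials])
    if np.ptp(accs) == 0:
        # degenerate zero-variance case (e.g. a perfectly separable cohort)
        t_stat = np.inf if accs[0] > chance else (-np.inf if accs[0] < chance else 0.0)
        p_val = 0.0 if accs[0] > chance else 1.0
    else:
        tt = stats.ttest_1samp(accs, chance, alternative="greater")
        t_stat, p_val = float(tt.statistic), float(tt.pvalue)

    return EvalReport(
        trials=trials,
        chance_level=chance,
        metric_means=metric_means,
        metric_sds=metric_sds,
        n_undefined=n_undef,
        weight_means=W.mean(axis=0),
        weight_sds=W.std(axis=0, ddof=1),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )
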