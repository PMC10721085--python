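"""Linear readout of the physical reservoir.

Only the readout is trained: per-class scores are a linear (ridge) or
softmax (multinomial logistic) function of the tracked coordinates.  The
ridge weights use the closed form

    W_out = Y_target^T X (X^T X + alpha I)^{-1}

with one-hot targets Y_target, no intercept, and a heavy default
regularizer alpha = 1e6.  Classification takes the argmax of a tau-step
moving average of the scores; accuracy is the fraction of correctly
labelled steps, and the cross-entropy error L = -mean_n log y_{true}(n)
quantifies score quality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import softmax
from sklearn.linear_model import LogisticRegression


@dataclass
class LabelSeries:
    """Per-step integer class labels plus class semantics.

    class_table maps class id -> (wind direction in degrees,
    speed level in {1, 4, 7}).
    """

    labels: np.ndarray
    n_classes: int
    class_table: dict[int, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if self.labels.min(initial=0) < 0 or \
                self.labels.max(initial=0) >= self.n_classes:
            raise ValueError("labels out of range for n_classes")

    def one_hot(self) -> np.ndarray:
        """N x C one-hot target matrix Y_target."""
        y = np.zeros((self.labels.size, self.n_classes))
        y[np.arange(self.labels.size), self.labels] = 1.0
        return y

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class StandardizationStats:
    """Per-column mean and population variance from the training rows."""

    mean: np.ndarray
    variance: np.ndarray
    epsilon: float = 1e-12

    def apply(self, X: np.ndarray) -> np.ndarray:
        denom = np.sqrt(np.maximum(self.variance, self.epsilon))
        return (np.asarray(X, float) - self.mean) / denom


def standardize_fit(X_train: np.ndarray,
                    epsilon: float = 1e-12) -> StandardizationStats:
    """Fit column means/variances (population convention, divide by N)."""
    X_train = np.asarray(X_train, float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    var = X_train.var(axis=0)
    if np.any(var <= epsilon):
        warnings.warn("zero-variance column(s) floored by epsilon during "
                      "standardization", RuntimeWarning, stacklevel=2)
    return StandardizationStats(X_train.mean(axis=0), var, epsilon)


def standardize_fit_apply(X_train: np.ndarray, X_other: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray | None,
                                     StandardizationStats]:
    """Standardize X_train and (with the same stats) X_other."""
    stats = standardize_fit(X_train)
    out = stats.apply(X_other) if X_other is not None else None
    return stats.apply(X_train), out, stats


def fit_ridge(X: np.ndarray, Y_target: np.ndarray,
              alpha: float = 1e6) -> np.ndarray:
    """Closed-form ridge readout W_out (C x M), no intercept.

    Solves W_out = Y^T X (X^T X + alpha I)^{-1} via a symmetric linear
    solve rather than an explicit inverse.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y_target, float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y_target must have the same number of rows")
    m = X.shape[1]
    gram = X.T @ X + alpha * np.eye(m)
    # (X^T X + aI) W^T = X^T Y  <=>  W = Y^T X (X^T X + aI)^{-1}
    return np.linalg.solve(gram, X.T @ Y).T


@dataclass
class ReadoutModel:
    """Trained readout: ridge weights or logistic coefficients.

    Exactly one of W_out (ridge, C x M) / beta (logistic) is set.  beta
    holds K-1 reference-class coefficient rows of length M+1 (intercept
    first); the last class is the reference with an implicit zero row.
    stats, when present, is applied to inputs before scoring.  tau_ma is
    the default moving-average window for classification.
    """

    method: str
    n_classes: int
    W_out: np.ndarray | None = None
    beta: np.ndarray | None = None
    alpha: float = 1e6
    stats: StandardizationStats | None = None
    tau_ma: int = 30
    converged: bool = True
    class_table: dict[int, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.W_out is None) == (self.beta is None):
            raise ValueError("exactly one of W_out / beta must be set")

    @property
    def n_units(self) -> int:
        if self.W_out is not None:
            return self.W_out.shape[1]
        return self.beta.shape[1] - 1

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        obj = {"method": self.method, "n_classes": self.n_classes,
               "alpha": self.alpha, "tau_ma": self.tau_ma,
               "converged": self.converged,
               "class_table": {str(k): list(v)
                               for k, v in self.class_table.items()}}
        if self.W_out is not None:
            obj["W_out"] = self.W_out.tolist()
        if self.beta is not None:
            obj["beta"] = self.beta.tolist()
        if self.stats is not None:
            obj["stats"] = {"mean": self.stats.mean.tolist(),
                            "variance": self.stats.variance.tolist(),
                            "epsilon": self.stats.epsilon}
        path.write_text(json.dumps(obj))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ReadoutModel":
        obj = json.loads(Path(path).read_text())
        stats = None
        if "stats" in obj:
            stats = StandardizationStats(np.asarray(obj["stats"]["mean"]),
                                         np.asarray(obj["stats"]["variance"]),
                                         obj["stats"]["epsilon"])
        return cls(method=obj["method"], n_classes=obj["n_classes"],
                   W_out=np.asarray(obj["W_out"]) if "W_out" in obj else None,
                   beta=np.asarray(obj["beta"]) if "beta" in obj else None,
                   alpha=obj.get("alpha", 1e6), stats=stats,
                   tau_ma=obj.get("tau_ma", 30),
                   converged=obj.get("converged", True),
                   class_table={int(k): (float(v[0]), int(v[1]))
                                for k, v in obj.get("class_table", {}).items()})


def predict_scores(model: ReadoutModel, X: np.ndarray) -> np.ndarray:
    """Per-step class scores y(n): linear scores (ridge) or softmax
    probabilities (logistic)."""
    X = np.asarray(X, float)
    if X.shape[1] != model.n_units:
        raise ValueError(f"X has {X.shape[1]} columns, model expects "
                         f"{model.n_units}")
    if model.stats is not None:
        X = model.stats.apply(X)
    if model.method == "ridge":
        return X @ model.W_out.T
    logits = model.beta[:, 0] + X @ model.beta[:, 1:].T  # (N, K-1)
    logits = np.column_stack([logits, np.zeros(X.shape[0])])  # reference class
    return softmax(logits, axis=1)


def moving_average(scores: np.ndarray, tau: int,
                   segment_starts: np.ndarray | None = None) -> np.ndarray:
    """Truncated tau-step trailing moving average of score rows.

    Early rows average over however many steps are available.  If
    segment_starts is given (indices where a new recording begins) the
    window is reset there, so smoothing never crosses recording
    boundaries.
    """
    scores = np.asarray(scores, float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau == 1:
        return scores.copy()
    n = scores.shape[0]
    starts = np.zeros(n, bool)
    starts[0] = True
    if segment_starts is not None:
        starts[np.asarray(segment_starts, int)] = True
    out = np.empty_like(scores)
    cum = np.zeros((n + 1, scores.shape[1]))
    np.cumsum(scores, axis=0, out=cum[1:])
    seg_start = 0
    for i in range(n):
        if starts[i]:
            seg_start = i
        lo = max(i - tau + 1, seg_start)
        out[i] = (cum[i + 1] - cum[lo]) / (i + 1 - lo)
    return out


def classify(scores: np.ndarray, tau_ma: int = 1,
             segment_starts: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """(smoothed scores, predicted classes) via moving-average argmax.

    Ties go to the smallest class index (numpy argmax convention).
    """
    smoothed = moving_average(scores, tau_ma, segment_starts)
    return smoothed, smoothed.argmax(axis=1)


def accuracy(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of steps whose predicted class equals the label."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must have equal length")
    return float(np.mean(predicted == labels))


def cross_entropy(scores: np.ndarray, Y_target: np.ndarray,
                  clip: float = 1e-12) -> float:
    """Mean negative log score of the true class.

    Scores are clipped to [clip, 1] before the log, so the function is
    defined even for raw (non-probability) ridge scores.
    """
    scores = np.clip(np.asarray(scores, float), clip, 1.0)
    Y = np.asarray(Y_target, float)
    return float(-(Y * np.log(scores)).sum() / scores.shape[0])


@dataclass
class ClassificationOutput:
    scores: np.ndarray
    smoothed: np.ndarray
    predicted: np.ndarray
    accuracy: float
    cross_entropy: float


def fit_multinomial_logistic(X: np.ndarray, labels: np.ndarray,
                             max_iter: int = 1500
                             ) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood softmax coefficients, reference-class form.

    Returns (beta, converged) where beta is (K-1) x (M+1) with the
    intercept in column 0 and the last class as the zero reference.  The
    likelihood is unpenalized; on separable data the optimizer may hit
    max_iter without converging, in which case converged is False and the
    coefficients are still returned.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels, int)
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("need at least 2 classes present in labels")
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable data hits max_iter by design
        clf.fit(X, labels)
    n_iter = int(np.max(clf.n_iter_))
    coef = clf.coef_
    intercept = clf.intercept_
    if present.size == 2:
        # sklearn stores one row for the binary case (class present[1] vs
        # present[0]); expand to the symmetric two-row form first.
        coef = np.vstack([-coef, coef])
        intercept = np.array([-intercept[0], intercept[0]])
    # reference-class parameterization: subtract the last class's row
    coef_ref = coef[:-1] - coef[-1]
    icpt_ref = intercept[:-1] - intercept[-1]
    beta = np.column_stack([icpt_ref, coef_ref])
    return beta, n_iter < max_iter


def fit_readout(X_train: np.ndarray, labels: LabelSeries | np.ndarray,
                method: str = "ridge", alpha: float = 1e6,
                standardize: bool = False, tau_ma: int = 30,
                max_iter: int = 1500,
                n_classes: int | None = None) -> ReadoutModel:
    """Train a readout model on (X_train, labels)."""
    if isinstance(labels, LabelSeries):
        lab = labels.labels
        n_classes = labels.n_classes
        table = labels.class_table
    else:
        lab = np.asarray(labels, int)
        n_classes = n_classes or int(lab.max()) + 1
        table = {}
    stats = None
    X_fit = np.asarray(X_train, float)
    if standardize:
        stats = standardize_fit(X_fit)
        X_fit = stats.apply(X_fit)
    if method == "ridge":
        y = np.zeros((lab.size, n_classes))
        y[np.arange(lab.size), lab] = 1.0
        w = fit_ridge(X_fit, y, alpha)
        return ReadoutModel("ridge", n_classes, W_out=w, alpha=alpha,
                            stats=stats, tau_ma=tau_ma, class_table=table)
    if method == "logistic":
        beta, conv = fit_multinomial_logistic(X_fit, lab, max_iter)
        if beta.shape[0] != n_classes - 1:
            raise ValueError("all classes must be present in training labels")
        return ReadoutModel("logistic", n_classes, beta=beta, stats=stats,
                            tau_ma=tau_ma, converged=conv, class_table=table)
    raise ValueError(f"unknown method {method!r}")


def evaluate_readout(model: ReadoutModel, X: np.ndarray,
                     labels: LabelSeries | np.ndarray,
                     tau_ma: int | None = None,
                     segment_starts: np.ndarray | None = None
                     ) -> ClassificationOutput:
    """Score, smooth, classify and summarize on a labelled series."""
    lab = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels, int)
    scores = predict_scores(model, X)
    tau = model.tau_ma if tau_ma is None else tau_ma
    smoothed, pred = classify(scores, tau, segment_starts)
    y = np.zeros((lab.size, model.n_classes))
    y[np.arange(lab.size), lab] = 1.0
    return ClassificationOutput(scores, smoothed, pred,
                                accuracy(pred, lab),
                                cross_entropy(scores, y))
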