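"""Robustness, generalization and augmentation experiments on a reservoir.

Four drivers probe what the harvested reservoir computes:

* unit subsampling -- retrain on random subsets of units to find how many
  coordinates suffice;
* weight ablation -- zero readout-weight columns (in feature-point pairs,
  without retraining) to measure robustness to lost sensors;
* leave-one-class-out -- train without one wind class and ask whether the
  readout still recognizes its wind *direction*;
* delay augmentation -- widen a unit-poor reservoir with time-shifted
  copies X(t + tau), ..., X(t + d*tau).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .readout import (LabelSeries, ReadoutModel, fit_readout, predict_scores,
                      classify, accuracy, standardize_fit)


def chronological_split(labels: np.ndarray, train_fraction: float = 0.7
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment chronological split indices.

    Each maximal run of a constant label is one recording; its first
    train_fraction of rows train, the rest test.
    """
    labels = np.asarray(labels)
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], boundaries, [labels.size]])
    train, test = [], []
    for lo, hi in zip(starts[:-1], starts[1:]):
        n_tr = int(round(train_fraction * (hi - lo)))
        train.extend(range(lo, lo + n_tr))
        test.extend(range(lo + n_tr, hi))
    return np.asarray(train), np.asarray(test)


# ---------------------------------------------------------------------------
# unit subsampling
# ---------------------------------------------------------------------------


@dataclass
class SubsampleResult:
    n_units: int
    accuracies: np.ndarray
    seed: int
    method: str
    unit_sets: list[np.ndarray] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))


def subsample_experiment(X: np.ndarray, labels: LabelSeries | np.ndarray,
                         n_units: int, n_trials: int = 1000, seed: int = 0,
                         method: str = "ridge", alpha: float = 1e6,
                         train_idx: np.ndarray | None = None,
                         test_idx: np.ndarray | None = None,
                         standardize: bool = False,
                         tau_ma: int = 1,
                         max_iter: int = 1500) -> SubsampleResult:
    """Test accuracy over random unit subsets, readout retrained per trial.

    Each trial draws n_units columns uniformly without replacement, trains
    on the train rows and evaluates step-wise accuracy on the test rows.
    For the ridge method the Gram matrices are precomputed once, so 1000
    trials cost little more than one full fit.
    """
    lab = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels, int)
    n_classes = labels.n_classes if isinstance(labels, LabelSeries) \
        else int(lab.max()) + 1
    X = np.asarray(X, float)
    m = X.shape[1]
    if not (1 <= n_units <= m):
        raise ValueError(f"n_units must be in [1, {m}]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if train_idx is None or test_idx is None:
        train_idx, test_idx = chronological_split(lab)
    rng = np.random.default_rng(seed)
    X_tr, X_te = X[train_idx], X[test_idx]
    y_tr, y_te = lab[train_idx], lab[test_idx]
    if standardize:
        stats = standardize_fit(X_tr)
        X_tr, X_te = stats.apply(X_tr), stats.apply(X_te)
    accs = np.empty(n_trials)
    unit_sets: list[np.ndarray] = []
    if method == "ridge":
        Y = np.zeros((y_tr.size, n_classes))
        Y[np.arange(y_tr.size), y_tr] = 1.0
        gram = X_tr.T @ X_tr
        xty = X_tr.T @ Y
        for trial in range(n_trials):
            idx = rng.choice(m, size=n_units, replace=False)
            unit_sets.append(idx)
            g = gram[np.ix_(idx, idx)] + alpha * np.eye(n_units)
            w = np.linalg.solve(g, xty[idx])  # (n_units, C)
            scores = X_te[:, idx] @ w
            _, pred = classify(scores, tau_ma)
            accs[trial] = accuracy(pred, y_te)
    elif method == "logistic":
        for trial in range(n_trials):
            idx = rng.choice(m, size=n_units, replace=False)
            unit_sets.append(idx)
            model = fit_readout(X_tr[:, idx], y_tr, method="logistic",
                                max_iter=max_iter, n_classes=n_classes)
            scores = predict_scores(model, X_te[:, idx])
            _, pred = classify(scores, tau_ma)
            accs[trial] = accuracy(pred, y_te)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SubsampleResult(n_units, accs, seed, method, unit_sets)


# ---------------------------------------------------------------------------
# weight ablation
# ---------------------------------------------------------------------------


@dataclass
class AblationTrace:
    basis_class: int
    removed_counts: np.ndarray
    accuracies: np.ndarray
    order: str


def ablate_weights(model: ReadoutModel, basis_class: int,
                   n_remove_units: int,
                   order: str = "increasing") -> ReadoutModel:
    """Zero n_remove_units readout-weight columns, in feature-point pairs.

    Units are ranked by |W_out[basis_class, unit]| (increasing or
    decreasing); walking the ranking, each visited unit's feature-point
    *pair* of columns (x and y of the same point) is zeroed across all
    classes, until n_remove_units columns are gone.  The weights are never
    retrained.
    """
    if model.method != "ridge" or model.W_out is None:
        raise ValueError("ablation operates on a ridge readout")
    if n_remove_units % 2 != 0 or n_remove_units < 0:
        raise ValueError("n_remove_units must be even and >= 0 "
                         "(units are removed in feature-point pairs)")
    if order not in ("increasing", "decreasing"):
        raise ValueError(f"unknown order {order!r}")
    if not (0 <= basis_class < model.n_classes):
        raise ValueError("basis_class out of range")
    w = model.W_out.copy()
    m = w.shape[1]
    if n_remove_units > m:
        raise ValueError("cannot remove more units than the model has")
    mags = np.abs(w[basis_class])
    ranking = np.lexsort((np.arange(m), mags))  # stable: ties by column index
    if order == "decreasing":
        ranking = ranking[::-1]
    removed = np.zeros(m, bool)
    n_removed = 0
    for unit in ranking:
        if n_removed >= n_remove_units:
            break
        if removed[unit]:
            continue
        pair = [unit - 1, unit] if unit % 2 else [unit, unit + 1]
        w[:, pair] = 0.0
        removed[pair] = True
        n_removed += 2
    out = ReadoutModel("ridge", model.n_classes, W_out=w, alpha=model.alpha,
                       stats=model.stats, tau_ma=model.tau_ma,
                       class_table=model.class_table)
    return out


def ablation_trace(model: ReadoutModel, X_test: np.ndarray,
                   labels_test: np.ndarray, basis_class: int,
                   order: str = "increasing", step: int = 2,
                   max_removed: int | None = None,
                   tau_ma: int = 1,
                   segment_starts: np.ndarray | None = None) -> AblationTrace:
    """Accuracy as a function of the number of ablated units.

    Sweeps removals 0, step, 2*step, ... up to M - 2 (or max_removed),
    re-evaluating the step-wise accuracy each time without retraining.
    """
    m = model.W_out.shape[1]
    stop = m - 2 if max_removed is None else max_removed
    counts = np.arange(0, stop + 1, step)
    accs = np.empty(counts.size)
    lab = np.asarray(labels_test, int)
    for i, n_rm in enumerate(counts):
        ablated = ablate_weights(model, basis_class, int(n_rm), order)
        scores = predict_scores(ablated, X_test)
        _, pred = classify(scores, tau_ma, segment_starts)
        accs[i] = accuracy(pred, lab)
    return AblationTrace(basis_class, counts, accs, order)


# ---------------------------------------------------------------------------
# leave-one-class-out generalization
# ---------------------------------------------------------------------------


@dataclass
class LocoResult:
    excluded_class: int
    retained_classes: np.ndarray
    scores: np.ndarray          # rows: excluded-class steps; cols: retained
    top_class: np.ndarray
    dominance: float            # fraction of steps whose top class shares
                                # the excluded class's wind direction


def leave_one_class_out(X: np.ndarray, labels: LabelSeries,
                        excluded_class: int, alpha: float = 1e6,
                        standardized: bool = True) -> LocoResult:
    """Train without one class; score that class's data with the rest.

    The readout is fitted (on standardized data by default) using only the
    rows of the retained classes; the excluded class's rows are then
    scored, and the dominance statistic reports how often the top-scoring
    class has the same wind direction as the excluded one (requires the
    label series' class_table).
    """
    lab = labels.labels
    if labels.n_classes < 3:
        raise ValueError("need at least 3 classes")
    if excluded_class not in np.unique(lab):
        raise ValueError(f"class {excluded_class} absent from labels")
    keep = lab != excluded_class
    retained = np.unique(lab[keep])
    assert excluded_class not in retained  # fitting must never see held-out rows
    X = np.asarray(X, float)
    X_tr, X_ex = X[keep], X[~keep]
    # compact retained-class indexing for the one-hot targets
    remap = {c: i for i, c in enumerate(retained)}
    y_tr = np.array([remap[c] for c in lab[keep]])
    model = fit_readout(X_tr, y_tr, method="ridge", alpha=alpha,
                        standardize=standardized,
                        n_classes=retained.size)
    scores = predict_scores(model, X_ex)
    top = retained[scores.argmax(axis=1)]
    table = labels.class_table
    if table:
        ex_dir = table[excluded_class][0]
        dominance = float(np.mean([table[int(c)][0] == ex_dir for c in top]))
    else:
        dominance = float("nan")
    return LocoResult(excluded_class, retained, scores, top, dominance)


# ---------------------------------------------------------------------------
# delay augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentConfig:
    tau_delay: int = 1
    d_max: int = 20
    base_units: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau_delay < 1:
            raise ValueError("tau_delay must be >= 1")
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")


def delay_augment(X: np.ndarray, cfg: AugmentConfig,
                  labels: np.ndarray | None = None
                  ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Widen X with delayed copies: X'(t) = [X(t), X(t+tau), ..., X(t+d*tau)].

    Restricted to cfg.base_units columns when given.  The last d*tau rows,
    which lack future samples, are dropped; labels (if provided) are
    trimmed to match and returned alongside.
    """
    X = np.asarray(X, float)
    if cfg.base_units is not None:
        X = X[:, np.asarray(cfg.base_units, int)]
    n = X.shape[0]
    span = cfg.d_max * cfg.tau_delay
    if n <= span:
        raise ValueError(f"series of {n} rows too short for d_max="
                         f"{cfg.d_max}, tau={cfg.tau_delay}")
    n_out = n - span
    parts = [X[d * cfg.tau_delay: d * cfg.tau_delay + n_out]
             for d in range(cfg.d_max + 1)]
    X_aug = np.concatenate(parts, axis=1)
    if labels is None:
        return X_aug
    return X_aug, np.asarray(labels)[:n_out]


@dataclass
class AugmentSweep:
    base_units: np.ndarray
    d_values: np.ndarray
    train_accuracies: np.ndarray
    test_accuracies: np.ndarray


def augment_experiment(X: np.ndarray, labels: LabelSeries | np.ndarray,
                       base_units: np.ndarray, tau_delay: int = 1,
                       d_max: int = 20, alpha: float = 1e6,
                       train_idx: np.ndarray | None = None,
                       test_idx: np.ndarray | None = None,
                       standardize: bool = False) -> AugmentSweep:
    """Ridge accuracy versus the delay-embedding depth d = 0 .. d_max.

    Delayed copies are built separately inside every contiguous recording
    segment of the train and test row sets, so no augmented row mixes
    recordings (or leaks test frames into training windows).
    """
    lab = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels, int)
    n_classes = labels.n_classes if isinstance(labels, LabelSeries) \
        else int(lab.max()) + 1
    X = np.asarray(X, float)
    if train_idx is None or test_idx is None:
        train_idx, test_idx = chronological_split(lab)

    def _segments(rows: np.ndarray) -> list[np.ndarray]:
        rows = np.asarray(rows)
        breaks = np.flatnonzero((np.diff(rows) != 1)
                                | (np.diff(lab[rows]) != 0)) + 1
        return np.split(rows, breaks)

    def _augment_rows(rows: np.ndarray, d: int):
        cfg = AugmentConfig(tau_delay, d, base_units)
        xs, ys = [], []
        for seg in _segments(rows):
            x_a, y_a = delay_augment(X[seg], cfg, lab[seg])
            xs.append(x_a)
            ys.append(y_a)
        return np.concatenate(xs), np.concatenate(ys)

    d_values = np.arange(d_max + 1)
    tr_acc = np.empty(d_values.size)
    te_acc = np.empty(d_values.size)
    for i, d in enumerate(d_values):
        X_tr, y_tr = _augment_rows(train_idx, int(d))
        X_te, y_te = _augment_rows(test_idx, int(d))
        model = fit_readout(X_tr, y_tr, method="ridge", alpha=alpha,
                            standardize=standardize, n_classes=n_classes)
        _, pred_tr = classify(predict_scores(model, X_tr), 1)
        _, pred_te = classify(predict_scores(model, X_te), 1)
        tr_acc[i] = accuracy(pred_tr, y_tr)
        te_acc[i] = accuracy(pred_te, y_te)
    return AugmentSweep(np.asarray(base_units), d_values, tr_acc, te_acc)
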