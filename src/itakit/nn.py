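"""Feed-forward neural-network cross-check of the penalized-regression path.

A fully connected network with four hidden layers is trained on the
lasso-selected features to capture non-linear structure the linear models
would miss.  Per-feature importance is measured by permutation (mean held-out
AUC drop over R shuffles of one column), the importance curve is knee-cut with
the same detector used for ridge coefficients, and the resulting selection is
compared with the ITA/ridge selection by Jaccard overlap.  A first-layer
weight-magnitude importance is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.inspection import permutation_importance
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .evaluation import auc
from .knee import CoefficientCurve, locate_knee, sort_coefficients


@dataclass
class NNConfig:
    """Feed-forward network settings: four hidden layers by default, widths
    tapering 64-32-16-8 with ReLU, Adam, early stopping on a 10% validation
    slice of the training data."""

    hidden_widths: tuple[int, ...] = (64, 32, 16, 8)
    activation: str = "relu"
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 3e-3
    patience: int = 25
    seed: int = 0
    early_stopping: bool = True
    validation_fraction: float = 0.1

    def __post_init__(self):
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("all hidden widths must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")

    @property
    def hidden_layers(self) -> int:
        return len(self.hidden_widths)

    def to_dict(self) -> dict:
        return asdict(self)


class FeedForwardValidator(ClassifierMixin, BaseEstimator):
    """Sigmoid-output feed-forward classifier on standardized inputs.

    ``epochs=0`` yields the network at (deterministic, seed-controlled)
    initialization — useful as a no-information baseline.
    """

    def __init__(self, hidden_widths=(64, 32, 16, 8), activation="relu",
                 epochs=200, batch_size=256, learning_rate=3e-3, patience=25,
                 seed=0, early_stopping=True, validation_fraction=0.1):
        self.hidden_widths = hidden_widths
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.seed = seed
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction

    def fit(self, X, y, feature_names=None):
        import copy
        import warnings as _w

        from sklearn.exceptions import ConvergenceWarning
        from sklearn.model_selection import train_test_split as _sk_split

        if hasattr(X, "columns"):
            feature_names = [str(c) for c in X.columns]
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if y.min() == y.max():
            raise ValueError("y must contain both classes")
        at_init = self.epochs == 0
        net = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_widths),
            activation=self.activation,
            solver="adam",
            # epochs=0: one vanishingly small step leaves the seeded
            # initialization effectively untouched
            learning_rate_init=1e-12 if at_init else self.learning_rate,
            max_iter=max(1, int(self.epochs)),
            batch_size=min(self.batch_size, X.shape[0]),
            random_state=self.seed,
            early_stopping=False,
            n_iter_no_change=max(1, int(self.epochs)),
        )
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        classes = np.array([0, 1])
        with _w.catch_warnings():
            _w.simplefilter("ignore", ConvergenceWarning)
            if at_init or not self.early_stopping:
                if at_init:
                    net.partial_fit(Xs, y, classes=classes)
                else:
                    net.fit(Xs, y)
                self.validation_auc_ = None
            else:
                # AUC-monitored early stopping on a stratified validation
                # slice: the rare class makes accuracy (sklearn's built-in
                # early-stopping score) flat at the majority rate, which
                # freezes training at near-initial weights
                itr, iva = _sk_split(
                    np.arange(len(y)), test_size=self.validation_fraction,
                    random_state=self.seed, stratify=y,
                )
                best, best_state, stale = -np.inf, None, 0
                for _epoch in range(int(self.epochs)):
                    net.partial_fit(Xs[itr], y[itr], classes=classes)
                    va = auc(net.predict_proba(Xs[iva])[:, 1], y[iva])
                    if va > best + 1e-4:
                        best, stale = va, 0
                        best_state = (copy.deepcopy(net.coefs_),
                                      copy.deepcopy(net.intercepts_))
                    else:
                        stale += 1
                        if stale >= self.patience:
                            break
                if best_state is not None:
                    net.coefs_, net.intercepts_ = best_state
                self.validation_auc_ = best
        if not np.isfinite(net.loss_):
            raise RuntimeError(
                f"training diverged: final loss {net.loss_!r}; "
                "lower the learning rate or standardize inputs"
            )
        self.net_ = net
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = (list(feature_names) if feature_names is not None
                               else [f"x{i}" for i in range(X.shape[1])])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        if hasattr(X, "to_numpy"):
            X = X.to_numpy()
        return self.net_.predict_proba(self.scaler_.transform(np.asarray(X, float)))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    @property
    def first_layer_weights_(self) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.coefs_[0]


def fit_feedforward(X, y, config: NNConfig | None = None,
                    feature_names=None) -> FeedForwardValidator:
    """Train the validator network on the lasso-support design matrix."""
    cfg = config or NNConfig()
    return FeedForwardValidator(
        hidden_widths=cfg.hidden_widths, activation=cfg.activation,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, patience=cfg.patience, seed=cfg.seed,
        early_stopping=cfg.early_stopping,
        validation_fraction=cfg.validation_fraction,
    ).fit(X, y, feature_names=feature_names)


@dataclass
class ImportanceResult:
    curve: CoefficientCurve  # sorted, knee located (may be None)
    raw_importance: dict[str, float]
    standard_errors: dict[str, float]
    method: str

    @property
    def selected(self) -> tuple[str, ...]:
        if self.curve.knee_index is None:
            return ()
        return self.curve.selected


def nn_importance(model: FeedForwardValidator, X, y, method: str = "permutation",
                  n_repeats: int = 10, seed: int = 0,
                  sensitivity: float = 1.0) -> ImportanceResult:
    """Per-feature importance on held-out data, knee-cut for selection.

    ``permutation`` (default): mean held-out AUC drop over ``n_repeats``
    shuffles of each column, clipped at 0.  ``weights``: mean |first-layer
    weight| per input — offered because weights are the closest analogue of a
    per-variable coefficient, but permutation is the better-defined notion for
    a deep net.
    """
    check_is_fitted(model, "net_")
    if hasattr(X, "to_numpy"):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    names = model.feature_names_
    if method == "permutation":
        if y.min() == y.max():
            raise ValueError("held-out data needs both classes for AUC scoring")
        res = permutation_importance(
            model, X, y, scoring="roc_auc", n_repeats=n_repeats,
            random_state=seed,
        )
        raw = dict(zip(names, res.importances_mean.tolist()))
        se = dict(zip(names, (res.importances_std / np.sqrt(n_repeats)).tolist()))
    elif method == "weights":
        w = np.abs(model.first_layer_weights_).mean(axis=1)
        raw = dict(zip(names, w.tolist()))
        se = {n: 0.0 for n in names}
    else:
        raise ValueError("method must be 'permutation' or 'weights'")
    clipped = {n: max(0.0, v) for n, v in raw.items()}
    curve = sort_coefficients(clipped, "absolute")
    if len(curve) >= 4:  # knee undefined on shorter curves
        curve = locate_knee(curve, sensitivity=sensitivity)
    return ImportanceResult(curve=curve, raw_importance=raw,
                            standard_errors=se, method=method)


def compare_selections(ita_selected, nn_selected) -> dict:
    """Intersection, Jaccard index and per-side exclusives of two selections."""
    a, b = set(ita_selected), set(nn_selected)
    if not a or not b:
        raise ValueError("both selections must be nonempty")
    inter = a & b
    union = a | b
    return {
        "intersection": tuple(sorted(inter)),
        "jaccard": len(inter) / len(union),
        "only_ita": tuple(sorted(a - b)),
        "only_nn": tuple(sorted(b - a)),
        "n_ita": len(a),
        "n_nn": len(b),
    }


def validate_against_ridge(matrix, seed: int = 0, nn_config: NNConfig | None = None,
                           train_fraction: float = 0.8, n_lambda: int = 16,
                           lambda_ratio: float = 1e-3, tol: float = 1e-7,
                           n_repeats: int = 20) -> dict:
    """Run the full cross-check on one design matrix.

    Pipeline: stratified train/test split → CV-tuned lasso → ridge refit on
    the lasso support with knee selection → feed-forward net on the same
    support with permutation-importance knee selection → overlap report.
    Selections are compared at the source-variable level (a category dummy
    counts as its parent variable), since the two methods routinely pick
    different levels of the same variable.
    """
    from .evaluation import split_indices
    from .penalized import PenalizedLogisticRegression, cross_validate_lambda

    tr, te = split_indices(matrix.y, train_fraction, seed, stratified=True)
    Xtr, ytr = matrix.X[tr], matrix.y[tr]
    Xte, yte = matrix.X[te], matrix.y[te]
    cv_kw = dict(k=5, seed=seed, tol=tol, n_lambda=n_lambda, ratio=lambda_ratio)

    lasso_cv = cross_validate_lambda(Xtr, ytr, "l1", **cv_kw)
    lasso = PenalizedLogisticRegression("l1", lasso_cv.lambda_star, tol=1e-8).fit(
        Xtr, ytr, feature_names=list(matrix.feature_names)
    )
    support = [matrix.feature_names[i] for i in lasso.support_]
    idx = list(lasso.support_)
    if not support:
        raise ValueError("empty lasso support: nothing for the validator to check")

    ridge_cv = cross_validate_lambda(Xtr[:, idx], ytr, "l2", **cv_kw)
    ridge = PenalizedLogisticRegression("l2", ridge_cv.lambda_star, tol=1e-9).fit(
        Xtr[:, idx], ytr, feature_names=support
    )
    ridge_curve = locate_knee(
        sort_coefficients(dict(zip(support, ridge.coef_std_)))
    )
    ridge_features = ridge_curve.selected if ridge_curve.knee_index is not None else ()

    net = fit_feedforward(Xtr[:, idx], ytr, nn_config or NNConfig(seed=seed),
                          feature_names=support)
    importance = nn_importance(net, Xte[:, idx], yte, n_repeats=n_repeats,
                               seed=seed)
    nn_features = importance.selected

    to_vars = lambda feats: tuple(sorted({matrix.source_map[f] for f in feats}))
    ridge_vars, nn_vars = to_vars(ridge_features), to_vars(nn_features)
    report = (compare_selections(ridge_vars, nn_vars)
              if ridge_vars and nn_vars else
              {"jaccard": 0.0, "intersection": (), "only_ita": ridge_vars,
               "only_nn": nn_vars, "n_ita": len(ridge_vars), "n_nn": len(nn_vars)})
    return {
        "jaccard": report["jaccard"],
        "overlap": report,
        "ridge_variables": ridge_vars,
        "nn_variables": nn_vars,
        "ridge_auc": auc(ridge.predict_proba(Xte[:, idx])[:, 1], yte),
        "nn_auc": auc(net.predict_proba(Xte[:, idx])[:, 1], yte),
        "lasso_support": tuple(support),
        "importance": importance,
    }
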