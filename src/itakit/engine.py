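"""Iterative thematic analysis (ITA).

Each iteration: cross-validated lasso reduces the active variable set to its
nonzero support; a cross-validated ridge refit on that support supplies
stable coefficient magnitudes; the sorted coefficient curve is cut at its
knee; variables above the knee are grouped by an expert-supplied theme map;
a theme is *valid* when it holds at least max(2, ceil(5% of the selected
variables)) members.  The top-scoring valid theme is then dropped — a
variable leaves the active set only when ALL of its themes have been dropped
— and the cycle repeats.  The loop stops when an iteration selects no
variable not seen before, when three consecutive iterations surface no new
theme, or when no valid theme remains to drop.  The 80/20 train/test split is
drawn once, before iteration 1, so per-round AUC/BER are comparable.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from .evaluation import EvalReport, choose_threshold, evaluate, split_indices
from .knee import CoefficientCurve, locate_knee, sort_coefficients
from .penalized import PenalizedLogisticRegression, cross_validate_lambda
from .preprocess import DesignMatrix

logger = logging.getLogger(__name__)


class ThemeMap:
    """Variable → set-of-theme-labels assignments (possibly empty, possibly
    multiple).  The machine-readable stand-in for expert thematic coding."""

    def __init__(self, assignments: Mapping[str, Iterable[str]]):
        self.assignments: dict[str, frozenset[str]] = {}
        for var, labels in assignments.items():
            labels = frozenset(str(l) for l in labels)
            if any(not l for l in labels):
                raise ValueError(f"{var}: theme labels must be nonempty strings")
            self.assignments[str(var)] = labels

    def themes_of(self, var: str) -> frozenset[str]:
        if var not in self.assignments:
            raise KeyError(f"variable {var!r} not in theme map")
        return self.assignments[var]

    def members_of(self, theme: str) -> tuple[str, ...]:
        return tuple(v for v, ts in self.assignments.items() if theme in ts)

    @property
    def all_labels(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.assignments.values():
            out |= ts
        return frozenset(out)

    @classmethod
    def from_file(cls, path) -> "ThemeMap":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(data)

    def to_dict(self) -> dict:
        return {v: sorted(ts) for v, ts in self.assignments.items()}


def identify_themes(selected: Sequence[str], theme_map: ThemeMap,
                    min_fraction: float = 0.05, min_count: int = 2,
                    ) -> tuple[dict[str, tuple[str, ...]], tuple[str, ...]]:
    """Valid themes among the selected variables, plus the unthemed leftovers.

    A theme is valid iff its selected-member count reaches
    max(min_count, ceil(min_fraction · |selected|)).  Selected variables with
    no theme (or absent from the map) are reported individually as unthemed —
    never silently dropped.
    """
    selected = list(dict.fromkeys(selected))  # dedupe, keep order
    if not selected:
        warnings.warn("empty selection: no themes to identify", UserWarning)
        return {}, ()
    unknown = [v for v in selected if v not in theme_map.assignments]
    if unknown:
        warnings.warn(
            f"{len(unknown)} selected variable(s) absent from theme map, "
            f"treated as unthemed: {unknown[:5]}",
            UserWarning,
        )
    members: dict[str, list[str]] = {}
    unthemed: list[str] = []
    for v in selected:
        themes = theme_map.assignments.get(v, frozenset())
        if not themes:
            unthemed.append(v)
        for t in sorted(themes):
            members.setdefault(t, []).append(v)
    need = max(min_count, math.ceil(min_fraction * len(selected)))
    valid = {t: tuple(vs) for t, vs in sorted(members.items()) if len(vs) >= need}
    return valid, tuple(unthemed)


def theme_score(theme: str, curve: CoefficientCurve,
                members: Sequence[str],
                source_map: Mapping[str, str] | None = None,
                mode: str = "max") -> float:
    """Importance score of a theme from its members' coefficient magnitudes.

    Each member variable scores the largest |coefficient| among its features
    on the curve; the theme aggregates member scores by ``mode`` ("max"
    default, "mean" and "variance" available).
    """
    if not members:
        raise ValueError(f"theme {theme!r} has no members to score")
    mags: dict[str, float] = {}
    for name, signed in zip(curve.names,
                            curve.signed_values if curve.signed_values is not None
                            else curve.values):
        var = source_map[name] if source_map and name in source_map else name
        mags[var] = max(mags.get(var, 0.0), abs(float(signed)))
    member_scores = [mags.get(v, 0.0) for v in members]
    if mode == "max":
        return float(max(member_scores))
    if mode == "mean":
        return float(np.mean(member_scores))
    if mode == "variance":
        return float(np.var(member_scores))
    raise ValueError("mode must be 'max', 'mean' or 'variance'")


def drop_theme(active: Sequence[str], theme: str, theme_map: ThemeMap,
               dropped: Iterable[str] = ()) -> tuple[str, ...]:
    """Remove the dropped theme's variables whose every theme is now dropped.

    A variable belonging to several themes survives until its last theme
    falls; variables outside the dropped theme (including unthemed ones) are
    untouched.
    """
    if theme not in theme_map.all_labels:
        raise KeyError(f"unknown theme {theme!r}")
    dropped_all = set(dropped) | {theme}
    out = []
    for v in active:
        themes = theme_map.assignments.get(v, frozenset())
        if theme in themes and themes <= dropped_all:
            continue
        out.append(v)
    return tuple(out)


@dataclass
class ITAConfig:
    """Run configuration for the ITA loop.

    The λ path defaults (16 points down from λ_max by factor 10³) and solver
    tolerance are the engine's computational defaults; the standalone
    cross-validation helper defaults to the finer 50-point/10⁴ path.
    """

    min_fraction: float = 0.05
    min_count: int = 2
    score_mode: str = "max"
    ranking_mode: str = "absolute"
    sensitivity: float = 1.0
    cv_folds: int = 5
    n_lambda: int = 16
    lambda_ratio: float = 1e-3
    train_fraction: float = 0.8
    threshold_mode: str = "balanced"
    tol: float = 1e-7
    max_iter: int = 100
    seed: int = 0
    max_iterations: int | None = None  # default: |themes| + 3

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ITAIteration:
    iteration_number: int
    active_variables: tuple[str, ...]
    lasso_lambda: float
    lasso_support: tuple[str, ...]  # feature (dummy) names
    ridge_lambda: float | None
    curve: CoefficientCurve | None
    selected: tuple[str, ...]  # feature names above the knee
    selected_variables: tuple[str, ...]  # source variables above the knee
    valid_themes: dict[str, tuple[str, ...]]
    new_themes: tuple[str, ...]
    new_variables: tuple[str, ...]
    unthemed: tuple[str, ...]
    dropped_theme: str | None
    metrics: EvalReport | None

    def to_dict(self) -> dict:
        return {
            "iteration_number": self.iteration_number,
            "active_variables": list(self.active_variables),
            "lasso_lambda": self.lasso_lambda,
            "lasso_support": list(self.lasso_support),
            "ridge_lambda": self.ridge_lambda,
            "curve": None if self.curve is None else {
                "names": list(self.curve.names),
                "values": self.curve.values.tolist(),
                "knee_index": self.curve.knee_index,
            },
            "selected": list(self.selected),
            "selected_variables": list(self.selected_variables),
            "valid_themes": {t: list(m) for t, m in self.valid_themes.items()},
            "new_themes": list(self.new_themes),
            "new_variables": list(self.new_variables),
            "unthemed": list(self.unthemed),
            "dropped_theme": self.dropped_theme,
            "metrics": None if self.metrics is None else self.metrics.to_dict(),
        }


STOP_REASONS = ("no_new_variables", "no_new_themes_3x", "exhausted")


@dataclass
class ITAResult:
    iterations: list[ITAIteration]
    all_themes: tuple[str, ...]  # union of valid themes, discovery order
    stop_reason: str
    config: ITAConfig

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def theme_discovery_order(self) -> tuple[str, ...]:
        return self.all_themes

    def to_dict(self) -> dict:
        return {
            "iterations": [it.to_dict() for it in self.iterations],
            "all_themes": list(self.all_themes),
            "stop_reason": self.stop_reason,
            "config": self.config.to_dict(),
        }

    def report_table(self) -> str:
        """Human-readable themes × member-variables table."""
        lines = []
        seen: dict[str, tuple[str, ...]] = {}
        for it in self.iterations:
            for t, m in it.valid_themes.items():
                seen.setdefault(t, m)
        for t in self.all_themes:
            lines.append(f"{t}:")
            for i, v in enumerate(seen.get(t, ()), 1):
                lines.append(f"  {i}. {v}")
        unthemed = [v for it in self.iterations for v in it.unthemed]
        if unthemed:
            lines.append("(unthemed):")
            for v in dict.fromkeys(unthemed):
                lines.append(f"  - {v}")
        return "\n".join(lines)


def _iterate_once(train: DesignMatrix, test: DesignMatrix,
                  active: tuple[str, ...], theme_map: ThemeMap,
                  cfg: ITAConfig, iteration_number: int,
                  ) -> ITAIteration:
    """One lasso → ridge → knee → themes pass on a fixed active set."""
    feats = train.features_of(active)
    Xtr = train.restrict(feats)
    cv_kwargs = dict(k=cfg.cv_folds, seed=cfg.seed, tol=cfg.tol,
                     max_iter=cfg.max_iter, n_lambda=cfg.n_lambda,
                     ratio=cfg.lambda_ratio)
    lasso_cv = cross_validate_lambda(Xtr.X, Xtr.y, "l1", **cv_kwargs)
    lasso = PenalizedLogisticRegression(
        penalty="l1", lam=lasso_cv.lambda_star, tol=cfg.tol,
        max_iter=cfg.max_iter, random_state=cfg.seed,
    ).fit(Xtr.X, Xtr.y, feature_names=list(Xtr.feature_names))
    support = tuple(Xtr.feature_names[i] for i in lasso.support_)

    base = dict(
        iteration_number=iteration_number, active_variables=active,
        lasso_lambda=float(lasso_cv.lambda_star), lasso_support=support,
        ridge_lambda=None, curve=None, selected=(), selected_variables=(),
        valid_themes={}, new_themes=(), new_variables=(), unthemed=(),
        dropped_theme=None, metrics=None,
    )
    if not support:
        logger.info("iteration %d: empty lasso support", iteration_number)
        return ITAIteration(**base)

    Xsup = Xtr.restrict(support)
    ridge_cv = cross_validate_lambda(Xsup.X, Xsup.y, "l2", **cv_kwargs)
    ridge = PenalizedLogisticRegression(
        penalty="l2", lam=ridge_cv.lambda_star, tol=cfg.tol,
        max_iter=cfg.max_iter, random_state=cfg.seed,
    ).fit(Xsup.X, Xsup.y, feature_names=list(Xsup.feature_names))

    # rank on the standardized (scale-free) coefficients the penalty acts on
    curve = sort_coefficients(dict(zip(Xsup.feature_names, ridge.coef_std_)),
                              cfg.ranking_mode)
    if len(curve) >= 4:
        curve = locate_knee(curve, sensitivity=cfg.sensitivity)
    else:  # too few points for a knee: selection is refused
        logger.info("iteration %d: support of %d features is too small for "
                    "knee detection", iteration_number, len(curve))
    test_sup = test.restrict(support)
    scores_tr = ridge.predict_proba(Xsup.X)[:, 1]
    scores_te = ridge.predict_proba(test_sup.X)[:, 1]
    thr = choose_threshold(scores_tr, Xsup.y, mode=cfg.threshold_mode)
    metrics = evaluate(scores_te, test_sup.y, threshold=thr, n_train=Xsup.n)

    base.update(ridge_lambda=float(ridge_cv.lambda_star), curve=curve,
                metrics=metrics)
    if curve.knee_index is None:
        logger.info("iteration %d: no knee on the coefficient curve",
                    iteration_number)
        return ITAIteration(**base)

    selected = curve.selected
    selected_vars = tuple(dict.fromkeys(train.source_map[f] for f in selected))
    valid, unthemed = identify_themes(
        selected_vars, theme_map, cfg.min_fraction, cfg.min_count
    )
    base.update(selected=selected, selected_variables=selected_vars,
                valid_themes=valid, unthemed=unthemed)
    return ITAIteration(**base)


def _order_by_score(themes, iteration: ITAIteration, matrix: DesignMatrix,
                    cfg: ITAConfig) -> tuple[str, ...]:
    """Importance order for themes surfacing in the same iteration."""
    if not themes or iteration.curve is None:
        return tuple(themes)
    return tuple(sorted(
        themes,
        key=lambda t: (
            -theme_score(t, iteration.curve, iteration.valid_themes[t],
                         matrix.source_map, cfg.score_mode),
            t,
        ),
    ))


def _pick_drop(iteration: ITAIteration, dropped: set[str],
               source_map: Mapping[str, str], cfg: ITAConfig) -> str | None:
    droppable = [t for t in iteration.valid_themes if t not in dropped]
    if not droppable or iteration.curve is None:
        return None
    scored = sorted(
        droppable,
        key=lambda t: (
            -theme_score(t, iteration.curve, iteration.valid_themes[t],
                         source_map, cfg.score_mode),
            -len(iteration.valid_themes[t]),
            t,
        ),
    )
    return scored[0]


def run_ita(matrix: DesignMatrix, theme_map: ThemeMap,
            config: ITAConfig | None = None) -> ITAResult:
    """Run the full ITA loop on a design matrix.  See the module docstring."""
    cfg = config or ITAConfig()
    if matrix.y.min() == matrix.y.max():
        raise ValueError("outcome must contain both classes")
    tr_idx, te_idx = split_indices(matrix.y, cfg.train_fraction, cfg.seed,
                                   stratified=True)
    train, test = matrix.take_rows(tr_idx), matrix.take_rows(te_idx)

    n_distinct = len(theme_map.all_labels)
    cap = cfg.max_iterations or (n_distinct + 3)

    active: tuple[str, ...] = matrix.sources
    dropped: set[str] = set()
    seen_vars: set[str] = set()
    discovery: dict[str, None] = {}
    no_new_theme_streak = 0
    iterations: list[ITAIteration] = []
    stop_reason = "exhausted"

    for i in range(1, cap + 1):
        it = _iterate_once(train, test, active, theme_map, cfg, i)
        it.new_variables = tuple(v for v in it.selected_variables
                                 if v not in seen_vars)
        it.new_themes = _order_by_score(
            [t for t in it.valid_themes if t not in discovery], it, matrix, cfg
        )
        for t in it.new_themes:
            discovery[t] = None
        seen_vars |= set(it.selected_variables)
        iterations.append(it)

        # stopping is checked before any theme drop
        if not it.new_variables:
            stop_reason = "no_new_variables"
            break
        no_new_theme_streak = 0 if it.new_themes else no_new_theme_streak + 1
        if no_new_theme_streak >= 3:
            stop_reason = "no_new_themes_3x"
            break
        choice = _pick_drop(it, dropped, matrix.source_map, cfg)
        if choice is None:
            stop_reason = "exhausted"
            break
        it.dropped_theme = choice
        dropped.add(choice)
        active = drop_theme(active, choice, theme_map, dropped)
        logger.info("iteration %d: dropped theme %r (%d variables remain)",
                    i, choice, len(active))
    return ITAResult(iterations=iterations, all_themes=tuple(discovery),
                     stop_reason=stop_reason, config=cfg)


def replay_trace(matrix: DesignMatrix, theme_map: ThemeMap,
                 result: ITAResult) -> ITAResult:
    """Re-execute a logged run from its per-iteration active sets and drops.

    Every model fit is recomputed from scratch; only the logged active sets
    and dropped themes steer the replay.  With deterministic solvers the
    replayed trace is identical to the original."""
    cfg = result.config
    tr_idx, te_idx = split_indices(matrix.y, cfg.train_fraction, cfg.seed,
                                   stratified=True)
    train, test = matrix.take_rows(tr_idx), matrix.take_rows(te_idx)
    seen_vars: set[str] = set()
    discovery: dict[str, None] = {}
    iterations = []
    for logged in result.iterations:
        it = _iterate_once(train, test, logged.active_variables, theme_map,
                           cfg, logged.iteration_number)
        it.new_variables = tuple(v for v in it.selected_variables
                                 if v not in seen_vars)
        it.new_themes = _order_by_score(
            [t for t in it.valid_themes if t not in discovery], it, matrix, cfg
        )
        for t in it.new_themes:
            discovery[t] = None
        seen_vars |= set(it.selected_variables)
        it.dropped_theme = logged.dropped_theme
        iterations.append(it)
    return ITAResult(iterations=iterations, all_themes=tuple(discovery),
                     stop_reason=result.stop_reason, config=cfg)


class IterativeThematicAnalysis(BaseEstimator):
    """Estimator façade over :func:`run_ita`.

    ``fit(X, y)`` accepts a DataFrame whose columns follow the
    ``"variable=category"`` dummy naming (source variables are inferred), or
    any array plus explicit ``feature_names``/``source_map``.  Fitted
    attributes: ``result_``, ``themes_``, ``selected_variables_``,
    ``n_iterations_``, ``stop_reason_``.
    """

    def __init__(self, theme_map=None, min_fraction: float = 0.05,
                 min_count: int = 2, score_mode: str = "max",
                 ranking_mode: str = "absolute", sensitivity: float = 1.0,
                 cv_folds: int = 5, n_lambda: int = 16,
                 lambda_ratio: float = 1e-3, train_fraction: float = 0.8,
                 threshold_mode: str = "balanced", tol: float = 1e-7,
                 max_iter: int = 100, seed: int = 0,
                 max_iterations: int | None = None):
        self.theme_map = theme_map
        self.min_fraction = min_fraction
        self.min_count = min_count
        self.score_mode = score_mode
        self.ranking_mode = ranking_mode
        self.sensitivity = sensitivity
        self.cv_folds = cv_folds
        self.n_lambda = n_lambda
        self.lambda_ratio = lambda_ratio
        self.train_fraction = train_fraction
        self.threshold_mode = threshold_mode
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.max_iterations = max_iterations

    def _config(self) -> ITAConfig:
        return ITAConfig(
            min_fraction=self.min_fraction, min_count=self.min_count,
            score_mode=self.score_mode, ranking_mode=self.ranking_mode,
            sensitivity=self.sensitivity, cv_folds=self.cv_folds,
            n_lambda=self.n_lambda, lambda_ratio=self.lambda_ratio,
            train_fraction=self.train_fraction,
            threshold_mode=self.threshold_mode, tol=self.tol,
            max_iter=self.max_iter, seed=self.seed,
            max_iterations=self.max_iterations,
        )

    def fit(self, X, y=None, feature_names=None, source_map=None):
        if isinstance(X, DesignMatrix):
            matrix = X
        else:
            if hasattr(X, "columns"):
                feature_names = [str(c) for c in X.columns]
                X = X.to_numpy()
            if feature_names is None:
                raise ValueError("feature_names required for array input")
            if source_map is None:
                source_map = {f: f.split("=", 1)[0] for f in feature_names}
            matrix = DesignMatrix(np.asarray(X, dtype=float), y,
                                  tuple(feature_names), dict(source_map))
        tm = self.theme_map
        if tm is None:
            raise ValueError("theme_map is required")
        if not isinstance(tm, ThemeMap):
            tm = ThemeMap(tm)
        self.result_ = run_ita(matrix, tm, self._config())
        self.themes_ = self.result_.all_themes
        self.stop_reason_ = self.result_.stop_reason
        self.n_iterations_ = self.result_.n_iterations
        sel: dict[str, None] = {}
        for it in self.result_.iterations:
            for v in it.selected_variables:
                sel.setdefault(v, None)
        self.selected_variables_ = tuple(sel)
        return self
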