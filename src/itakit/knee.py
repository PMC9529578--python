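"""Knee-point selection on sorted coefficient curves.

Penalized-regression coefficients sorted from high to low trace a curve that
falls steeply over the informative features and then flattens over the bulk of
near-zero ones.  The point of maximum curvature of that curve — the *knee* —
is used as the selection cutoff instead of p-values, which are anti-conservative
in penalized high-dimensional fits.  The detector is the Kneedle procedure:
min–max normalize both axes, take the difference between the (flipped)
normalized curve and the diagonal, and report the first significant local
maximum of that difference curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

RANKING_MODES = ("absolute", "signed")


@dataclass
class CoefficientCurve:
    """Coefficients sorted descending by the ranking key, with optional knee.

    ``values`` holds the ranking key (magnitudes in ``absolute`` mode, raw
    signed coefficients in ``signed`` mode) and is nonincreasing.
    ``signed_values`` always holds the raw signed coefficient in curve order.
    """

    values: np.ndarray
    names: tuple[str, ...]
    ranking_mode: str = "absolute"
    knee_index: int | None = None
    signed_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.names = tuple(self.names)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("values and names must be 1-d and of equal length")
        if len(self.values) == 0:
            raise ValueError("empty coefficient curve")
        if self.ranking_mode not in RANKING_MODES:
            raise ValueError(f"ranking_mode must be one of {RANKING_MODES}")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("curve values must be nonincreasing")
        if self.signed_values is not None:
            self.signed_values = np.asarray(self.signed_values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def knee_value(self) -> float:
        if self.knee_index is None:
            raise ValueError("knee_index is not set on this curve")
        return float(self.values[self.knee_index])

    @property
    def selected(self) -> tuple[str, ...]:
        """Names with ranking value strictly above the knee value.

        A strict prefix of ``names``: ties exactly at the knee value are
        excluded ("higher than the knee point" is read strictly).
        """
        knee_value = self.knee_value  # raises if knee unset
        mask = self.values > knee_value
        return tuple(np.asarray(self.names, dtype=object)[mask])

    def to_frame(self):
        import pandas as pd

        sel: set[str] = set(self.selected) if self.knee_index is not None else set()
        return pd.DataFrame(
            {
                "rank": np.arange(len(self)),
                "name": list(self.names),
                "value": self.values,
                "signed_value": (
                    self.signed_values if self.signed_values is not None else self.values
                ),
                "selected": [n in sel for n in self.names],
            }
        )


def sort_coefficients(
    coefficients: Mapping[str, float] | Sequence[tuple[str, float]],
    ranking_mode: str = "absolute",
) -> CoefficientCurve:
    """Sort named coefficients high-to-low into a :class:`CoefficientCurve`.

    ``absolute`` mode ranks by magnitude (so strong protective effects rank
    high); ``signed`` mode ranks by the raw coefficient.  Ties are broken by
    feature name (lexicographic) so the order is deterministic.
    """
    if hasattr(coefficients, "items"):
        items = list(coefficients.items())  # type: ignore[union-attr]
    else:
        items = list(coefficients)
    if not items:
        raise ValueError("no coefficients to sort")
    if ranking_mode not in RANKING_MODES:
        raise ValueError(f"ranking_mode must be one of {RANKING_MODES}")
    key = (lambda nv: (-abs(nv[1]), nv[0])) if ranking_mode == "absolute" else (
        lambda nv: (-nv[1], nv[0])
    )
    items.sort(key=key)
    names = tuple(n for n, _ in items)
    signed = np.array([v for _, v in items], dtype=float)
    values = np.abs(signed) if ranking_mode == "absolute" else signed.copy()
    return CoefficientCurve(
        values=values, names=names, ranking_mode=ranking_mode, signed_values=signed
    )


def find_knee(curve: CoefficientCurve, sensitivity: float = 1.0,
              smooth: bool = True) -> int | None:
    """Locate the point of maximum curvature of a nonincreasing curve.

    Kneedle for a decreasing curve flattening rightward: lightly smooth and
    normalize the curve, flip y so it becomes concave-increasing, and form
    the difference d(i) = (1 - y_norm(i)) - x_norm(i).  Candidate knees are the
    interior local maxima of d; a candidate is confirmed when d subsequently
    drops below its value minus ``sensitivity`` times the mean x-spacing.
    Returns the 0-based index, or ``None`` when the curve has no significant
    knee (e.g. perfectly linear descent).

    Smoothing (centered moving average, window 5% of the curve length, only
    applied from 8 points up) is the Kneedle procedure's own first step:
    sampled coefficient curves generically contain near-tie plateaus whose
    difference-curve wiggles would otherwise be confirmed as spurious early
    knees.
    """
    v = np.asarray(curve.values, dtype=float)
    n = len(v)
    if n < 4:
        raise ValueError("need at least 4 points to locate a knee")
    span = v[0] - v[-1]
    if span <= 0:  # flat (all-equal) curve: zero curvature everywhere
        return None
    x = np.linspace(0.0, 1.0, n)
    y = (v - v[-1]) / span  # 1 -> 0, nonincreasing
    if smooth and n >= 8:
        w = max(3, int(round(0.05 * n)) | 1)
        pad = w // 2
        ypad = np.r_[y[pad:0:-1], y, y[-2:-pad - 2:-1]]  # reflect edges
        y = np.convolve(ypad, np.ones(w) / w, mode="valid")
        y = (y - y[-1]) / (y[0] - y[-1])  # re-normalize after averaging
    d = (1.0 - y) - x

    spacing = 1.0 / (n - 1)
    maxima = [
        i
        for i in range(1, n - 1)
        if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    for pos, lmx in enumerate(maxima):
        threshold = d[lmx] - sensitivity * spacing
        stop = maxima[pos + 1] if pos + 1 < len(maxima) else n
        for j in range(lmx + 1, stop):
            if d[j] < threshold:
                return lmx
        # difference never dropped below threshold before the next candidate
        if stop == n and d[-1] < threshold:
            return lmx
    return None


def locate_knee(curve: CoefficientCurve, sensitivity: float = 1.0) -> CoefficientCurve:
    """Return the same curve with ``knee_index`` filled in (or left None)."""
    curve.knee_index = find_knee(curve, sensitivity=sensitivity)
    if curve.knee_index is None:
        logger.info("no knee detected on %d-point curve", len(curve))
    return curve


def select_above_knee(curve: CoefficientCurve) -> tuple[str, ...]:
    """Names of features strictly above the knee value.

    Raises if the knee is unset; for degenerate curves (no knee) the caller
    must decide — typically by stopping the enclosing iteration.
    """
    if curve.knee_index is None:
        raise ValueError(
            "knee_index is not set; run find_knee first (a curve with no knee "
            "supports no selection)"
        )
    selected = curve.selected
    logger.info(
        "knee at rank %d (value %.6g): %d features selected",
        curve.knee_index,
        curve.knee_value,
        len(selected),
    )
    return selected


class KneeThresholdSelector(SelectorMixin, BaseEstimator):
    """Feature selector keeping coefficients above the knee of a fitted model.

    Fits ``estimator`` (any linear model exposing ``coef_``), sorts its
    coefficients, finds the knee, and keeps features strictly above it.
    Composes with sklearn pipelines.
    """

    def __init__(self, estimator=None, ranking_mode: str = "absolute",
                 sensitivity: float = 1.0):
        self.estimator = estimator
        self.ranking_mode = ranking_mode
        self.sensitivity = sensitivity

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        from .penalized import PenalizedLogisticRegression

        est = self.estimator
        est = clone(est) if est is not None else PenalizedLogisticRegression(penalty="l2", lam=1.0)
        est.fit(X, y)
        coef = np.ravel(est.coef_)
        if feature_names is None:
            feature_names = getattr(est, "feature_names_", None)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(len(coef))]
        self.estimator_ = est
        self.curve_ = locate_knee(
            sort_coefficients(dict(zip(feature_names, coef)), self.ranking_mode),
            sensitivity=self.sensitivity,
        )
        self.knee_index_ = self.curve_.knee_index
        names = list(feature_names)
        selected = set(self.curve_.selected) if self.knee_index_ is not None else set()
        self.support_mask_ = np.array([n in selected for n in names])
        self.n_features_in_ = len(names)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
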