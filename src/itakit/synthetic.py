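"""DHS-style synthetic survey generator with planted theme structure.

Emulates the statistical shape of a large household-survey recode file:
thousands of respondents, blocks of correlated categorical questions
(questionnaire modules = themes), redundant duplicate encodings, pure-noise
questions, and a rare binary outcome driven by a sparse logistic model whose
nonzero effects cluster inside the planted themes.

Mechanism: each theme j has one latent standard-normal factor f_j; variable k
of the theme observes z = sqrt(rho)·f_j + sqrt(1−rho)·eps and is cut into
equiprobable categories at standard-normal quantiles, so dummies within a
theme are block-correlated like the items of a real questionnaire module.
The outcome's log-odds put weight theme_effects[j] on the top category of
every variable in theme j; the intercept is calibrated by bisection so the
mean of the realized per-respondent probabilities equals the target
prevalence.  Noise variables are independent draws with exactly zero effect
and are grouped into pseudo-themes in the theme map so downstream theme
recovery can be scored against false positives.  Redundant variables are
deterministic coarsenings (category merges) of a parent variable, mirroring
age carried both continuous and binned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .preprocess import VariableCatalog, CatalogEntry

OUTCOME_NAME = "outcome"


class InvalidConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator settings.  Defaults are the package's study conditions:

    20,000 respondents; 8 themes × 5 four-category variables with per-theme
    log-odds effects spaced 1.0 down to 0.5 on the top category; 50 noise
    variables (200 noise dummies); 5 redundant recodings; within-theme latent
    correlation 0.6; outcome prevalence 2%.
    """

    n_respondents: int = 20_000
    n_themes: int = 8
    vars_per_theme: int = 5
    categories_per_var: int = 4
    n_noise_vars: int = 50
    n_redundant_vars: int = 5
    theme_effects: tuple[float, ...] | None = None
    within_theme_correlation: float = 0.6
    target_prevalence: float = 0.02
    seed: int = 0
    noise_theme_size: int = 5  # 0 = leave noise variables unthemed

    def __post_init__(self):
        if self.theme_effects is None:
            self.theme_effects = tuple(
                np.linspace(1.0, 0.5, self.n_themes)
            ) if self.n_themes > 0 else ()
        self.theme_effects = tuple(float(e) for e in self.theme_effects)
        if self.n_respondents <= 0 or self.n_themes <= 0 or self.vars_per_theme <= 0:
            raise InvalidConfigError("counts must be positive")
        if self.categories_per_var < 2:
            raise InvalidConfigError("categories_per_var must be >= 2")
        if self.n_noise_vars < 0 or self.n_redundant_vars < 0:
            raise InvalidConfigError("noise/redundant counts must be nonnegative")
        if len(self.theme_effects) != self.n_themes:
            raise InvalidConfigError("theme_effects length must equal n_themes")
        if not all(np.isfinite(self.theme_effects)):
            raise InvalidConfigError("theme_effects must be finite")
        if not 0.0 <= self.within_theme_correlation < 1.0:
            raise InvalidConfigError("within_theme_correlation must be in [0, 1)")
        if not 0.0 < self.target_prevalence < 0.5:
            raise InvalidConfigError("target_prevalence must be in (0, 0.5)")
        if self.n_redundant_vars > self.n_themes * self.vars_per_theme:
            raise InvalidConfigError("more redundant variables than parents")

    @property
    def n_raw_variables(self) -> int:
        return (self.n_themes * self.vars_per_theme + self.n_noise_vars
                + self.n_redundant_vars)


@dataclass
class SyntheticSurvey:
    table: pd.DataFrame  # respondent × raw-variable categorical table
    outcome: np.ndarray  # binary, 1 = user
    true_theta: dict[str, float]  # dummy-level name -> log-odds effect
    true_theme_map: dict[str, tuple[str, ...]]  # variable -> theme labels
    intercept: float
    linear_predictor: np.ndarray  # eta without intercept, for oracle checks
    config: SyntheticConfig


def _categorize(z: np.ndarray, k: int) -> np.ndarray:
    """Cut a standard-normal column at its population quantiles into
    equiprobable categories c0..c{k-1}."""
    cuts = norm.ppf(np.arange(1, k) / k)
    return np.searchsorted(cuts, z)


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-6) -> float:
    """Bisection on b so that mean(sigmoid(b + eta)) = target."""
    if not np.isfinite(eta).all():
        raise InvalidConfigError("non-finite linear predictor; cannot calibrate")
    lo, hi = -60.0, 60.0
    f = lambda b: float(expit(b + eta).mean()) - target
    if f(lo) > 0 or f(hi) < 0:
        raise InvalidConfigError("prevalence target unreachable")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survey(config: SyntheticConfig) -> SyntheticSurvey:
    """Deterministic (per seed) synthetic survey with known ground truth."""
    k = config.categories_per_var
    rho = config.within_theme_correlation
    n = config.n_respondents
    # one independent stream per generation component
    ss = np.random.SeedSequence(config.seed)
    rng_theme, rng_noise, rng_outcome = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    columns: dict[str, np.ndarray] = {}
    true_theta: dict[str, float] = {}
    theme_map: dict[str, tuple[str, ...]] = {}
    eta = np.zeros(n)
    top = f"c{k - 1}"

    theme_var_names: list[str] = []
    for j in range(config.n_themes):
        label = f"theme_{j + 1}"
        factor = rng_theme.standard_normal(n)
        for v in range(config.vars_per_theme):
            name = f"t{j + 1}_v{v + 1}"
            z = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * rng_theme.standard_normal(n)
            codes = _categorize(z, k)
            columns[name] = codes
            theme_map[name] = (label,)
            effect = config.theme_effects[j]
            true_theta[f"{name}={top}"] = effect
            eta += effect * (codes == k - 1)
            theme_var_names.append(name)

    for m in range(config.n_noise_vars):
        name = f"noise_v{m + 1}"
        columns[name] = _categorize(rng_noise.standard_normal(n), k)
        if config.noise_theme_size > 0:
            theme_map[name] = (f"noise_{m // config.noise_theme_size + 1}",)
        else:
            theme_map[name] = ()

    redundant_parents: dict[str, str] = {}
    for r in range(config.n_redundant_vars):
        parent = theme_var_names[r % len(theme_var_names)]
        name = f"red{r + 1}_{parent}"
        # coarsened recode: merge adjacent category pairs
        columns[name] = columns[parent] // 2
        theme_map[name] = theme_map[parent]
        redundant_parents[name] = parent

    intercept = _calibrate_intercept(eta, config.target_prevalence)
    outcome = rng_outcome.binomial(1, expit(intercept + eta)).astype(int)

    table = pd.DataFrame(
        {name: pd.Series([f"c{c}" for c in codes], dtype=object)
         for name, codes in columns.items()}
    )
    survey = SyntheticSurvey(
        table=table,
        outcome=outcome,
        true_theta=true_theta,
        true_theme_map=theme_map,
        intercept=intercept,
        linear_predictor=eta,
        config=config,
    )
    survey.redundant_parents = redundant_parents  # type: ignore[attr-defined]
    return survey


def planted_themes(config: SyntheticConfig) -> tuple[str, ...]:
    return tuple(f"theme_{j + 1}" for j in range(config.n_themes))


def default_catalog(survey: SyntheticSurvey) -> VariableCatalog:
    entries = [CatalogEntry(name=OUTCOME_NAME, role="outcome", kind="continuous")]
    redundant = getattr(survey, "redundant_parents", {})
    for name in survey.table.columns:
        role = "redundant" if name in redundant else "analysis"
        entries.append(CatalogEntry(name=name, role=role, kind="categorical"))
    return VariableCatalog(entries)


def write_fixtures(survey: SyntheticSurvey, path) -> dict[str, Path]:
    """Emit the CSV table (outcome column included), variable catalog,
    theme map and ground truth in the formats the pipeline reads."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table = survey.table.copy()
    table[OUTCOME_NAME] = survey.outcome
    files = {
        "table": path / "table.csv",
        "catalog": path / "catalog.yaml",
        "themes": path / "themes.yaml",
        "truth": path / "truth.json",
    }
    table.to_csv(files["table"], index=False)
    files["catalog"].write_text(
        yaml.safe_dump(default_catalog(survey).to_dict(), sort_keys=False)
    )
    files["themes"].write_text(
        yaml.safe_dump(
            {var: list(themes) for var, themes in survey.true_theme_map.items()},
            sort_keys=True,
        )
    )
    files["truth"].write_text(json.dumps(
        {
            "true_theta": survey.true_theta,
            "intercept": survey.intercept,
            "seed": survey.config.seed,
        },
        indent=2,
        sort_keys=True,
    ))
    return files


def read_fixtures(path) -> tuple[pd.DataFrame, VariableCatalog, dict]:
    path = Path(path)
    table = pd.read_csv(path / "table.csv", dtype=object)
    table[OUTCOME_NAME] = table[OUTCOME_NAME].astype(int)
    catalog = VariableCatalog.from_file(path / "catalog.yaml")
    themes = yaml.safe_load((path / "themes.yaml").read_text())
    return table, catalog, themes


def staged_discovery_matrix(seed: int = 3, n: int = 8000, rho: float = 0.95):
    """Design matrix + theme map engineered for staged theme discovery.

    One dominant theme (A, three variables) drives the outcome together with
    themes B, C, D.  Themes E, F, G and one unthemed variable are built as
    noisy copies (correlation ``rho``) of A's variables with no direct effect:
    while A is active the lasso prunes them, and only after A is dropped do
    they inherit its signal and surface above the knee.  Under the default
    pipeline settings the run discovers A-D in iteration 1, E-G plus the
    unthemed variable in iteration 2, and stops in iteration 3 with no new
    variables — seven themes in total.

    Returns ``(DesignMatrix, ThemeMap)``.  The default seed is part of the
    fixture definition: the staging relies on sampling-dependent knee
    positions, so a different seed may discover the proxy themes in a
    different pattern.
    """
    from .engine import ThemeMap

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    effects = {"a1": 1.5, "a2": 1.4, "a3": 1.3, "b1": 1.15, "b2": 1.05,
               "c1": 0.95, "c2": 0.9, "d1": 0.8, "d2": 0.75}
    for v in effects:
        cols[v] = rng.standard_normal(n)

    def proxy(parent: str) -> np.ndarray:
        return rho * cols[parent] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)

    cols["e1"], cols["e2"] = proxy("a1"), proxy("a2")
    cols["f1"], cols["f2"] = proxy("a3"), proxy("a1")
    cols["g1"], cols["g2"] = proxy("a2"), proxy("a3")
    cols["tv_access"] = proxy("a2")
    for i in range(20):
        cols[f"z{i + 1}"] = rng.standard_normal(n)

    eta = sum(e * cols[v] for v, e in effects.items())
    y = rng.binomial(1, expit(eta - 4.5))
    names = tuple(cols)
    from .preprocess import DesignMatrix

    matrix = DesignMatrix(np.column_stack([cols[k] for k in names]), y,
                          names, {k: k for k in names})
    theme_map = ThemeMap({
        "a1": ["A"], "a2": ["A"], "a3": ["A"],
        **{f"{t}{i + 1}": [t.upper()] for t in "bcdefg" for i in range(2)},
        "tv_access": [],
        **{f"z{i + 1}": [] for i in range(20)},
    })
    return matrix, theme_map


def nn_validation_config(seed: int = 0) -> SyntheticConfig:
    """Linear-truth conditions for the feed-forward cross-check.

    Signal variables are mutually independent (within-theme correlation 0) so
    permutation importance does not split credit among correlated mates, the
    effects decline steadily (1.6 → 0.8 log-odds over four themes) to give
    both importance curves a single clean knee, and prevalence is 5% so a
    four-hidden-layer net is trainable at n = 10^4.
    """
    return SyntheticConfig(
        n_respondents=10_000, n_themes=4, vars_per_theme=3,
        categories_per_var=4, n_noise_vars=20, n_redundant_vars=0,
        theme_effects=(1.6, 1.3, 1.0, 0.8), target_prevalence=0.05,
        within_theme_correlation=0.0, seed=seed,
    )
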