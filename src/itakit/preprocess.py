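"""Survey preprocessing: role screening, recategorization, one-hot encoding.

Raw survey exports carry columns that must not enter an exploratory model:
identifiers (irrelevant), duplicate encodings of the same construct
(redundant — e.g. age both continuous and binned), and variables synonymous
with the outcome (endogenous — e.g. "ever used IUD" when modelling current
IUD use).  A variable catalog declares each column's role and optional
recategorization rules mapping raw values onto the literature-standard
categories (e.g. birth parity 0/1/2/3+).  Screened, recoded variables are
one-hot encoded with FULL (non-drop-first) dummies so every category level is
a named feature; the penalty absorbs the induced collinearity.  Missing
values become an explicit "missing" category.
"""

from __future__ import annotations

import json
import logging
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLES = ("analysis", "outcome", "irrelevant", "redundant", "endogenous")
KINDS = ("categorical", "continuous")
MISSING_LABEL = "missing"


@dataclass(frozen=True)
class Rule:
    """One recategorization bucket: a label plus a predicate over raw values.

    The predicate is either an explicit value set or a half-open numeric
    interval [lo, hi).  A raw value equal to the label itself always matches
    (this makes recategorization idempotent).
    """

    label: str
    values: frozenset | None = None
    lo: float | None = None
    hi: float | None = None

    def matches(self, value: Any) -> bool:
        if value == self.label or str(value) == self.label:
            return True
        if self.values is not None and (value in self.values or str(value) in
                                        {str(v) for v in self.values}):
            return True
        if (self.lo is not None or self.hi is not None) and isinstance(
            value, numbers.Number
        ) and not pd.isna(value):
            lo = -np.inf if self.lo is None else self.lo
            hi = np.inf if self.hi is None else self.hi
            return lo <= value < hi
        return False

    @classmethod
    def from_dict(cls, d: Mapping) -> "Rule":
        return cls(
            label=str(d["label"]),
            values=frozenset(d["values"]) if "values" in d else None,
            lo=d.get("min"),
            hi=d.get("max"),
        )


def _rules_overlap(a: Rule, b: Rule) -> bool:
    if a.values is not None and b.values is not None and a.values & b.values:
        return True
    if (a.lo is not None or a.hi is not None) and (b.lo is not None or b.hi is not None):
        alo = -np.inf if a.lo is None else a.lo
        ahi = np.inf if a.hi is None else a.hi
        blo = -np.inf if b.lo is None else b.lo
        bhi = np.inf if b.hi is None else b.hi
        if max(alo, blo) < min(ahi, bhi):
            return True
    if a.values is not None and (b.lo is not None or b.hi is not None):
        return any(b.matches(v) for v in a.values)
    if b.values is not None and (a.lo is not None or a.hi is not None):
        return any(a.matches(v) for v in b.values)
    return False


@dataclass
class CatalogEntry:
    name: str
    role: str
    kind: str | None = None  # None -> inferred from dtype at encoding time
    rules: tuple[Rule, ...] | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.kind is not None and self.kind not in KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.rules is not None:
            rules = tuple(self.rules)
            for i, a in enumerate(rules):
                for b in rules[i + 1:]:
                    if _rules_overlap(a, b):
                        raise ValueError(
                            f"{self.name}: overlapping recategorization rules "
                            f"{a.label!r} and {b.label!r}"
                        )
            self.rules = rules


class VariableCatalog:
    """Declares every raw column's role, kind, and recategorization rule."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self.entries: dict[str, CatalogEntry] = {}
        for e in entries:
            if e.name in self.entries:
                raise ValueError(f"duplicate catalog entry {e.name!r}")
            self.entries[e.name] = e
        outcomes = [e.name for e in self.entries.values() if e.role == "outcome"]
        if len(outcomes) != 1:
            raise ValueError(
                f"catalog must declare exactly one outcome, found {outcomes}"
            )
        self.outcome_name: str = outcomes[0]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> CatalogEntry:
        return self.entries[name]

    @classmethod
    def from_dict(cls, data: Mapping) -> "VariableCatalog":
        entries = []
        for item in data["variables"]:
            rules = item.get("rules")
            entries.append(
                CatalogEntry(
                    name=str(item["name"]),
                    role=item["role"],
                    kind=item.get("kind"),
                    rules=tuple(Rule.from_dict(r) for r in rules) if rules else None,
                )
            )
        return cls(entries)

    @classmethod
    def from_file(cls, path) -> "VariableCatalog":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = []
        for e in self.entries.values():
            item: dict[str, Any] = {"name": e.name, "role": e.role}
            if e.kind:
                item["kind"] = e.kind
            if e.rules:
                item["rules"] = [
                    {k: v for k, v in (
                        ("label", r.label),
                        ("values", sorted(r.values, key=str) if r.values else None),
                        ("min", r.lo), ("max", r.hi),
                    ) if v is not None}
                    for r in e.rules
                ]
            out.append(item)
        return {"variables": out}


@dataclass
class DesignMatrix:
    """One-hot-encoded respondent × feature matrix with binary outcome.

    ``feature_names`` are dummy-level names ``"<variable>=<category>"`` for
    encoded categoricals and the bare variable name for continuous
    pass-through columns; ``source_map`` sends each feature to its source
    variable.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    source_map: dict[str, str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y).astype(int)
        self.feature_names = tuple(self.feature_names)
        if self.X.shape != (len(self.y), len(self.feature_names)):
            raise ValueError("X shape inconsistent with y / feature_names")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        missing = set(self.feature_names) - set(self.source_map)
        if missing:
            raise ValueError(f"source_map missing features: {sorted(missing)[:5]}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def sources(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f in self.feature_names:
            seen.setdefault(self.source_map[f], None)
        return tuple(seen)

    def features_of(self, variables: Iterable[str]) -> tuple[str, ...]:
        wanted = set(variables)
        return tuple(f for f in self.feature_names if self.source_map[f] in wanted)

    def take_rows(self, idx) -> "DesignMatrix":
        return DesignMatrix(self.X[idx], self.y[idx], self.feature_names,
                            dict(self.source_map))

    def restrict(self, feature_subset: Iterable[str]) -> "DesignMatrix":
        keep = set(feature_subset)
        cols = [i for i, f in enumerate(self.feature_names) if f in keep]
        names = tuple(self.feature_names[i] for i in cols)
        return DesignMatrix(self.X[:, cols], self.y, names,
                            {f: self.source_map[f] for f in names})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.feature_names))


def screen_variables(table: pd.DataFrame, catalog: VariableCatalog) -> pd.DataFrame:
    """Keep only analysis and outcome columns; log every exclusion."""
    uncataloged = [c for c in table.columns if c not in catalog]
    if uncataloged:
        raise ValueError(f"columns missing from catalog: {uncataloged}")
    keep, dropped = [], []
    for c in table.columns:
        if catalog[c].role in ("analysis", "outcome"):
            keep.append(c)
        else:
            dropped.append((c, catalog[c].role))
    for name, role in dropped:
        logger.info("screened out %r (role=%s)", name, role)
    return table[keep]


def recategorize(table: pd.DataFrame, catalog: VariableCatalog) -> pd.DataFrame:
    """Apply each catalog recategorization rule; unruled columns untouched.

    Raises when an observed value matches no rule (rules must be exhaustive
    over the data).  Values already equal to a rule label map to themselves,
    so applying the recode twice equals applying it once.
    """
    out = table.copy()
    for name in table.columns:
        entry = catalog[name] if name in catalog else None
        if entry is None or not entry.rules:
            continue
        col = table[name]
        uniques = pd.unique(col)
        mapping: dict[Any, str] = {}
        unmatched = []
        for v in uniques:
            hits = [r.label for r in entry.rules if r.matches(v)]
            if not hits:
                unmatched.append(v)
            else:
                mapping[v] = hits[0]  # rules validated mutually exclusive
        if unmatched:
            raise ValueError(
                f"{name}: values match no recategorization rule: {unmatched[:10]}"
            )
        out[name] = col.map(mapping).astype(object)
    return out


def _is_continuous(col: pd.Series, entry: CatalogEntry | None) -> bool:
    if entry is not None:
        if entry.kind == "continuous":
            return True
        if entry.kind == "categorical" or entry.rules:
            return False
    return pd.api.types.is_float_dtype(col)


def one_hot(table: pd.DataFrame, outcome_name: str,
            catalog: VariableCatalog | None = None) -> DesignMatrix:
    """Full one-hot encoding: a k-category variable becomes k dummy columns.

    Continuous columns pass through on the raw scale (standardization is a
    fit-time concern).  Missing categorical values become a "missing" level;
    missing continuous values are mean-imputed with a companion
    ``var=missing`` indicator.  Constant columns are kept but logged — the
    penalty handles them.
    """
    if outcome_name not in table.columns:
        raise ValueError(f"outcome column {outcome_name!r} not in table")
    y = pd.to_numeric(table[outcome_name], errors="raise").astype(int).to_numpy()

    blocks: list[np.ndarray] = []
    names: list[str] = []
    source_map: dict[str, str] = {}
    for var in table.columns:
        if var == outcome_name:
            continue
        col = table[var]
        entry = catalog[var] if (catalog is not None and var in catalog) else None
        if _is_continuous(col, entry):
            vals = pd.to_numeric(col, errors="raise").astype(float)
            if vals.isna().any():
                ind = vals.isna().to_numpy().astype(float)
                vals = vals.fillna(vals.mean())
                blocks.append(ind[:, None])
                names.append(f"{var}={MISSING_LABEL}")
                source_map[f"{var}={MISSING_LABEL}"] = var
            blocks.append(vals.to_numpy()[:, None])
            names.append(var)
            source_map[var] = var
        else:
            labels = col.astype(object).where(~col.isna(), MISSING_LABEL).astype(str)
            cats = sorted(labels.unique())
            if len(cats) == 1:
                logger.warning("variable %r is constant after screening", var)
            codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()
            dummies = np.zeros((len(labels), len(cats)))
            dummies[np.arange(len(labels)), codes] = 1.0
            blocks.append(dummies)
            for c in cats:
                fname = f"{var}={c}"
                names.append(fname)
                source_map[fname] = var
    X = np.hstack(blocks) if blocks else np.empty((len(y), 0))
    return DesignMatrix(X=X, y=y, feature_names=tuple(names), source_map=source_map)


def build_design_matrix(table: pd.DataFrame,
                        catalog: VariableCatalog) -> DesignMatrix:
    """screen → recategorize → one-hot, the full preprocessing chain."""
    screened = screen_variables(table, catalog)
    recoded = recategorize(screened, catalog)
    return one_hot(recoded, catalog.outcome_name, catalog)
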