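"""Raw survey table -> numeric design matrix.

Steps, in the order the pipeline applies them:

1. outcome aggregation (any-vs-none over the violence item triple),
2. full one-hot encoding of categoricals with >= 3 levels (no reference
   level is dropped — every level is a candidate feature; penalization
   absorbs the induced collinearity),
3. z-scoring of continuous columns (unweighted population moments; the
   survey weights enter the likelihood, not the feature scaling),
4. redundancy removal: declared duplicate representations (``duplicate_of``
   in the variable dictionary) and bitwise-identical columns.

Missing covariate values: one-hot indicators get 0 in every level column;
continuous values are mean-imputed, with a companion missingness indicator
added only when more than 1% of a variable is missing.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Variable",
    "VariableDictionary",
    "EncodedMatrix",
    "aggregate_outcome",
    "one_hot_encode",
    "normalize_continuous",
    "remove_redundant",
    "prepare",
]

MISSINGNESS_INDICATOR_THRESHOLD = 0.01


@dataclasses.dataclass(frozen=True)
class Variable:
    name: str
    kind: str  # "categorical" | "continuous" | "binary"
    levels: tuple[str, ...] | None = None
    duplicate_of: str | None = None

    def __post_init__(self):
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) < 3:
                raise ValueError(f"categorical {self.name!r} must list >= 3 levels")
        elif self.kind == "binary":
            if self.levels is not None and len(self.levels) != 2:
                raise ValueError(f"binary {self.name!r} must have exactly 2 levels")
        elif self.kind != "continuous":
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")


class VariableDictionary:
    """Per-variable metadata: kind, levels, declared duplicate links."""

    def __init__(self, variables: list[Variable]):
        self._vars = {v.name: v for v in variables}
        if len(self._vars) != len(variables):
            raise ValueError("duplicate variable names in dictionary")
        for v in variables:
            if v.duplicate_of is not None and v.duplicate_of not in self._vars:
                raise ValueError(
                    f"{v.name!r} declares duplicate_of {v.duplicate_of!r}, "
                    "which is not in the dictionary")
        self._check_no_cycles()

    def _check_no_cycles(self):
        for name in self._vars:
            seen = set()
            cur = name
            while self._vars[cur].duplicate_of is not None:
                if cur in seen:
                    raise ValueError(f"duplicate_of cycle involving {name!r}")
                seen.add(cur)
                cur = self._vars[cur].duplicate_of

    def __getitem__(self, name: str) -> Variable:
        return self._vars[name]

    def __contains__(self, name: str) -> bool:
        return name in self._vars

    def __iter__(self):
        return iter(self._vars.values())

    def __len__(self):
        return len(self._vars)

    @classmethod
    def from_mapping(cls, mapping: dict[str, dict]) -> "VariableDictionary":
        """Build from {name: {kind, levels, duplicate_of}} (generator output)."""
        out = []
        for name, d in mapping.items():
            levels = tuple(d["levels"]) if d.get("levels") else None
            kind = d["kind"]
            if kind == "categorical" and levels is not None and len(levels) == 2:
                kind = "binary"
            out.append(Variable(name=name, kind=kind, levels=levels,
                                duplicate_of=d.get("duplicate_of")))
        return cls(out)

    @classmethod
    def from_csv(cls, path) -> "VariableDictionary":
        df = pd.read_csv(path, keep_default_na=False)
        mapping = {}
        for _, row in df.iterrows():
            levels = row["levels"].split("|") if row.get("levels") else None
            mapping[row["name"]] = {"kind": row["kind"], "levels": levels,
                                    "duplicate_of": row["duplicate_of"] or None}
        return cls.from_mapping(mapping)


@dataclasses.dataclass
class EncodedMatrix:
    """Dense numeric design matrix with aligned outcome, weights, provenance.

    ``provenance`` maps each feature name to (source variable, level);
    ``level`` is None for continuous features.
    """

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    w: np.ndarray
    provenance: dict[str, tuple[str, str | None]]

    def __post_init__(self):
        if not (self.X.shape[0] == self.y.size == self.w.size):
            raise ValueError("X, y, w row counts disagree")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def source_variable(self, feature: str) -> str:
        return self.provenance[feature][0]

    def variables_of(self, features) -> list[str]:
        """Unique source variables of the given features, first-seen order."""
        seen: dict[str, None] = {}
        for f in features:
            seen.setdefault(self.provenance[f][0])
        return list(seen)

    def columns_of_variables(self, variables) -> list[str]:
        vs = set(variables)
        return [f for f in self.feature_names if self.provenance[f][0] in vs]

    def subset_features(self, features) -> "EncodedMatrix":
        idx = [self.feature_names.index(f) for f in features]
        return EncodedMatrix(
            X=self.X[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            y=self.y, w=self.w,
            provenance={f: self.provenance[f] for f in features},
        )

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"feature": f, "source_variable": s, "level": lv}
             for f, (s, lv) in self.provenance.items()]
        )


def aggregate_outcome(items: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a triple of binary item indicators to any-vs-none.

    Outcome is 1 if any answered item is 1, 0 if all answered items are 0.
    Respondents with all three items missing cannot be classified and are
    dropped; returns ``(outcome, keep_mask)`` aligned to the input rows,
    with the number of drops logged.
    """
    vals = items.to_numpy(dtype=float)
    if vals.shape[1] != 3:
        raise ValueError("expected exactly three item columns")
    answered = ~np.isnan(vals)
    keep = answered.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("aggregate_outcome: dropped %d respondents with all "
                    "items missing", n_dropped)
    any_yes = np.nansum(np.where(answered, vals, 0.0), axis=1) > 0
    outcome = np.where(any_yes, 1, 0)
    return outcome[keep], keep


def one_hot_encode(table: pd.DataFrame, dictionary: VariableDictionary,
                   outcome_col: str = "outcome",
                   weight_col: str = "weight") -> EncodedMatrix:
    """Expand the raw table into the numeric design matrix.

    Categoricals with k >= 3 levels become k {0,1} indicator columns named
    ``var=level`` (full one-hot); binaries become a single 0/1 column;
    continuous columns pass through (normalisation is a separate step).
    An unseen categorical level raises with the variable and level named.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    provenance: dict[str, tuple[str, str | None]] = {}
    var_names = [v.name for v in dictionary if v.name in table.columns]
    missing = [c for c in table.columns
               if c not in (outcome_col, weight_col, "id") and c not in dictionary]
    if missing:
        raise ValueError(f"variables missing from the dictionary: {missing}")

    for name in var_names:
        var = dictionary[name]
        col = table[name]
        if var.kind == "categorical":
            observed = set(col.dropna().astype(str).unique())
            unseen = observed - set(var.levels)
            if unseen:
                raise ValueError(
                    f"variable {name!r}: unseen level(s) {sorted(unseen)}")
            for level in var.levels:
                names.append(f"{name}={level}")
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
                provenance[names[-1]] = (name, level)
        elif var.kind == "binary":
            if var.levels is not None:
                observed = set(col.dropna().astype(str).unique())
                unseen = observed - set(var.levels)
                if unseen:
                    raise ValueError(
                        f"variable {name!r}: unseen level(s) {sorted(unseen)}")
                vals = (col.astype(str) == var.levels[1]).to_numpy(dtype=float)
            else:
                vals = col.to_numpy(dtype=float)
                vals = np.where(np.isnan(vals), 0.0, vals)
            names.append(name)
            cols.append(vals)
            provenance[name] = (name, None)
        else:  # continuous
            vals = col.to_numpy(dtype=float)
            frac_missing = float(np.isnan(vals).mean())
            if frac_missing > 0:
                mean = float(np.nanmean(vals))
                filled = np.where(np.isnan(vals), mean, vals)
                if frac_missing > MISSINGNESS_INDICATOR_THRESHOLD:
                    names.append(f"{name}__missing")
                    cols.append(np.isnan(vals).astype(float))
                    provenance[names[-1]] = (name, "__missing")
                vals = filled
            names.append(name)
            cols.append(vals)
            provenance[name] = (name, None)

    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    y = table[outcome_col].to_numpy(dtype=int)
    w = table[weight_col].to_numpy(dtype=float)
    return EncodedMatrix(X=X, feature_names=names, y=y, w=w,
                         provenance=provenance)


def normalize_continuous(matrix: EncodedMatrix,
                         dictionary: VariableDictionary) -> EncodedMatrix:
    """Z-score continuous columns in place of their raw values.

    Uses unweighted population moments (ddof=0).  Constant columns carry no
    information and are dropped with a logged warning.
    """
    keep = np.ones(matrix.p, dtype=bool)
    X = matrix.X.copy()
    for j, f in enumerate(matrix.feature_names):
        src, level = matrix.provenance[f]
        if level is not None or dictionary[src].kind != "continuous":
            continue
        col = X[:, j]
        sd = float(col.std(ddof=0))
        if sd == 0.0:
            logger.warning("normalize_continuous: dropping constant column %r", f)
            keep[j] = False
            continue
        X[:, j] = (col - col.mean()) / sd
    names = [f for j, f in enumerate(matrix.feature_names) if keep[j]]
    return EncodedMatrix(X=X[:, keep], feature_names=names, y=matrix.y,
                         w=matrix.w,
                         provenance={f: matrix.provenance[f] for f in names})


def remove_redundant(matrix: EncodedMatrix,
                     dictionary: VariableDictionary) -> EncodedMatrix:
    """Drop redundant representations so each measure enters once.

    (a) every column derived from a variable with ``duplicate_of`` set is
    dropped (the source representation is kept); (b) bitwise-identical
    columns are deduplicated keeping the first in feature-name order.
    """
    keep = []
    for f in matrix.feature_names:
        src, _ = matrix.provenance[f]
        if src in dictionary and dictionary[src].duplicate_of is not None:
            continue
        keep.append(f)

    by_name = sorted(keep)
    seen: dict[bytes, str] = {}
    drop: set[str] = set()
    idx = {f: j for j, f in enumerate(matrix.feature_names)}
    for f in by_name:
        key = matrix.X[:, idx[f]].tobytes()
        if key in seen:
            drop.add(f)
        else:
            seen[key] = f
    final = [f for f in keep if f not in drop]
    cols = [idx[f] for f in final]
    return EncodedMatrix(X=matrix.X[:, cols], feature_names=final,
                         y=matrix.y, w=matrix.w,
                         provenance={f: matrix.provenance[f] for f in final})


def prepare(table: pd.DataFrame, dictionary: VariableDictionary,
            **encode_kwargs) -> EncodedMatrix:
    """Full preparation chain: encode -> normalize -> deduplicate."""
    m = one_hot_encode(table, dictionary, **encode_kwargs)
    m = normalize_continuous(m, dictionary)
    return remove_redundant(m, dictionary)
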