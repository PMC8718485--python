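"""The iterative thematic analysis loop.

Each round, on the currently active features of a fixed 80/20
train/test split:

1. lasso (L1) logistic regression with fivefold-CV-tuned lambda on the
   training rows; features with zero coefficients are dropped;
2. ridge (L2) logistic regression, lambda re-tuned by CV, refit on the
   lasso support only (a parsimonious ranking model);
3. weighted test AUC and balanced error rate; if AUC falls below the floor
   (default 0.75) the loop stops before any further exclusion;
4. knee-point selection on the descending |ridge coefficient| curve;
5. the selected features are mapped to their source variables, any uncoded
   variable is sent to the theme-map provider, newly surfaced variables
   whose themes are all already excluded are dropped, themes are qualified
   (>= 2 selected members and >= 5% of the selected variables), and the
   theme containing the top-ranked selected variable is excluded — a
   variable leaves the active set only when *all* of its themes are
   excluded;
6. stopping rules: AUC below floor, three consecutive rounds without a new
   qualified theme, no new variable identified this round, or a maximum
   round guard.

The loop is a pure function of (encoded data, seeds, theme map), which is
what makes interrupted runs resumable by re-running with the completed
coding worksheet merged in.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .knee import NoKneeError, find_knee, rank_coefficients, select_above_knee
from .metrics import SplitSpec, choose_threshold, evaluate_scores, make_split
from .models import (RegularizedFit, default_lambda_grid,
                     fit_penalized_logistic, lasso_path, lasso_support,
                     penalized_objective, select_lambda_cv)
from .prep import EncodedMatrix

__all__ = [
    "ThemeMap",
    "EngineConfig",
    "IterationState",
    "CodingRequired",
    "MappingProvider",
    "ground_truth_provider",
    "qualify_themes",
    "find_dominant_theme",
    "apply_exclusion",
    "filter_previously_excluded",
    "check_stopping",
    "run_iterative_analysis",
    "request_coding",
    "coder_agreement",
]

THEME_MIN_MEMBERS = 2
THEME_MIN_FRACTION = 0.05


class ThemeMap:
    """Variable -> set-of-theme-labels assignments from one coder."""

    def __init__(self, assignments: dict[str, set[str]] | None = None,
                 coder_id: str = "coder"):
        self.assignments: dict[str, set[str]] = {
            v: set(labels) for v, labels in (assignments or {}).items()}
        for v, labels in self.assignments.items():
            if not labels:
                raise ValueError(f"variable {v!r} assigned an empty theme set")
        self.coder_id = coder_id

    def themes_of(self, variable: str) -> set[str]:
        return self.assignments.get(variable, set())

    def is_coded(self, variable: str) -> bool:
        return variable in self.assignments

    def update(self, new: dict[str, set[str]]) -> None:
        for v, labels in new.items():
            if not labels:
                raise ValueError(f"variable {v!r} assigned an empty theme set")
            self.assignments[v] = set(labels)

    @classmethod
    def from_csv(cls, path, coder_id: str = "coder") -> "ThemeMap":
        """Read a long-format map: columns ``variable``, ``theme``."""
        df = pd.read_csv(path)
        out: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            out.setdefault(str(row["variable"]), set()).add(str(row["theme"]))
        return cls(out, coder_id=coder_id)

    def to_csv(self, path) -> None:
        rows = [{"variable": v, "theme": t}
                for v in sorted(self.assignments)
                for t in sorted(self.assignments[v])]
        pd.DataFrame(rows, columns=["variable", "theme"]).to_csv(path, index=False)


class CodingRequired(RuntimeError):
    """Raised when selected variables lack theme codes; carries a worksheet."""

    def __init__(self, worksheet: pd.DataFrame, round_index: int):
        self.worksheet = worksheet
        self.round_index = round_index
        super().__init__(
            f"{len(worksheet)} selected variables in round {round_index} "
            "have no theme code; complete the worksheet and resume")


class MappingProvider:
    """Theme-map provider backed by a fixed mapping.

    ``fallback='misc'`` assigns each unmapped variable a singleton
    ``misc::<variable>`` label (it can then never form a qualifying theme);
    ``fallback='request'`` signals the engine to emit a coding worksheet.
    """

    def __init__(self, theme_map: ThemeMap, fallback: str = "request"):
        if fallback not in ("misc", "request"):
            raise ValueError("fallback must be 'misc' or 'request'")
        self.theme_map = theme_map
        self.fallback = fallback

    def code(self, variables: list[str]) -> tuple[dict[str, set[str]], list[str]]:
        """Return (codes, still_uncoded)."""
        codes: dict[str, set[str]] = {}
        uncoded: list[str] = []
        for v in variables:
            if self.theme_map.is_coded(v):
                codes[v] = self.theme_map.themes_of(v)
            elif self.fallback == "misc":
                codes[v] = {f"misc::{v}"}
            else:
                uncoded.append(v)
        return codes, uncoded


def ground_truth_provider(ground_truth) -> MappingProvider:
    """Provider that codes from the generator's planted theme map.

    Unthemed (null) variables get singleton ``misc::`` labels, standing in
    for a human coder filing unrelated items under one-off categories.
    """
    tm = ThemeMap({v: set(s) for v, s in ground_truth.theme_map.items()},
                  coder_id="ground_truth")
    return MappingProvider(tm, fallback="misc")


@dataclasses.dataclass(frozen=True)
class EngineConfig:
    """All tunables of one iterative analysis run."""

    split: SplitSpec = SplitSpec(train_fraction=0.8, stratified=True, seed=0)
    cv_seed: int = 0
    cv_folds: int = 5
    n_lambda: int = 6
    lambda_ratio: float = 0.02
    ridge_lambda_ratio: float = 1e-4
    cv_tol: float = 1e-2
    cv_max_iter: int = 500
    fit_tol: float = 1e-4
    fit_max_iter: int = 2000
    l1_solver: str = "liblinear"
    support_tol: float = 1e-10
    auc_floor: float = 0.75
    no_new_theme_rounds: int = 3
    max_rounds: int = 25
    weighted_metrics: bool = True

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class IterationState:
    """Evolving bookkeeping across rounds."""

    round: int = 0
    active_features: list[str] = dataclasses.field(default_factory=list)
    excluded_themes: list[str] = dataclasses.field(default_factory=list)
    history: list[dict] = dataclasses.field(default_factory=list)
    rounds_without_new_theme: int = 0
    stop_reason: str | None = None
    seen_variables: set[str] = dataclasses.field(default_factory=set)
    qualified_ever: set[str] = dataclasses.field(default_factory=set)


# ---------------------------------------------------------------------------
# Rule logic (pure functions)
# ---------------------------------------------------------------------------

def qualify_themes(selected_vars: list[str], theme_map: ThemeMap) -> set[str]:
    """Themes with >= 2 selected members and >= 5% of the selected variables.

    The 5% floor is ceil(0.05 * |selected|), so with 40 selected variables a
    2-member theme qualifies, while with 100 selected it takes 5 members.
    """
    if not selected_vars:
        return set()
    counts: dict[str, int] = {}
    for v in selected_vars:
        for t in theme_map.themes_of(v):
            counts[t] = counts.get(t, 0) + 1
    floor = max(THEME_MIN_MEMBERS, math.ceil(THEME_MIN_FRACTION * len(selected_vars)))
    return {t for t, c in counts.items() if c >= floor}


def find_dominant_theme(ranked_vars: list[str], qualified: set[str],
                        theme_map: ThemeMap) -> str:
    """First qualified theme met walking the ranked variables from the top.

    If the top variable belongs to several qualified themes the tie is
    broken toward the theme with more coded members overall, then
    lexicographically.
    """
    if not qualified:
        raise ValueError("no qualified theme to pick a dominant one from")
    sizes: dict[str, int] = {}
    for v, labels in theme_map.assignments.items():
        for t in labels:
            sizes[t] = sizes.get(t, 0) + 1
    for v in ranked_vars:
        cands = theme_map.themes_of(v) & qualified
        if cands:
            return sorted(cands, key=lambda t: (-sizes.get(t, 0), t))[0]
    raise ValueError("no ranked variable belongs to a qualified theme")


def apply_exclusion(state: IterationState, dominant_theme: str,
                    theme_map: ThemeMap,
                    encoded: EncodedMatrix) -> list[str]:
    """Exclude a theme; drop variables with *all* their themes excluded.

    Variables also belonging to a still-active theme are retained.  Returns
    the updated active feature list (state is updated in place).
    """
    if dominant_theme not in state.excluded_themes:
        state.excluded_themes.append(dominant_theme)
    excluded = set(state.excluded_themes)
    drop_vars = {v for v, labels in theme_map.assignments.items()
                 if labels and labels <= excluded}
    state.active_features = [
        f for f in state.active_features
        if encoded.source_variable(f) not in drop_vars]
    return state.active_features


def filter_previously_excluded(newly_selected_vars: list[str],
                               state: IterationState,
                               theme_map: ThemeMap) -> tuple[list[str], list[str]]:
    """Drop new variables whose theme sets fall inside the excluded set.

    Returns ``(retained, dropped)`` preserving order.  A variable with at
    least one non-excluded theme is retained.
    """
    excluded = set(state.excluded_themes)
    retained, dropped = [], []
    for v in newly_selected_vars:
        labels = theme_map.themes_of(v)
        if labels and labels <= excluded:
            dropped.append(v)
        else:
            retained.append(v)
    return retained, dropped


def check_stopping(state: IterationState, test_auc: float,
                   new_variables_found: bool = True,
                   config: EngineConfig = EngineConfig()) -> tuple[bool, str | None]:
    """Evaluate the stopping rules in order of precedence.

    (a) test AUC below the floor, (b) ``no_new_theme_rounds`` consecutive
    rounds without a newly qualified theme, (c) no variable unseen in prior
    rounds in the current selection, plus a max-round guard.
    """
    if test_auc < config.auc_floor:
        return True, "auc_floor"
    if state.rounds_without_new_theme >= config.no_new_theme_rounds:
        return True, "no_new_themes_3"
    if not new_variables_found:
        return True, "no_new_variables"
    if state.round >= config.max_rounds:
        return True, "max_rounds"
    return False, None


# ---------------------------------------------------------------------------
# Coding worksheet
# ---------------------------------------------------------------------------

def request_coding(uncoded_vars: list[str], ranked_vars: list[str],
                   var_top_coef: dict[str, float]) -> pd.DataFrame:
    """Worksheet for the human coders: variable, rank, coefficient, theme.

    The ``theme`` column is left blank; multiple themes may be entered
    separated by ``|``.  The engine halts resumably when this is emitted.
    """
    rank_of = {v: i + 1 for i, v in enumerate(ranked_vars)}
    rows = [{"variable": v, "rank": rank_of.get(v, ""),
             "coefficient": var_top_coef.get(v, float("nan")),
             "suggested_context": "selected above knee point",
             "theme": ""}
            for v in uncoded_vars]
    return pd.DataFrame(rows, columns=["variable", "rank", "coefficient",
                                       "suggested_context", "theme"])


def read_completed_worksheet(path) -> dict[str, set[str]]:
    """Parse a completed coding worksheet; error on unassigned rows."""
    df = pd.read_csv(path, keep_default_na=False)
    blank = [str(r["variable"]) for _, r in df.iterrows()
             if not str(r["theme"]).strip()]
    if blank:
        raise ValueError(f"worksheet rows without a theme: {blank}")
    return {str(r["variable"]): {t.strip() for t in str(r["theme"]).split("|")}
            for _, r in df.iterrows()}


def coder_agreement(map_a: ThemeMap, map_b: ThemeMap,
                    variables: list[str]) -> float:
    """Percent of variables with identical theme sets across two coders."""
    for v in variables:
        if not map_a.is_coded(v) or not map_b.is_coded(v):
            raise ValueError(f"variable {v!r} is not coded by both coders")
    if not variables:
        raise ValueError("empty variable list")
    same = sum(map_a.themes_of(v) == map_b.themes_of(v) for v in variables)
    return 100.0 * same / len(variables)


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------

def run_iterative_analysis(encoded: EncodedMatrix, provider,
                           config: EngineConfig = EngineConfig()) -> dict:
    """Run the full loop and return the analysis report (a plain dict).

    ``provider`` supplies theme codes for surfaced variables (for example
    :func:`ground_truth_provider` on synthetic data, or a
    :class:`MappingProvider` over a human-coded CSV).  Raises
    :class:`CodingRequired` when codes are missing and the provider asks
    for a worksheet.
    """
    state = IterationState(active_features=list(encoded.feature_names))
    # codes gathered during THIS run: only variables that actually surfaced
    # are ever coded, so exclusion can never act on unseen variables (this
    # also makes interrupted-and-resumed runs identical to uninterrupted ones)
    known = ThemeMap({}, coder_id=getattr(provider.theme_map, "coder_id", "run"))

    train, test = make_split(encoded.n, config.split, y=encoded.y)
    Xtr_all, ytr, wtr = encoded.X[train], encoded.y[train], encoded.w[train]
    Xte_all, yte, wte = encoded.X[test], encoded.y[test], encoded.w[test]
    if not config.weighted_metrics:
        wtr_m = np.ones_like(wtr)
        wte_m = np.ones_like(wte)
    else:
        wtr_m, wte_m = wtr, wte

    col_index = {f: j for j, f in enumerate(encoded.feature_names)}

    report: dict = {
        "config": config.as_dict(),
        "n_train": int(train.size),
        "n_test": int(test.size),
        "rounds": [],
        "stop_reason": None,
        "excluded_themes": [],
    }

    while True:
        state.round += 1
        rnd: dict = {"round": state.round,
                     "n_active_features": len(state.active_features)}
        cols = [col_index[f] for f in state.active_features]
        Xtr = Xtr_all[:, cols]
        Xte = Xte_all[:, cols]
        names = list(state.active_features)

        # (1) lasso with CV-tuned lambda on the active features
        grid = default_lambda_grid(Xtr, ytr, wtr, n=config.n_lambda,
                                   ratio=config.lambda_ratio)
        cv = select_lambda_cv(Xtr, ytr, wtr, grid=grid, k=config.cv_folds,
                              seed=config.cv_seed, penalty="l1",
                              tol=config.cv_tol, max_iter=config.cv_max_iter,
                              solver=config.l1_solver)
        if config.l1_solver == "liblinear":
            # warm screened path down to the selected lambda
            path_grid = grid[grid >= cv.best_lambda]
            thetas, bs = lasso_path(Xtr, ytr, wtr, lambdas=path_grid,
                                    tol=config.fit_tol,
                                    max_iter=config.fit_max_iter)
            lasso_fit = RegularizedFit(
                theta=thetas[-1], intercept=float(bs[-1]), penalty="l1",
                lam=cv.best_lambda, converged=True,
                objective_value=penalized_objective(
                    Xtr, ytr, wtr, thetas[-1], float(bs[-1]),
                    cv.best_lambda, "l1"),
                feature_names=tuple(names))
        else:
            lasso_fit = fit_penalized_logistic(
                Xtr, ytr, wtr, lam=cv.best_lambda, penalty="l1",
                tol=config.fit_tol, max_iter=config.fit_max_iter,
                feature_names=names, solver=config.l1_solver)
        support = list(lasso_support(lasso_fit, tol=config.support_tol))
        rnd["lasso_lambda"] = cv.best_lambda
        rnd["lasso_support_size"] = len(support)

        if not support:
            # intercept-only model: constant score, AUC exactly 0.5
            rnd["test_metrics"] = {"auc": 0.5, "ber": 0.5,
                                   "sensitivity": 1.0, "specificity": 0.0,
                                   "threshold": float("nan"),
                                   "weighted": config.weighted_metrics}
            rnd["selected_variables"] = []
            rnd["qualified_themes"] = []
            rnd["dominant_theme"] = None
            report["rounds"].append(rnd)
            state.stop_reason = ("auc_floor" if 0.5 < config.auc_floor
                                 else "empty_support")
            break

        sup_cols = [names.index(f) for f in support]

        # (2) ridge refit on the lasso support, lambda re-tuned
        ridge_grid = default_lambda_grid(Xtr[:, sup_cols], ytr, wtr,
                                         n=config.n_lambda,
                                         ratio=config.ridge_lambda_ratio)
        ridge_cv = select_lambda_cv(Xtr[:, sup_cols], ytr, wtr,
                                    grid=ridge_grid, k=config.cv_folds,
                                    seed=config.cv_seed, penalty="l2",
                                    tol=config.cv_tol,
                                    max_iter=config.cv_max_iter)
        ridge_fit = fit_penalized_logistic(Xtr[:, sup_cols], ytr, wtr,
                                           lam=ridge_cv.best_lambda,
                                           penalty="l2", tol=config.fit_tol,
                                           max_iter=config.fit_max_iter,
                                           feature_names=support)
        rnd["ridge_lambda"] = ridge_cv.best_lambda

        # (3) weighted test AUC / BER with a train-frozen threshold
        scores_tr = ridge_fit.predict_score(Xtr[:, sup_cols])
        scores_te = ridge_fit.predict_score(Xte[:, sup_cols])
        thr = choose_threshold(scores_tr, ytr, wtr_m)
        metrics = evaluate_scores(scores_te, yte, wte_m, threshold=thr,
                                  weighted=config.weighted_metrics)
        rnd["test_metrics"] = metrics.as_dict()

        if metrics.auc < config.auc_floor:
            rnd["selected_variables"] = []
            rnd["qualified_themes"] = []
            rnd["dominant_theme"] = None
            report["rounds"].append(rnd)
            state.stop_reason = "auc_floor"
            break

        # (4) knee-point selection on the ridge coefficient curve
        curve = rank_coefficients(ridge_fit, names=support, source="ridge")
        try:
            knee = find_knee(curve)
        except NoKneeError as err:
            rnd["selected_variables"] = []
            rnd["no_knee"] = str(err)
            report["rounds"].append(rnd)
            state.stop_reason = "no_knee"
            break
        selected_features = select_above_knee(curve, knee)
        rnd["knee_rank"] = knee.knee_rank

        # ranked source variables (first occurrence keeps rank order)
        ranked_vars = encoded.variables_of(curve.names)
        selected_vars = encoded.variables_of(selected_features)
        rnd["selected_features"] = selected_features

        # (5) coding
        uncoded = [v for v in selected_vars if not known.is_coded(v)]
        if uncoded:
            codes, still_uncoded = provider.code(uncoded)
            known.update(codes)
            if still_uncoded:
                var_top = {}
                for f, val in zip(curve.names, curve.values):
                    v = encoded.source_variable(f)
                    var_top.setdefault(v, float(val))
                raise CodingRequired(
                    request_coding(still_uncoded, ranked_vars, var_top),
                    state.round)

        new_vars = [v for v in selected_vars if v not in state.seen_variables]
        state.seen_variables.update(selected_vars)

        retained_vars, dropped_vars = filter_previously_excluded(
            selected_vars, state, known)
        if dropped_vars:
            dropped_set = set(dropped_vars)
            state.active_features = [
                f for f in state.active_features
                if encoded.source_variable(f) not in dropped_set]
        rnd["selected_variables"] = retained_vars
        rnd["dropped_previously_excluded"] = dropped_vars

        qualified = qualify_themes(retained_vars, known)
        new_themes = qualified - state.qualified_ever
        state.qualified_ever |= qualified
        rnd["qualified_themes"] = sorted(qualified)
        rnd["new_themes"] = sorted(new_themes)
        rnd["new_variables"] = new_vars

        if new_themes:
            state.rounds_without_new_theme = 0
        else:
            state.rounds_without_new_theme += 1

        if not qualified:
            rnd["dominant_theme"] = None
            report["rounds"].append(rnd)
            state.stop_reason = "no_qualified_theme"
            break

        ranked_retained = [v for v in ranked_vars if v in set(retained_vars)]
        dominant = find_dominant_theme(ranked_retained, qualified, known)
        rnd["dominant_theme"] = dominant
        apply_exclusion(state, dominant, known, encoded)
        rnd["n_active_after_exclusion"] = len(state.active_features)
        report["rounds"].append(rnd)

        stop, reason = check_stopping(state, metrics.auc,
                                      new_variables_found=bool(new_vars),
                                      config=config)
        if stop:
            state.stop_reason = reason
            break
        if not state.active_features:
            state.stop_reason = "no_active_features"
            break

    report["stop_reason"] = state.stop_reason
    report["excluded_themes"] = list(state.excluded_themes)
    report["seen_variables"] = sorted(state.seen_variables)
    return report
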