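"""Survey-weighted evaluation: splits, AUC, balanced error rate, reports.

Every metric here accepts per-respondent survey weights.  With unit weights
the weighted formulas reduce exactly to their unweighted textbook forms, and
integer weights are equivalent to row replication; both properties are
exercised in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "SplitSpec",
    "EvalMetrics",
    "make_split",
    "weighted_auc",
    "choose_threshold",
    "confusion_metrics",
    "write_report",
]


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Specification of the train/test partition (default 80/20, stratified)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class EvalMetrics:
    """Discrimination and error summary for one model on one data split.

    ``ber`` is the balanced error rate 1 - (sensitivity + specificity) / 2,
    a symmetric error summary suited to rare outcomes where raw accuracy is
    dominated by the majority class.
    """

    auc: float
    ber: float
    sensitivity: float
    specificity: float
    threshold: float
    weighted: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_split(n: int, spec: SplitSpec, y: np.ndarray | None = None):
    """Partition ``range(n)`` into train/test index arrays.

    Stratification by outcome requires ``y``; both sides must end up with
    both outcome classes or a ``ValueError`` is raised.
    """
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    idx = np.arange(n)
    strat = None
    if spec.stratified:
        if y is None:
            raise ValueError("stratified split requires the outcome vector")
        strat = np.asarray(y)
    train, test = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    train = np.sort(train)
    test = np.sort(test)
    if y is not None:
        y = np.asarray(y)
        for name, part in (("train", train), ("test", test)):
            if np.unique(y[part]).size < 2:
                raise ValueError(f"{name} split contains a single outcome class")
    return train, test


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")


def weighted_auc(scores, y, w=None) -> float:
    """Survey-weighted AUC as the weighted Mann-Whitney statistic.

    Sum over (positive i, negative j) pairs of w_i * w_j * [1(s_i > s_j)
    + 0.5 * 1(s_i == s_j)], normalised by the total pair weight.  Computed
    in O(n log n) via weighted midranks; equal to brute-force pair
    enumeration (asserted in tests).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    w = np.ones_like(scores) if w is None else np.asarray(w, dtype=float)
    _check_two_classes(y)
    pos = y == 1
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    w_sorted = w[order]
    # weighted midranks: rank(s) = W_below + (w_tie_group + own weight)/2,
    # expressed via cumulative weights over tie groups
    cum = np.concatenate([[0.0], np.cumsum(w_sorted)])
    ranks = np.empty_like(s_sorted)
    i = 0
    n = s_sorted.size
    while i < n:
        j = i
        while j + 1 < n and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        # midrank of the tie group [i, j]: weight below + half the group weight
        ranks[i : j + 1] = cum[i] + (cum[j + 1] - cum[i]) / 2.0
        i = j + 1
    r = np.empty_like(ranks)
    r[order] = ranks
    w_pos = w[pos].sum()
    w_neg = w[~pos].sum()
    # sum over positives of (weight below each positive among ALL points,
    # midrank style) minus the positive-vs-positive contribution
    u = float(np.sum(w[pos] * r[pos]))
    # within-positive pairs contribute w_i*w_j/2 each plus self terms; the
    # midrank sum over positives restricted to positives equals W_pos^2/2
    u -= w_pos**2 / 2.0
    if w_pos <= 0 or w_neg <= 0:
        raise ValueError("both classes must carry positive weight")
    return u / (w_pos * w_neg)


def confusion_metrics(yhat, y, w=None, threshold: float = float("nan"),
                      weighted: bool = True) -> EvalMetrics:
    """Weighted sensitivity, specificity and balanced error rate.

    ``auc`` is not computable from hard predictions and is reported as NaN;
    use :func:`weighted_auc` on the scores for discrimination.
    """
    yhat = np.asarray(yhat)
    y = np.asarray(y)
    w = np.ones(y.shape, dtype=float) if w is None else np.asarray(w, dtype=float)
    wtp = float(w[(yhat == 1) & (y == 1)].sum())
    wfn = float(w[(yhat == 0) & (y == 1)].sum())
    wtn = float(w[(yhat == 0) & (y == 0)].sum())
    wfp = float(w[(yhat == 1) & (y == 0)].sum())
    sens = wtp / (wtp + wfn) if (wtp + wfn) > 0 else float("nan")
    spec = wtn / (wtn + wfp) if (wtn + wfp) > 0 else float("nan")
    ber = 1.0 - (sens + spec) / 2.0
    return EvalMetrics(auc=float("nan"), ber=ber, sensitivity=sens,
                       specificity=spec, threshold=threshold, weighted=weighted)


def choose_threshold(scores, y, w=None) -> float:
    """Threshold over observed scores minimising weighted BER.

    Candidate thresholds are the unique observed scores; a point is
    classified positive when ``score >= threshold``.  Ties in BER are broken
    toward the lower threshold.  Chosen on the training split only and then
    frozen, so test metrics are leakage-free.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    w = np.ones_like(scores) if w is None else np.asarray(w, dtype=float)
    _check_two_classes(y)
    cand = np.unique(scores)
    best_t, best_ber = cand[0], np.inf
    w_pos = w[y == 1].sum()
    w_neg = w[y == 0].sum()
    # sort descending; sweeping the threshold down adds points to "positive"
    order = np.argsort(-scores, kind="mergesort")
    tp = 0.0
    fp = 0.0
    i = 0
    n = scores.size
    while i < n:
        j = i
        t = scores[order[i]]
        while j < n and scores[order[j]] == t:
            k = order[j]
            if y[k] == 1:
                tp += w[k]
            else:
                fp += w[k]
            j += 1
        sens = tp / w_pos
        spec = (w_neg - fp) / w_neg
        ber = 1.0 - (sens + spec) / 2.0
        # sweep goes from high to low threshold: <= keeps the lowest tied one
        if ber <= best_ber:
            best_ber = ber
            best_t = t
        i = j
    return float(best_t)


def evaluate_scores(scores, y, w=None, threshold: float | None = None,
                    weighted: bool = True) -> EvalMetrics:
    """AUC plus thresholded confusion metrics in one EvalMetrics record.

    If ``threshold`` is None it is chosen on these data (training use only).
    """
    w_used = None if not weighted else w
    auc = weighted_auc(scores, y, w_used)
    if threshold is None:
        threshold = choose_threshold(scores, y, w_used)
    yhat = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    cm = confusion_metrics(yhat, y, w_used, threshold=threshold, weighted=weighted)
    return dataclasses.replace(cm, auc=auc)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(report: dict, out_dir: str | Path, stem: str = "report") -> dict[str, Path]:
    """Write a machine-readable JSON report and a Markdown summary.

    ``report`` is the dict produced by the iterative engine or the NN
    pipeline.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{stem}.json"
    md_path = out_dir / f"{stem}.md"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonable))
    md_path.write_text(_markdown_summary(report))
    return {"json": json_path, "markdown": md_path}


def _markdown_summary(report: dict) -> str:
    lines = ["# Iterative thematic analysis report", ""]
    if "stop_reason" in report:
        lines += [f"Stop reason: **{report.get('stop_reason')}**", ""]
    rounds = report.get("rounds", [])
    if rounds:
        lines += ["## Metrics per round", "",
                  "| round | test AUC | test BER | knee rank | #selected vars | dominant theme |",
                  "|---|---|---|---|---|---|"]
        for r in rounds:
            m = r.get("test_metrics", {})
            lines.append(
                "| {round} | {auc:.4f} | {ber:.4f} | {knee} | {nsel} | {dom} |".format(
                    round=r.get("round"),
                    auc=m.get("auc", float("nan")),
                    ber=m.get("ber", float("nan")),
                    knee=r.get("knee_rank", "-"),
                    nsel=len(r.get("selected_variables", [])),
                    dom=r.get("dominant_theme", "-"),
                )
            )
        lines.append("")
        lines += ["## Themes included/excluded per round", ""]
        all_themes = sorted({t for r in rounds for t in r.get("qualified_themes", [])})
        if all_themes:
            header = "| theme | " + " | ".join(f"round {r['round']}" for r in rounds) + " |"
            lines += [header, "|" + "---|" * (len(rounds) + 1)]
            for theme in all_themes:
                cells = []
                for r in rounds:
                    if theme == r.get("dominant_theme"):
                        cells.append("excluded")
                    elif theme in r.get("qualified_themes", []):
                        cells.append("included")
                    else:
                        cells.append("-")
                lines.append(f"| {theme} | " + " | ".join(cells) + " |")
            lines.append("")
    return "\n".join(lines)
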