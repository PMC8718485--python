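"""Four-hidden-layer feed-forward classifier with first-layer importance.

A compact, fully deterministic NumPy implementation: ReLU hidden layers,
sigmoid output, survey-weighted binary cross-entropy, Adam updates with
decoupled weight decay, mini-batches with seeded shuffling, and early
stopping on the weighted AUC of a held-out fifth of the training data.
Weight decay is what makes first-layer importance interpretable: without
it, weight magnitudes remain dominated by their random initialisation even
in a well-discriminating network; with it, weights that receive no
sustaining gradient shrink toward zero and magnitude tracks use.

Variable importance is read directly off the trained network's first
weight matrix: importance of input j is the sum of |W1[j, unit]| over the
first hidden layer's units (derivation id "sum-abs-first-layer"; an L2-norm
aggregation is selectable for sensitivity analysis).  The importance curve
is then fed to the same knee-point selector as the ridge coefficients.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .knee import CoefficientCurve, KneeResult, NoKneeError, find_knee, select_above_knee
from .metrics import weighted_auc
from .models import fit_penalized_logistic, lasso_support, select_lambda_cv

__all__ = [
    "NNConfig",
    "NNModel",
    "ImportanceRanking",
    "fit_nn",
    "first_layer_importance",
    "nn_pipeline",
]


@dataclasses.dataclass(frozen=True)
class NNConfig:
    hidden_sizes: tuple[int, int, int, int] = (64, 32, 16, 8)
    activation: str = "relu"
    epochs: int = 60
    batch_size: int = 256
    learning_rate: float = 1e-3
    weight_decay: float = 2.0
    early_stop_patience: int = 8
    importance_aggregation: str = "sum-abs-first-layer"  # or "l2-first-layer"
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_sizes) != 4 or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("exactly four positive hidden layer sizes required")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclasses.dataclass
class NNModel:
    weights: list[np.ndarray]  # W[l] has shape (fan_in, fan_out)
    biases: list[np.ndarray]
    config: NNConfig
    feature_names: tuple[str, ...] | None
    val_auc_history: list[float]
    best_epoch: int

    def predict_score(self, X) -> np.ndarray:
        """Pre-sigmoid logit score (monotone in predicted risk)."""
        a = np.asarray(X, dtype=float)
        act = _ACTIVATIONS[self.config.activation][0]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = act(a @ W + b)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.predict_score(X))


@dataclasses.dataclass(frozen=True)
class ImportanceRanking:
    importance: np.ndarray
    feature_names: tuple[str, ...]
    derivation: str

    def as_curve(self) -> CoefficientCurve:
        order = sorted(range(self.importance.size),
                       key=lambda j: (-self.importance[j], self.feature_names[j]))
        return CoefficientCurve(values=self.importance[list(order)],
                                names=tuple(self.feature_names[j] for j in order),
                                source="nn_importance")


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


def fit_nn(X, y, w=None, config: NNConfig = NNConfig(),
           feature_names=None) -> NNModel:
    """Train the classifier with Adam and early stopping on held-out AUC.

    A fifth of the rows (seeded, stratified by outcome) is held out for
    early stopping; training minimises the weighted cross-entropy on the
    rest.  The returned model carries the weights of the best-validation
    epoch.  Raises on divergent (non-finite) loss, naming the epoch.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(config.seed)

    # stratified 1/5 validation split for early stopping
    val = np.zeros(n, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        take = rng.permutation(idx)[: max(1, idx.size // 5)]
        val[take] = True
    Xtr, ytr, wtr = X[~val], y[~val], w[~val]
    Xva, yva, wva = X[val], y[val], w[val]

    sizes = [p, *config.hidden_sizes, 1]
    weights, biases, m_w, v_w, m_b, v_b = [], [], [], [], [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
        m_w.append(np.zeros((fan_in, fan_out)))
        v_w.append(np.zeros((fan_in, fan_out)))
        m_b.append(np.zeros(fan_out))
        v_b.append(np.zeros(fan_out))

    act, dact = _ACTIVATIONS[config.activation]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    t = 0
    best = (-np.inf, None, None, 0)
    history: list[float] = []
    patience_left = config.early_stop_patience
    w_mean = wtr.mean()

    # overflow in a diverging forward pass is detected explicitly via the
    # logit finiteness check; silence the intermediate numpy warnings
    old_err = np.seterr(over="ignore", invalid="ignore")
    try:
        for epoch in range(config.epochs):
            order = rng.permutation(Xtr.shape[0])
            for start in range(0, Xtr.shape[0], config.batch_size):
                batch = order[start : start + config.batch_size]
                xb, yb, wb = Xtr[batch], ytr[batch], wtr[batch]
                # forward
                pre, post = [], [xb]
                a = xb
                for W, b in zip(weights[:-1], biases[:-1]):
                    z = a @ W + b
                    pre.append(z)
                    a = act(z)
                    post.append(a)
                logit = (a @ weights[-1] + biases[-1]).ravel()
                if not np.isfinite(logit).all():
                    raise FloatingPointError(f"divergent loss at epoch {epoch}")
                prob = _sigmoid(logit)
                # backward: d(weighted BCE)/d(logit) = w*(p - y), normalised
                delta = (wb * (prob - yb) / (w_mean * len(yb)))[:, None]
                grads_w, grads_b = [None] * len(weights), [None] * len(weights)
                for layer in range(len(weights) - 1, -1, -1):
                    grads_w[layer] = post[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ weights[layer].T) * dact(pre[layer - 1])
                t += 1
                for layer in range(len(weights)):
                    for g, theta, m, v, decay in (
                            (grads_w[layer], weights[layer], m_w[layer],
                             v_w[layer], config.weight_decay),
                            (grads_b[layer], biases[layer], m_b[layer],
                             v_b[layer], 0.0)):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        mh = m / (1 - beta1**t)
                        vh = v / (1 - beta2**t)
                        # decoupled weight decay (biases exempt): weights that
                        # receive no sustaining gradient shrink toward zero, so
                        # first-layer magnitudes reflect use, not initialisation
                        theta -= lr * (mh / (np.sqrt(vh) + eps) + decay * theta)
            # early-stopping check on the held-out fifth
            model = NNModel(weights=weights, biases=biases, config=config,
                            feature_names=None, val_auc_history=[], best_epoch=0)
            scores = model.predict_score(Xva)
            auc = 0.5 if np.ptp(scores) == 0 else weighted_auc(scores, yva, wva)
            history.append(float(auc))
            if auc > best[0]:
                best = (auc, [W.copy() for W in weights],
                        [b.copy() for b in biases], epoch)
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    finally:
        np.seterr(**old_err)

    _, bw, bb, be = best
    return NNModel(weights=bw if bw is not None else weights,
                   biases=bb if bb is not None else biases,
                   config=config,
                   feature_names=tuple(feature_names) if feature_names is not None else None,
                   val_auc_history=history, best_epoch=be)


def first_layer_importance(model: NNModel) -> ImportanceRanking:
    """Aggregate |first-layer weights| per input into a nonnegative score."""
    W1 = model.weights[0]
    agg = model.config.importance_aggregation
    if agg == "sum-abs-first-layer":
        imp = np.abs(W1).sum(axis=1)
    elif agg == "l2-first-layer":
        imp = np.sqrt((W1**2).sum(axis=1))
    else:
        raise ValueError(f"unknown importance aggregation {agg!r}")
    names = model.feature_names
    if names is None:
        names = tuple(f"x{j}" for j in range(W1.shape[0]))
    return ImportanceRanking(importance=imp, feature_names=names,
                             derivation=agg)


def nn_pipeline(encoded, config: NNConfig = NNConfig(), split=None,
                lambda_grid=None, cv_seed: int = 0,
                lasso_kwargs: dict | None = None) -> dict:
    """Lasso prefilter -> NN -> first-layer importance -> knee selection.

    ``encoded`` is an :class:`~themewise.prep.EncodedMatrix`; ``split`` is a
    (train_idx, test_idx) pair (made with metrics.make_split if omitted).
    Returns a report dict with the selected features (a prefix of the
    importance ranking), the ranking itself, and test AUC/BER.
    """
    from .metrics import SplitSpec, evaluate_scores, make_split, choose_threshold

    lasso_kwargs = dict(lasso_kwargs or {})
    if split is None:
        split = make_split(encoded.n, SplitSpec(seed=cv_seed), y=encoded.y)
    tr, te = split
    Xtr, ytr, wtr = encoded.X[tr], encoded.y[tr], encoded.w[tr]
    Xte, yte, wte = encoded.X[te], encoded.y[te], encoded.w[te]

    cv = select_lambda_cv(Xtr, ytr, wtr, grid=lambda_grid, seed=cv_seed,
                          penalty="l1", **lasso_kwargs)
    fit = fit_penalized_logistic(Xtr, ytr, wtr, lam=cv.best_lambda,
                                 penalty="l1", tol=1e-6, max_iter=5000,
                                 feature_names=encoded.feature_names)
    support = list(lasso_support(fit))
    report: dict = {"lasso_lambda": cv.best_lambda, "lasso_support": support,
                    "selected_features": [], "importance": None,
                    "test_metrics": None, "knee_rank": None}
    if not support:
        return report

    cols = [encoded.feature_names.index(f) for f in support]
    model = fit_nn(Xtr[:, cols], ytr, wtr, config=config,
                   feature_names=support)
    ranking = first_layer_importance(model)
    report["importance"] = {f: float(v) for f, v in
                            zip(ranking.feature_names, ranking.importance)}
    scores_tr = model.predict_score(Xtr[:, cols])
    scores_te = model.predict_score(Xte[:, cols])
    thr = choose_threshold(scores_tr, ytr, wtr)
    metrics = evaluate_scores(scores_te, yte, wte, threshold=thr)
    report["test_metrics"] = metrics.as_dict()

    curve = ranking.as_curve()
    try:
        knee: KneeResult = find_knee(curve)
    except NoKneeError:
        report["no_knee"] = True
        return report
    report["knee_rank"] = knee.knee_rank
    report["selected_features"] = select_above_knee(curve, knee)
    return report
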