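"""Cross-domain linear classifiers built on penalized logistic regression.

All methods share one convex core: minimize a weighted sum of per-domain mean
cross-entropies plus a quadratic penalty, solved by damped Newton iteration to
a gradient norm of 1e-8.  The five fitting strategies are

* ``baseline`` - ridge logistic regression on source data only,
* ``naive``    - the same fit on pooled source + target rows,
* ``rtlc``     - regular-transfer parameter anchoring: refit on target data
  while penalizing deviation of (weights, intercept) from the source model,
* ``bw``       - balanced weighting: minimize
  (1-gamma) * L_source + gamma * L_target, with L the per-domain MEAN
  cross-entropy so gamma has a sample-size-free meaning,
* ``fa``       - feature augmentation: source rows embed as (x, x, 0) and
  target rows as (x, 0, x) over a tripled feature space (general /
  source-specific / target-specific blocks),
* ``pred``     - the source model's real-valued decision score appended as an
  extra target feature.

Predictions are binary with the tie rule score >= 0 -> label 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "LinearModel",
    "FitReport",
    "ConvergenceError",
    "fit_logistic",
    "fit_naive",
    "fit_rtlc",
    "fit_bw",
    "fit_fa",
    "fit_pred",
    "predict_labels",
    "balanced_accuracy",
]

GRAD_TOL = 1e-8
MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Solver failed to reach the gradient tolerance within max iterations."""


@dataclass
class FitReport:
    objective_value: float
    gradient_norm: float
    n_iter: int


@dataclass
class LinearModel:
    """A fitted linear decision function with optional feature augmentation.

    ``weights`` live in the model's (possibly augmented) feature space;
    ``n_input_features`` is the pre-augmentation dimension d.  For
    ``fa_triple`` the weights are the concatenated (general, source-specific,
    target-specific) blocks of length d each; for ``pred_append`` they are the
    d input weights followed by the coefficient on the source score.
    """

    weights: np.ndarray
    intercept: float
    method: str
    hyperparams: dict = field(default_factory=dict)
    feature_map: str = "identity"
    n_input_features: int | None = None
    source_model: "LinearModel | None" = None
    fit_report: FitReport | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all() or not np.isfinite(self.intercept):
            raise ValueError("model parameters must be finite")
        if self.n_input_features is None:
            self.n_input_features = len(self.weights)
        for k, v in self.hyperparams.items():
            if v < 0:
                raise ValueError(f"hyperparameter {k} must be nonnegative")
        if not 0 <= self.hyperparams.get("gamma", 0.0) <= 1:
            raise ValueError("gamma must lie in [0, 1]")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Real-valued score for target-domain inputs of d columns;
        augmentation per ``feature_map`` is applied internally."""
        X = np.asarray(X, dtype=float)
        d = self.n_input_features
        if X.shape[1] != d:
            raise ValueError(
                f"expected {d} input features, got {X.shape[1]}")
        if self.feature_map == "identity":
            return X @ self.weights + self.intercept
        if self.feature_map == "fa_triple":
            w_gen, _w_src, w_tgt = np.split(self.weights, 3)
            return X @ (w_gen + w_tgt) + self.intercept
        if self.feature_map == "pred_append":
            s = self.source_model.decision_function(X)
            return X @ self.weights[:d] + s * self.weights[d] + self.intercept
        raise ValueError(f"unknown feature_map {self.feature_map!r}")

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "method": self.method,
            "hyperparams": dict(self.hyperparams),
            "feature_map": self.feature_map,
            "n_input_features": int(self.n_input_features),
        }
        if self.source_model is not None:
            out["source_model"] = self.source_model.to_dict()
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        src = d.get("source_model")
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            method=d["method"],
            hyperparams=dict(d["hyperparams"]),
            feature_map=d["feature_map"],
            n_input_features=int(d["n_input_features"]),
            source_model=cls.from_dict(src) if src else None,
        )

    @classmethod
    def from_json(cls, s: str) -> "LinearModel":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Convex core


def _check_classes(y: np.ndarray, what: str = "input") -> None:
    y = np.asarray(y)
    if len(y) == 0 or len(np.unique(y)) < 2:
        raise ValueError(f"{what} must contain both classes")


def _minimize_newton(blocks, pen_scale, pen_center, theta0,
                     tol=GRAD_TOL, max_iter=MAX_ITER):
    """Minimize sum_g w_g * mean_CE(Xa_g theta, y_g) + sum_i c_i (theta_i-m_i)^2.

    ``blocks`` is a list of (Xa, y, weight) with Xa carrying the intercept
    column.  Damped Newton with Armijo backtracking; deterministic.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    p = len(theta)

    def value(th):
        f = 0.0
        for Xa, y, w in blocks:
            if w == 0.0 or len(y) == 0:
                continue
            z = Xa @ th
            f += w * float(np.mean(np.logaddexp(0.0, z) - y * z))
        f += float(pen_scale @ (th - pen_center) ** 2)
        return f

    def value_grad_hess(th):
        f = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        for Xa, y, w in blocks:
            if w == 0.0 or len(y) == 0:
                continue
            n = len(y)
            z = Xa @ th
            f += w * float(np.mean(np.logaddexp(0.0, z) - y * z))
            s = 1.0 / (1.0 + np.exp(-z))
            g += (w / n) * (Xa.T @ (s - y))
            H += (w / n) * ((Xa * (s * (1.0 - s))[:, None]).T @ Xa)
        diff = th - pen_center
        f += float(pen_scale @ diff ** 2)
        g += 2.0 * pen_scale * diff
        H[np.diag_indices(p)] += 2.0 * pen_scale
        return f, g, H

    f, g, H = value_grad_hess(theta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gn = float(np.linalg.norm(g))
        if gn <= tol:
            return theta, FitReport(f, gn, n_iter - 1)
        damp = 0.0
        eye = np.eye(p)
        while True:
            try:
                cf = cho_factor(H + damp * eye, lower=True)
                break
            except np.linalg.LinAlgError:
                damp = 1e-10 if damp == 0.0 else damp * 100.0
        step = cho_solve(cf, -g)
        slope = float(g @ step)
        # Armijo backtracking with an epsilon slack: near the optimum the
        # predicted decrease drops below the float64 resolution of f and the
        # plain test would reject the (safe, contracting) full Newton step
        f_eps = 1e-15 * (1.0 + abs(f))
        t = 1.0
        while t > 1e-14:
            f_new = value(theta + t * step)
            if f_new <= f + 1e-4 * t * slope + f_eps:
                break
            t *= 0.5
        theta = theta + t * step
        f, g, H = value_grad_hess(theta)
    gn = float(np.linalg.norm(g))
    if gn <= tol:
        return theta, FitReport(f, gn, n_iter)
    raise ConvergenceError(
        f"gradient norm {gn:.3e} > {tol:.0e} after {n_iter} iterations "
        "(is the data separable with zero ridge?)")


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _fit_core(blocks_raw, lam_ridge=0.0, anchor=None, lam_anchor=0.0):
    """Fit theta = (w, b). Ridge penalizes w only; anchoring penalizes both."""
    blocks = [(_augment(X), np.asarray(y, dtype=float), w)
              for X, y, w in blocks_raw]
    p = blocks[0][0].shape[1]
    pen_scale = np.zeros(p)
    pen_center = np.zeros(p)
    if lam_ridge:
        pen_scale[:-1] += lam_ridge
    theta0 = np.zeros(p)
    if anchor is not None:
        pen_scale += lam_anchor
        pen_center = np.asarray(anchor, dtype=float)
        theta0 = pen_center.copy()
    theta, report = _minimize_newton(blocks, pen_scale, pen_center, theta0)
    return theta[:-1], float(theta[-1]), report


# ---------------------------------------------------------------------------
# Public fitting strategies


def fit_logistic(X, y, lam_ridge: float = 1.0) -> LinearModel:
    """Ridge-penalized logistic regression: mean cross-entropy +
    lam_ridge * ||w||^2 (intercept unpenalized), solved to gradient norm 1e-8.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    if lam_ridge < 0:
        raise ValueError("lam_ridge must be nonnegative")
    w, b, rep = _fit_core([(X, y, 1.0)], lam_ridge=lam_ridge)
    return LinearModel(w, b, "baseline", {"lambda_ridge": lam_ridge},
                       fit_report=rep)


def fit_naive(source, target_train, lam_ridge: float = 1.0) -> LinearModel:
    """Pooled fit on row-concatenated source + target training data."""
    Xs, ys = source.X, source.y
    Xt, yt = target_train.X, target_train.y
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target feature counts differ")
    X = np.vstack([Xs, Xt]) if len(yt) else np.asarray(Xs, dtype=float)
    y = np.concatenate([ys, yt]) if len(yt) else ys
    model = fit_logistic(X, y, lam_ridge)
    model.method = "naive"
    return model

def fit_rtlc(source_model: LinearModel, target_train,
             lam_anchor: float = 1.0) -> LinearModel:
    """Regular-transfer refit: minimize the target mean cross-entropy plus
    lam_anchor * ||theta - theta_source||^2, anchoring weights AND intercept.
    """
    if source_model.feature_map != "identity":
        raise ValueError("source model must be an unaugmented linear model")
    Xt, yt = target_train.X, target_train.y
    if Xt.shape[1] != source_model.n_input_features:
        raise ValueError("target features do not match source model")
    _check_classes(yt, "target")
    if not lam_anchor > 0:
        raise ValueError("lam_anchor must be positive")
    anchor = np.append(source_model.weights, source_model.intercept)
    w, b, rep = _fit_core([(Xt, yt, 1.0)], anchor=anchor,
                          lam_anchor=lam_anchor)
    return LinearModel(w, b, "rtlc", {"lambda_anchor": lam_anchor},
                       fit_report=rep)


def fit_bw(source, target_train, gamma: float = 0.5,
           lam_ridge: float = 1.0) -> LinearModel:
    """Balanced weighting: minimize
    (1-gamma) * L_source + gamma * L_target + lam_ridge * ||w||^2,
    each L the per-domain MEAN cross-entropy."""
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    Xs, ys = source.X, source.y
    Xt, yt = target_train.X, target_train.y
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target feature counts differ")
    _check_classes(ys, "source")
    _check_classes(yt, "target")
    w, b, rep = _fit_core(
        [(Xs, ys, 1.0 - gamma), (Xt, yt, gamma)], lam_ridge=lam_ridge)
    return LinearModel(w, b, "bw",
                       {"gamma": gamma, "lambda_ridge": lam_ridge},
                       fit_report=rep)


def fit_fa(source, target_train, lam_ridge: float = 1.0) -> LinearModel:
    """Feature-augmentation fit over a tripled (general/source/target) space.

    Source rows embed as (x, x, 0), target rows as (x, 0, x); a single pooled
    logistic fit learns all three blocks.  Target prediction uses (x, 0, x).
    """
    Xs, ys = np.asarray(source.X, float), source.y
    Xt, yt = np.asarray(target_train.X, float), target_train.y
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target feature counts differ")
    d = Xs.shape[1]
    Zs = np.hstack([Xs, Xs, np.zeros_like(Xs)])
    Zt = np.hstack([Xt, np.zeros_like(Xt), Xt])
    Z = np.vstack([Zs, Zt])
    y = np.concatenate([ys, yt])
    _check_classes(y)
    w, b, rep = _fit_core([(Z, y, 1.0)], lam_ridge=lam_ridge)
    return LinearModel(w, b, "fa", {"lambda_ridge": lam_ridge},
                       feature_map="fa_triple", n_input_features=d,
                       fit_report=rep)


def fit_pred(source_model: LinearModel, target_train,
             lam_ridge: float = 1.0) -> LinearModel:
    """Append the source model's decision score as one extra target feature
    and fit a logistic classifier on the augmented target data."""
    Xt, yt = np.asarray(target_train.X, float), target_train.y
    if Xt.shape[1] != source_model.n_input_features:
        raise ValueError("target features do not match source model")
    _check_classes(yt, "target")
    s = source_model.decision_function(Xt)
    Z = np.hstack([Xt, s[:, None]])
    w, b, rep = _fit_core([(Z, yt, 1.0)], lam_ridge=lam_ridge)
    return LinearModel(w, b, "pred", {"lambda_ridge": lam_ridge},
                       feature_map="pred_append", n_input_features=Xt.shape[1],
                       source_model=source_model, fit_report=rep)


# ---------------------------------------------------------------------------
# Prediction and scoring


def predict_labels(model: LinearModel, X) -> np.ndarray:
    """Binary labels from decision scores; score exactly 0 maps to label 1."""
    return (model.decision_function(X) >= 0.0).astype(int)


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of the two per-class recalls; chance level is 0.5."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    pos = y_true == 1
    neg = y_true == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy undefined: y_true is single-class")
    recall_pos = float(np.mean(y_pred[pos] == 1))
    recall_neg = float(np.mean(y_pred[neg] == 0))
    return 0.5 * (recall_pos + recall_neg)
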