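"""Classifiers and evaluation statistics for fused paired-case data.

Four model families operate on the PTO feature matrix:

* a two-class linear discriminant (pooled-covariance Fisher form) reported
  as an affine score ``f_calc = a0 + sum_k a_k x_k``, optionally preceded
  by forward-stepwise (FSW) selection under the Wilks-lambda criterion and
  merged with an expert-guided (EGS) forced-in/forced-out list;
* a linear neural network (LNN; no hidden layer — logistic regression),
  a one-hidden-layer perceptron (MLP, 11 units) and a two-hidden-layer
  network (DLN, 10+10 units), all sigmoid networks trained on
  cross-entropy.

Evaluation reports sensitivity, specificity and accuracy (percent),
the Pearson chi-square of the 2x2 predicted-vs-observed table with its
p-level, and the rank-based AUROC; robustness summarizes mean and sample
standard deviation of each statistic across working samples.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.neural_network import MLPClassifier

log = logging.getLogger(__name__)

#: Sentinel for statistics that are undefined on the given data (e.g. a
#: class entirely absent). Callers should test with ``math.isnan``.
UNDEFINED = float("nan")

#: Default epoch budgets per architecture (backprop passes; the deeper
#: network gets a 20-epoch refinement on top of its 100).
DEFAULT_EPOCHS = {(): 200, (11,): 96, (10, 10): 120}


def _as_matrix(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
        np.asarray(X, dtype=float)


# Linear discriminant --------------------------------------------------------

@dataclass
class LinearModel:
    """Affine discriminant score with a classification threshold.

    ``score = a0 + sum a_k x_k`` is the log posterior-odds under the
    equal-covariance Gaussian model, so the logistic map of the score is a
    probability. Classify 1 iff score > threshold (default 0).
    """

    intercept: float
    coefficients: dict[str, float]
    selected_features: tuple[str, ...]
    threshold: float = 0.0

    def __post_init__(self):
        extra = set(self.coefficients) - set(self.selected_features)
        if extra:
            raise ValueError(f"coefficients for unselected features: {extra}")
        if not all(math.isfinite(v) for v in
                   (self.intercept, *self.coefficients.values())):
            raise ValueError("model parameters must be finite")

    def score(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept)
        for name, a in self.coefficients.items():
            out = out + a * X[name].to_numpy(dtype=float)
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.score(X) > self.threshold).astype(int)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.score(X)))

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "kind": "linear", "intercept": self.intercept,
            "coefficients": self.coefficients,
            "selected_features": list(self.selected_features),
            "threshold": self.threshold}, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        d = json.loads(Path(path).read_text())
        return cls(d["intercept"], d["coefficients"],
                   tuple(d["selected_features"]), d["threshold"])


def fit_linear(X: pd.DataFrame, y, training_mask=None,
               features: tuple[str, ...] | None = None) -> LinearModel:
    """Two-class Fisher discriminant with pooled covariance.

    The score includes the log prior-odds term, making it the Gaussian
    log posterior odds. A singular pooled covariance is ridge-regularized
    (1e-8, trace-scaled) and logged.
    """
    features = tuple(features) if features is not None else tuple(X.columns)
    mask = np.ones(len(X), bool) if training_mask is None \
        else np.asarray(training_mask, bool)
    Xt = X.loc[mask, list(features)].to_numpy(dtype=float)
    yt = np.asarray(y)[mask].astype(int)
    if not np.isfinite(Xt).all():
        raise ValueError("features must be finite")
    n1, n0 = int(yt.sum()), int((1 - yt).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("training rows must contain both classes")
    X0, X1 = Xt[yt == 0], Xt[yt == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1)
         + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
    S = np.atleast_2d(S)
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(S) / S.shape[0]
        log.warning("singular pooled covariance: ridge-regularizing (%.3g)", ridge)
        w = np.linalg.solve(S + ridge * np.eye(S.shape[0]), mu1 - mu0)
    a0 = float(-0.5 * w @ (mu0 + mu1) + math.log(n1 / n0))
    return LinearModel(intercept=a0,
                       coefficients=dict(zip(features, map(float, w))),
                       selected_features=features)


# Forward-stepwise selection -------------------------------------------------

def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Two-class Wilks lambda = det(W)/det(T) for the given columns."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for cls in (0, 1):
        Xg = X[y == cls]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    sT, ldT = np.linalg.slogdet(np.atleast_2d(T))
    sW, ldW = np.linalg.slogdet(np.atleast_2d(W))
    if sT <= 0 or sW <= 0:
        return 1.0  # degenerate scatter: no discriminable variation
    return float(np.exp(ldW - ldT))


def forward_stepwise(X: pd.DataFrame, y, training_mask=None,
                     alpha: float = 0.05,
                     max_features: int | None = None,
                     forced_in: tuple[str, ...] = (),
                     forced_out: tuple[str, ...] = ()) -> tuple[str, ...]:
    """Greedy forward selection under the Wilks-lambda partial-F criterion.

    At each step the candidate with the largest F-to-enter joins the model
    if its p-value is below ``alpha``; selection stops when none qualifies
    or ``max_features`` is reached. ``forced_in``/``forced_out`` implement
    expert-guided selection: forced-in features are seated first and never
    removed, forced-out ones are never considered. Deterministic given its
    inputs (ties resolve to the earlier column).
    """
    mask = np.ones(len(X), bool) if training_mask is None \
        else np.asarray(training_mask, bool)
    Xt = X.loc[mask]
    yt = np.asarray(y)[mask].astype(int)
    selected = [f for f in forced_in if f in X.columns]
    candidates = [c for c in X.columns
                  if c not in selected and c not in forced_out]
    n = len(Xt)
    g = 2
    while candidates:
        if max_features is not None and len(selected) >= max_features:
            break
        p = len(selected)
        lam_base = _wilks_lambda(Xt[selected].to_numpy(float), yt) \
            if selected else 1.0
        best = None
        for c in candidates:
            lam = _wilks_lambda(Xt[selected + [c]].to_numpy(float), yt)
            if lam <= 0:
                lam = np.finfo(float).tiny
            F = (lam_base / lam - 1.0) * (n - g - p) / (g - 1)
            if best is None or F > best[1]:
                best = (c, F)
        c, F = best
        p_value = stats.f.sf(F, g - 1, n - g - p) if F >= 0 else 1.0
        if p_value >= alpha:
            break
        selected.append(c)
        candidates.remove(c)
        log.info("FSW: entered %r (F=%.3f, p=%.3g)", c, F, p_value)
    return tuple(selected)


# Neural models --------------------------------------------------------------

@dataclass
class NetworkModel:
    """Sigmoid feed-forward network in stored-weight form.

    ``architecture`` lists hidden-layer widths: ``()`` is the linear
    neural network (logistic regression), ``(11,)`` the one-hidden-layer
    perceptron and ``(10, 10)`` the deep variant. The forward pass is
    reproduced from the stored weights, so scoring is independent of the
    fitting backend.
    """

    architecture: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_names: tuple[str, ...]
    epochs: int
    seed: int
    activation: str = "logistic"

    def __post_init__(self):
        if any(wd < 1 for wd in self.architecture):
            raise ValueError("hidden-layer widths must be >= 1")
        widths = [len(self.feature_names), *self.architecture, 1]
        for ell, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            if self.weights[ell].shape != (a, b):
                raise ValueError(
                    f"layer {ell}: weight shape {self.weights[ell].shape} "
                    f"inconsistent with architecture {widths}")

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Pre-sigmoid output (log-odds scale)."""
        h = _as_matrix(X[list(self.feature_names)]
                       if isinstance(X, pd.DataFrame) else X)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = 1.0 / (1.0 + np.exp(-(h @ W + b)))
        return (h @ self.weights[-1] + self.biases[-1]).ravel()

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.score(X)))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "kind": "network", "architecture": list(self.architecture),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_names": list(self.feature_names),
            "epochs": self.epochs, "seed": self.seed}, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["architecture"]),
                   [np.asarray(w) for w in d["weights"]],
                   [np.asarray(b) for b in d["biases"]],
                   tuple(d["feature_names"]), d["epochs"], d["seed"])


def fit_network(X: pd.DataFrame, y, training_mask=None,
                architecture: tuple[int, ...] = (11,),
                epochs: int | None = None, seed: int = 0,
                learning_rate: float = 1e-3) -> NetworkModel:
    """Train a sigmoid network on cross-entropy; expects standardized
    features. Seeded weight initialization makes identical configs yield
    identical weights."""
    architecture = tuple(architecture)
    epochs = epochs if epochs is not None else DEFAULT_EPOCHS.get(architecture, 100)
    mask = np.ones(len(X), bool) if training_mask is None \
        else np.asarray(training_mask, bool)
    names = tuple(X.columns)
    Xt = X.loc[mask].to_numpy(dtype=float)
    yt = np.asarray(y)[mask].astype(int)
    if len(np.unique(yt)) < 2:
        raise ValueError("training rows must contain both classes")

    if architecture == ():
        est = LogisticRegression(max_iter=max(epochs, 100), C=1e6,
                                 solver="lbfgs")
        est.fit(Xt, yt)
        weights = [est.coef_.T.copy()]
        biases = [est.intercept_.copy()]
    else:
        est = MLPClassifier(hidden_layer_sizes=architecture,
                            activation="logistic", solver="adam",
                            learning_rate_init=learning_rate,
                            max_iter=epochs, random_state=seed,
                            batch_size=min(200, len(Xt)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xt, yt)
        weights = [w.copy() for w in est.coefs_]
        biases = [b.copy() for b in est.intercepts_]
    if any(not np.isfinite(w).all() for w in weights):
        raise RuntimeError(
            f"network training diverged (non-finite weights); config: "
            f"architecture={architecture}, epochs={epochs}, seed={seed}, "
            f"learning_rate={learning_rate}")
    return NetworkModel(architecture=architecture, weights=weights,
                        biases=biases, feature_names=names,
                        epochs=epochs, seed=seed)


# Metrics --------------------------------------------------------------------

@dataclass
class MetricsRecord:
    """Confusion counts and derived statistics for one subset."""

    subset: str
    tp: int
    fn: int
    tn: int
    fp: int
    chi2: float = UNDEFINED
    p_level: float = UNDEFINED
    auroc: float = UNDEFINED

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sn(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else UNDEFINED

    @property
    def sp(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else UNDEFINED

    @property
    def ac(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else UNDEFINED

    def to_dict(self) -> dict:
        return {"subset": self.subset, "tp": self.tp, "fn": self.fn,
                "tn": self.tn, "fp": self.fp, "n": self.n,
                "Sn": self.sn, "Sp": self.sp, "Ac": self.ac,
                "chi2": self.chi2, "p_level": self.p_level,
                "auroc": self.auroc}


def confusion_metrics(predicted, observed, subset: str = "t",
                      scores=None) -> MetricsRecord:
    """Confusion counts, Sn/Sp/Ac, Pearson chi-square of the 2x2
    predicted-vs-observed table, and (when scores are given) the AUROC.
    Statistics undefined on the data (an absent class) come back as the
    NaN sentinel rather than raising."""
    pred = np.asarray(predicted).astype(int)
    obs = np.asarray(observed).astype(int)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    tp = int(((pred == 1) & (obs == 1)).sum())
    fn = int(((pred == 0) & (obs == 1)).sum())
    tn = int(((pred == 0) & (obs == 0)).sum())
    fp = int(((pred == 1) & (obs == 0)).sum())
    table = np.array([[tn, fp], [fn, tp]])
    chi2 = p_level = UNDEFINED
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p_level, _, _ = stats.chi2_contingency(table, correction=False)
    rec = MetricsRecord(subset=subset, tp=tp, fn=fn, tn=tn, fp=fp,
                        chi2=float(chi2), p_level=float(p_level))
    if scores is not None:
        rec.auroc = auroc(scores, obs)
    return rec


def auroc(scores, observed) -> float:
    """Rank-based (Mann-Whitney) AUROC; ties count one half. Returns the
    NaN sentinel when only one class is present."""
    obs = np.asarray(observed).astype(int)
    if obs.min() == obs.max():
        return UNDEFINED
    return float(roc_auc_score(obs, np.asarray(scores, dtype=float)))


@dataclass
class RobustnessSummary:
    """Mean and sample SDV of each statistic across working samples."""

    n_samples: int
    mean: dict[str, float]
    sdv: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.sdv.values() if not math.isnan(v)):
            raise ValueError("SDV must be >= 0")


_ROBUST_FIELDS = ("Sn", "Sp", "Ac", "chi2", "auroc", "tp", "fn", "tn", "fp")


def robustness(records: list[MetricsRecord]) -> RobustnessSummary:
    """Cross-sample mean and sample standard deviation of each metric and
    confusion count. Records should describe the same model family and
    subset across samples."""
    if len(records) < 2:
        raise ValueError("robustness needs at least 2 samples")
    mean, sdv = {}, {}
    for name in _ROBUST_FIELDS:
        vals = np.array([r.to_dict()[name] for r in records], dtype=float)
        if np.isnan(vals).any():
            mean[name] = sdv[name] = UNDEFINED
        else:
            mean[name] = float(vals.mean())
            sdv[name] = float(vals.std(ddof=1))
    return RobustnessSummary(n_samples=len(records), mean=mean, sdv=sdv)


def input_sensitivity(model, X: pd.DataFrame, y, subset_mask=None,
                      training_mask=None) -> dict[str, float]:
    """Leave-one-feature-at-mean sensitivity ratios.

    Each feature column is replaced by its training mean and the
    cross-entropy loss is recomputed on the subset rows; the ratio to the
    baseline loss is ~1 for an uninformative feature and > 1 for an
    informative one. Constant (zeroed) columns report 0 by convention.
    """
    mask = np.ones(len(X), bool) if subset_mask is None \
        else np.asarray(subset_mask, bool)
    tmask = mask if training_mask is None else np.asarray(training_mask, bool)
    Xs = X.loc[mask]
    ys = np.asarray(y)[mask].astype(int)
    base = log_loss(ys, model.predict_proba(Xs), labels=[0, 1])
    out = {}
    for name in X.columns:
        col = X.loc[tmask, name].to_numpy(dtype=float)
        if col.std() == 0.0:
            out[name] = 0.0
            continue
        Xp = Xs.copy()
        Xp[name] = col.mean()
        out[name] = float(log_loss(ys, model.predict_proba(Xp),
                                   labels=[0, 1]) / base)
    return out
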