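"""Probabilistic Classification Vector Machine (PCVM).

A sparse probabilistic kernel classifier for binary labels y ∈ {−1, +1}:

    l(x) = ψ( Σ_i w_i φ_{i,θ}(x) + b ),   ψ = standard normal CDF (probit),

with Gaussian-RBF basis functions centred on training points. Each weight
carries a truncated-Gaussian prior restricted to sign(w_i) = y_i, which
drives most weights to zero during training; the surviving basis points play
the role of "classification vectors". Training is expectation–maximization:
the E-step takes the truncated-normal mean of the probit latent variable and
the posterior mean of the per-weight precision hyperparameters, the M-step
solves a ridge-type system for the weights and bias, and basis points whose
precision exceeds ``prune_threshold`` are removed.

The sign constraint is handled by reparametrizing w_i = y_i·ŵ_i with
ŵ_i ≥ 0, so w_i·y_i ≥ 0 holds after every iteration by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

__all__ = ["probit_link", "PCVMModel", "Predictions", "PCVMConfig",
           "PCVMClassifier", "pcvm_train", "pcvm_predict",
           "select_kernel_width"]

_JITTER = 1e-10  # keeps 1/w² finite at exact zeros


def probit_link(z):
    """Probit link ψ(z): the standard normal CDF, mapping scores to
    probabilities in (0, 1). Monotone; ψ(−z) = 1 − ψ(z)."""
    return norm.cdf(z)


def _rbf_kernel(A: np.ndarray, B: np.ndarray, width: float) -> np.ndarray:
    """Gaussian kernel exp(−‖a−b‖²/θ²) between row sets A and B."""
    d2 = (np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-np.clip(d2, 0.0, None) / width**2)


@dataclass(frozen=True)
class PCVMConfig:
    """Training hyperparameters.

    kernel_width
        RBF width θ; ``None`` selects it by cross-validation over a log grid
        around the median pairwise distance (see ``select_kernel_width``).
    prune_threshold
        Basis points whose weight precision ᾱ_i = 1/ŵ_i² exceeds this are
        removed (default 1e6, i.e. |ŵ_i| < 1e−3).
    """

    kernel_width: float | None = None
    max_iter: int = 500
    tol: float = 1e-4
    prune_threshold: float = 1e6
    seed: int = 0
    cv_folds: int = 10
    width_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class PCVMModel:
    """A trained PCVM: retained basis points and their signed weights."""

    basis_points: np.ndarray     # (n_basis, d)
    basis_labels: np.ndarray     # (n_basis,) ±1 labels of the basis points
    weights: np.ndarray          # (n_basis,) signed, w_i·y_i ≥ 0
    bias: float
    kernel_width: float
    prune_threshold: float
    training_log: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.weights * self.basis_labels < -1e-12):
            raise ValueError("weight signs must agree with basis-point labels")

    @property
    def n_basis(self) -> int:
        return len(self.weights)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.basis_points.shape[1]:
            raise ValueError(
                f"expected {self.basis_points.shape[1]} features, "
                f"got {X.shape[1]}")
        K = _rbf_kernel(X, self.basis_points, self.kernel_width)
        return K @ self.weights + self.bias

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "shpcvm-pcvm",
            "version": 1,
            "basis_points": self.basis_points.tolist(),
            "basis_labels": self.basis_labels.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "kernel_width": self.kernel_width,
            "prune_threshold": self.prune_threshold,
            "training_log": self.training_log,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCVMModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "shpcvm-pcvm":
            raise ValueError("not a PCVM model file")
        return cls(
            basis_points=np.array(d["basis_points"], dtype=float),
            basis_labels=np.array(d["basis_labels"], dtype=float),
            weights=np.array(d["weights"], dtype=float),
            bias=float(d["bias"]),
            kernel_width=float(d["kernel_width"]),
            prune_threshold=float(d["prune_threshold"]),
            training_log=d.get("training_log", {}),
        )


@dataclass(frozen=True)
class Predictions:
    """Per-sample probability of the active class and the hard ±1 label
    (thresholded at 0.5; ties resolve to +1)."""

    prob: np.ndarray
    label: np.ndarray

    def __post_init__(self):
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Training


def _em_fit(K: np.ndarray, y: np.ndarray, cfg: PCVMConfig, rng) -> tuple:
    """EM loop on a fixed kernel matrix; returns (keep_idx, ŵ, b, log)."""
    n = len(y)
    M = K * y[None, :]                      # columns scaled by basis labels
    keep = np.arange(n)
    w_hat = np.abs(rng.normal(0.0, 0.1, size=n))   # ŵ ≥ 0 at init
    b = float(rng.normal(0.0, 0.1))  # exactly 0 would pin β̄ = 1/b² at ∞
    loglik_trace: list[float] = []
    sign_margin_trace: list[float] = []   # min w_i·y_i after each iteration
    converged = False
    delta = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Mk = M[:, keep]
        eta = Mk @ w_hat + b
        # E-step: mean of the probit latent variable truncated to the side
        # of the observed label: z̄ = η + y·N(η)/Ψ(yη).
        z_bar = eta + y * norm.pdf(eta) / np.clip(norm.cdf(y * eta), 1e-12, None)
        # E-step for the hyperparameters (posterior means under the
        # sparsity-inducing priors).
        alpha = 1.0 / (w_hat**2 + _JITTER)
        beta = 1.0 / (b**2 + _JITTER)
        # M-step: ridge system for the non-negative weights, then the bias.
        A = Mk.T @ Mk + np.diag(alpha)
        w_new = np.linalg.solve(A, Mk.T @ (z_bar - b))
        w_new = np.clip(w_new, 0.0, None)   # MAP under the truncated prior
        b_new = float(np.sum(z_bar - Mk @ w_new) / (n + beta))

        delta = float(np.max(np.abs(w_new - w_hat))) if len(w_new) else 0.0
        delta = max(delta, abs(b_new - b))
        w_hat, b = w_new, b_new

        # Prune basis points whose precision blew up.
        alive = 1.0 / (w_hat**2 + _JITTER) <= cfg.prune_threshold
        if not alive.all() and alive.any():
            keep = keep[alive]
            w_hat = w_hat[alive]

        eta = M[:, keep] @ w_hat + b
        loglik_trace.append(float(np.sum(np.log(
            np.clip(norm.cdf(y * eta), 1e-300, None)))))
        sign_margin_trace.append(float(w_hat.min()) if len(w_hat) else 0.0)
        if delta < cfg.tol:
            converged = True
            break
    log = {"n_iter": it, "final_change": delta, "converged": converged,
           "loglik_trace": loglik_trace,
           "sign_margin_trace": sign_margin_trace}
    return keep, w_hat, b, log


def select_kernel_width(X: np.ndarray, y: np.ndarray,
                        cfg: PCVMConfig) -> float:
    """Pick the RBF width by stratified k-fold CV accuracy over a log grid
    of multiples of the median pairwise distance."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    d2 = (np.sum(X**2, axis=1)[:, None] + np.sum(X**2, axis=1)[None, :]
          - 2.0 * X @ X.T)
    med = float(np.sqrt(np.clip(np.median(d2[np.triu_indices(len(X), 1)]),
                                1e-12, None)))
    widths = [med * g for g in cfg.width_grid]
    folds = min(cfg.cv_folds, int(np.bincount(((np.asarray(y) + 1) // 2)
                                              .astype(int)).min()))
    folds = max(folds, 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    best_w, best_acc = widths[0], -np.inf
    for width in widths:
        accs = []
        for tr, te in skf.split(X, y):
            sub_cfg = PCVMConfig(kernel_width=width, max_iter=cfg.max_iter,
                                 tol=cfg.tol,
                                 prune_threshold=cfg.prune_threshold,
                                 seed=cfg.seed)
            try:
                model = pcvm_train(X[tr], y[tr], sub_cfg)
            except ValueError:   # a fold lost one class entirely
                continue
            pred = pcvm_predict(model, X[te])
            accs.append(float(np.mean(pred.label == y[te])))
        acc = float(np.mean(accs)) if accs else -np.inf
        if acc > best_acc + 1e-12:
            best_acc, best_w = acc, width
    return best_w


def pcvm_train(X: np.ndarray, y: np.ndarray,
               cfg: PCVMConfig | None = None) -> PCVMModel:
    """Train a PCVM on features X (n × d) and ±1 labels y."""
    cfg = cfg or PCVMConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be -1/+1")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) < 4:
        raise ValueError("need at least 4 training samples")

    width = cfg.kernel_width
    if width is None:
        width = select_kernel_width(X, y, cfg)
    rng = np.random.default_rng(cfg.seed)
    K = _rbf_kernel(X, X, width)
    keep, w_hat, b, log = _em_fit(K, y, cfg, rng)
    return PCVMModel(
        basis_points=X[keep],
        basis_labels=y[keep],
        weights=w_hat * y[keep],       # back to signed weights
        bias=b,
        kernel_width=width,
        prune_threshold=cfg.prune_threshold,
        training_log=log,
    )


def pcvm_predict(model: PCVMModel, X: np.ndarray) -> Predictions:
    """Predict active-class probabilities ψ(Φ_θ(x)·w + b) and ±1 labels."""
    prob = probit_link(model.decision_function(X))
    label = np.where(prob >= 0.5, 1, -1)
    return Predictions(prob=prob, label=label)


class PCVMClassifier:
    """scikit-learn style wrapper: fit / predict / predict_proba.

    Parameters mirror :class:`PCVMConfig`; after ``fit`` the trained
    :class:`PCVMModel` is available as ``model_``.
    """

    def __init__(self, kernel_width: float | None = None, max_iter: int = 500,
                 tol: float = 1e-4, prune_threshold: float = 1e6,
                 seed: int = 0, cv_folds: int = 10):
        self.kernel_width = kernel_width
        self.max_iter = max_iter
        self.tol = tol
        self.prune_threshold = prune_threshold
        self.seed = seed
        self.cv_folds = cv_folds

    def _config(self) -> PCVMConfig:
        return PCVMConfig(kernel_width=self.kernel_width,
                          max_iter=self.max_iter, tol=self.tol,
                          prune_threshold=self.prune_threshold,
                          seed=self.seed, cv_folds=self.cv_folds)

    def fit(self, X, y):
        self.model_ = pcvm_train(X, y, self._config())
        return self

    def predict(self, X):
        return pcvm_predict(self.model_, X).label

    def predict_proba(self, X):
        p = pcvm_predict(self.model_, X).prob
        return np.column_stack([1.0 - p, p])

    def get_params(self, deep=True):
        return {"kernel_width": self.kernel_width, "max_iter": self.max_iter,
                "tol": self.tol, "prune_threshold": self.prune_threshold,
                "seed": self.seed, "cv_folds": self.cv_folds}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
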