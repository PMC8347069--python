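"""PCA dimensionality reduction and the gesture-recognition network.

The classifier is a single-hidden-layer feedforward network — 18 tansig
(hyperbolic tangent) hidden units and a softmax output layer, one unit per
gesture class — trained by Levenberg-Marquardt (LM) on the sum of squared
errors between the softmax outputs and one-hot targets, with
validation-based early stopping.

LM interpolates between Gauss-Newton and gradient descent through a
damping factor mu: each epoch solves the damped normal equations

    (J^T J + mu I) delta = -J^T r

for the residual Jacobian J (computed analytically by backpropagation).
A step that lowers the training error is accepted and mu is decreased;
otherwise mu is increased and the step re-solved, up to a cap mu_max.
Training stops at the epoch cap, when mu exceeds its cap, or when the
validation error has not improved for ``patience`` consecutive epochs;
the weights at the best validation epoch are returned.

Feature vectors are centred, scaled to unit variance and projected onto
the principal components that capture a cumulative 0.95 of the variance
before entering the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import FeatureTable

__all__ = [
    "PcaModel",
    "NetConfig",
    "MlpWeights",
    "GestureClassifier",
    "ConvergenceError",
    "fit_pca",
    "transform",
    "init_weights",
    "forward",
    "train_network",
    "predict",
    "fit_classifier",
    "save_classifier",
    "load_classifier",
]


class ConvergenceError(RuntimeError):
    """Raised when LM training encounters a non-finite error.

    Carries the per-epoch training log in ``log``.
    """

    def __init__(self, message: str, log: list[dict]):
        super().__init__(message)
        self.log = log


# --------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    """Standardising principal-component reduction.

    ``components`` has one orthonormal column per retained component;
    ``explained`` holds the variance fraction of every component (not just
    the retained ones).  ``n_out`` is the smallest k whose cumulative
    explained variance reaches ``variance_threshold``.
    """

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    variance_threshold: float
    explained: np.ndarray

    @property
    def n_in(self) -> int:
        return self.components.shape[0]

    @property
    def n_out(self) -> int:
        return self.components.shape[1]


def fit_pca(
    table: FeatureTable | np.ndarray,
    threshold: float = 0.95,
    standardize: bool = True,
) -> PcaModel:
    """Fit a PCA retaining the minimal components reaching ``threshold``.

    Features are centred and (by default) scaled to unit variance before
    the eigendecomposition — the six features mix counts and amplitudes of
    very different magnitudes.  Component signs are fixed by making each
    component's largest-magnitude loading positive, so the fit is fully
    deterministic.
    """
    X = table.matrix if isinstance(table, FeatureTable) else np.asarray(table, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not (0 < threshold <= 1):
        raise ValueError("variance threshold must be in (0, 1]")

    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        # constant columns (e.g. WAMP at zero threshold) carry no variance;
        # leave them unscaled rather than dividing by zero
        scale = np.where(scale == 0, 1.0, scale)
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale

    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total == 0:
        raise ValueError("degenerate input: no variance")
    explained = ev / total
    cum = np.cumsum(explained)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(cum))

    components = Vt[:k].T.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(components[:, j])))
        if components[i, j] < 0:
            components[:, j] = -components[:, j]

    return PcaModel(
        mean=mean,
        scale=scale,
        components=components,
        variance_threshold=threshold,
        explained=explained,
    )


def transform(pca: PcaModel, rows: np.ndarray) -> np.ndarray:
    """Project rows onto the retained components."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != pca.n_in:
        raise ValueError(f"expected {pca.n_in} columns, got {X.shape[1]}")
    return ((X - pca.mean) / pca.scale) @ pca.components


# --------------------------------------------------------------------------
# Network


@dataclass(frozen=True)
class NetConfig:
    """Architecture and LM training-schedule parameters."""

    hidden_units: int = 18
    max_epochs: int = 1000
    patience: int = 6
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        for name in ("mu_init", "mu_inc", "mu_dec", "mu_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MlpWeights:
    """Weights of the two-layer network (hidden tansig, output softmax)."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (n_out, hidden)
    b2: np.ndarray  # (n_out,)

    def copy(self) -> "MlpWeights":
        return MlpWeights(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def unpack(self, theta: np.ndarray) -> "MlpWeights":
        h, d = self.W1.shape
        k = self.W2.shape[0]
        i = 0
        W1 = theta[i : i + h * d].reshape(h, d); i += h * d
        b1 = theta[i : i + h]; i += h
        W2 = theta[i : i + k * h].reshape(k, h); i += k * h
        b2 = theta[i : i + k]
        return MlpWeights(W1.copy(), b1.copy(), W2.copy(), b2.copy())


def init_weights(n_in: int, hidden: int, n_out: int, seed: int) -> MlpWeights:
    """Seeded uniform[-0.5, 0.5] initialisation scaled by 1/sqrt(fan-in)."""
    rng = np.random.default_rng(seed)
    return MlpWeights(
        W1=rng.uniform(-0.5, 0.5, (hidden, n_in)) / np.sqrt(n_in),
        b1=rng.uniform(-0.5, 0.5, hidden) / np.sqrt(n_in),
        W2=rng.uniform(-0.5, 0.5, (n_out, hidden)) / np.sqrt(hidden),
        b2=rng.uniform(-0.5, 0.5, n_out) / np.sqrt(hidden),
    )


def forward(w: MlpWeights, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass; returns (hidden activations, softmax probabilities)."""
    A = np.tanh(X @ w.W1.T + w.b1)
    Z = A @ w.W2.T + w.b2
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    Y = E / E.sum(axis=1, keepdims=True)
    return A, Y


def _sse(w: MlpWeights, X: np.ndarray, T: np.ndarray) -> float:
    _, Y = forward(w, X)
    return float(np.sum((Y - T) ** 2))


def _jacobian(w: MlpWeights, X: np.ndarray, A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the per-sample residuals r = y - t w.r.t. weights.

    Rows are (sample, output) residuals flattened; columns follow
    ``MlpWeights.pack`` order.
    """
    n, d = X.shape
    k, h = w.W2.shape
    # softmax Jacobian S[n, out, logit] = y_out (delta - y_logit)
    S = -Y[:, :, None] * Y[:, None, :]
    idx = np.arange(k)
    S[:, idx, idx] += Y
    # back through the hidden layer: G[n, out, hidden]
    G = (S @ w.W2) * (1.0 - A**2)[:, None, :]

    J_W1 = np.einsum("nkj,ni->nkji", G, X).reshape(n * k, h * d)
    J_b1 = G.reshape(n * k, h)
    J_W2 = np.einsum("nkm,nj->nkmj", S, A).reshape(n * k, k * h)
    J_b2 = S.reshape(n * k, k)
    return np.concatenate([J_W1, J_b1, J_W2, J_b2], axis=1)


def lm_step(
    w: MlpWeights, X: np.ndarray, T: np.ndarray, mu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One damped Gauss-Newton solve; returns (delta, gradient, residuals).

    Exposed separately so the mu -> infinity gradient-descent limit and the
    descent property can be examined directly.
    """
    A, Y = forward(w, X)
    r = (Y - T).ravel()
    J = _jacobian(w, X, A, Y)
    g = J.T @ r
    H = J.T @ J
    H[np.diag_indices_from(H)] += mu
    delta = np.linalg.solve(H, -g)
    return delta, g, r


def train_network(
    X: np.ndarray,
    y: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    cfg: NetConfig | None = None,
    labels: list[str] | None = None,
) -> tuple[MlpWeights, list[str], list[dict]]:
    """Train the network by Levenberg-Marquardt with early stopping.

    ``y`` / ``yval`` are class labels (any hashable); targets are their
    one-hot encodings over ``labels`` (default: order of first appearance
    in ``y``).  Returns the weights of the best-validation epoch, the label
    order, and the per-epoch log (train/validation SSE and mu).
    """
    cfg = cfg or NetConfig()
    X = np.asarray(X, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    y = np.asarray(y)
    yval = np.asarray(yval)
    if labels is None:
        labels = list(dict.fromkeys(y.tolist()))
    if Xval.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    if X.shape[0] < len(labels):
        raise ValueError("need at least one training row per class")
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    try:
        T = np.eye(len(labels))[[lab_idx[v] for v in y.tolist()]]
        Tval = np.eye(len(labels))[[lab_idx[v] for v in yval.tolist()]]
    except KeyError as exc:
        raise ValueError(f"label {exc} not in label list") from exc

    w = init_weights(X.shape[1], cfg.hidden_units, len(labels), cfg.seed)
    theta = w.pack()
    mu = cfg.mu_init
    train_err = _sse(w, X, T)
    best_val = _sse(w, Xval, Tval)
    best_w = w.copy()
    bad_epochs = 0
    log: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        A, Y = forward(w, X)
        r = (Y - T).ravel()
        J = _jacobian(w, X, A, Y)
        g = J.T @ r
        H = J.T @ J
        diag = np.diag_indices_from(H)

        accepted = False
        while mu <= cfg.mu_max:
            Hd = H.copy()
            Hd[diag] += mu
            try:
                delta = np.linalg.solve(Hd, -g)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_inc
                continue
            cand = w.unpack(theta + delta)
            cand_err = _sse(cand, X, T)
            if not np.isfinite(cand_err):
                raise ConvergenceError(
                    f"non-finite training error at epoch {epoch}", log
                )
            if cand_err < train_err:
                w = cand
                theta = theta + delta
                train_err = cand_err
                mu = max(mu * cfg.mu_dec, np.finfo(float).tiny)
                accepted = True
                break
            mu *= cfg.mu_inc

        val_err = _sse(w, Xval, Tval)
        log.append(
            {"epoch": epoch, "train_sse": train_err, "val_sse": val_err, "mu": mu,
             "accepted": accepted}
        )
        if val_err < best_val:
            best_val = val_err
            best_w = w.copy()
            bad_epochs = 0
        else:
            bad_epochs += 1

        if not accepted:  # mu exhausted: no descent direction left
            break
        if bad_epochs >= cfg.patience:
            break

    return best_w, labels, log


# --------------------------------------------------------------------------
# Classifier bundle


@dataclass
class GestureClassifier:
    """Fitted PCA + trained network + ordered label map."""

    pca: PcaModel
    weights: MlpWeights
    labels: list[str]
    training_log: list[dict] = field(default_factory=list)
    config: NetConfig = field(default_factory=NetConfig)

    @property
    def n_in(self) -> int:
        return self.pca.n_out


def predict(
    model: GestureClassifier, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Classify reduced feature rows.

    Returns ``(labels, probabilities)``; each probability row is a softmax
    distribution over the model's classes, and the label is the argmax
    (ties broken by label order).
    """
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != model.weights.W1.shape[1]:
        raise ValueError(
            f"expected {model.weights.W1.shape[1]} columns, got {X.shape[1]}"
        )
    _, probs = forward(model.weights, X)
    idx = probs.argmax(axis=1)
    return np.array([model.labels[i] for i in idx]), probs


def classify_features(
    model: GestureClassifier, feature_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce raw feature rows through the model's PCA, then classify."""
    return predict(model, transform(model.pca, feature_rows))


def fit_classifier(
    table: FeatureTable,
    cfg: NetConfig | None = None,
    pca_threshold: float = 0.95,
    val_fraction: float = 0.1,
    labels: list[str] | None = None,
) -> GestureClassifier:
    """Fit PCA and train a classifier on a feature table.

    A seeded stratified ``val_fraction`` of the rows is held out for early
    stopping; the rest trains the network.
    """
    from sklearn.model_selection import train_test_split

    cfg = cfg or NetConfig()
    y = table.labels
    if labels is None:
        labels = table.label_order
    pca = fit_pca(table, threshold=pca_threshold)
    Z = transform(pca, table.matrix)
    idx_train, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=val_fraction,
        stratify=y,
        random_state=cfg.seed % (2**32),
    )
    w, labels, log = train_network(
        Z[idx_train], y[idx_train], Z[idx_val], y[idx_val], cfg, labels=labels
    )
    return GestureClassifier(pca=pca, weights=w, labels=labels,
                             training_log=log, config=cfg)


def save_classifier(model: GestureClassifier, path: str | Path) -> None:
    """Persist a classifier (weights, PCA, labels, config) as JSON."""
    payload = {
        "labels": list(model.labels),
        "config": asdict(model.config),
        "pca": {
            "mean": model.pca.mean.tolist(),
            "scale": model.pca.scale.tolist(),
            "components": model.pca.components.tolist(),
            "variance_threshold": model.pca.variance_threshold,
            "explained": model.pca.explained.tolist(),
        },
        "weights": {
            "W1": model.weights.W1.tolist(),
            "b1": model.weights.b1.tolist(),
            "W2": model.weights.W2.tolist(),
            "b2": model.weights.b2.tolist(),
        },
        "training_log": model.training_log,
    }
    Path(path).write_text(json.dumps(payload))


def load_classifier(path: str | Path) -> GestureClassifier:
    payload = json.loads(Path(path).read_text())
    pca = PcaModel(
        mean=np.array(payload["pca"]["mean"]),
        scale=np.array(payload["pca"]["scale"]),
        components=np.array(payload["pca"]["components"]),
        variance_threshold=payload["pca"]["variance_threshold"],
        explained=np.array(payload["pca"]["explained"]),
    )
    w = MlpWeights(
        W1=np.array(payload["weights"]["W1"]),
        b1=np.array(payload["weights"]["b1"]),
        W2=np.array(payload["weights"]["W2"]),
        b2=np.array(payload["weights"]["b2"]),
    )
    return GestureClassifier(
        pca=pca,
        weights=w,
        labels=payload["labels"],
        training_log=payload.get("training_log", []),
        config=NetConfig(**payload["config"]),
    )
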