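"""Additive multi-head attention over feature positions.

Each feature position u of an encoded window is treated as a token. Its key
is the concatenation of the feature value x_u with a learned positional
embedding e_u; each head owns a learned query vector q and weight matrices
Wq (h×q_dim), Wk (h×k_dim) and Wv (h). The additive score of the query
against position u is

    a(q, k_u) = Wvᵀ tanh(Wq q + Wk k_u),

normalized across positions by a softmax into per-head weights that sum
to 1; heads are combined by arithmetic mean. The transform re-weights the
input features elementwise, rescaled by the number of positions d so that
uniform weights reproduce the input exactly:

    out_u = d · w̄_u · x_u .

All attention parameters and a logistic readout on the re-weighted features
are trained jointly by full-batch gradient descent on the mean binary
cross-entropy of the readout's predictions — positions whose values help
separate methylated from background windows earn more than the uniform
1/d share of attention mass. Two numerical choices make that concentration
actually reachable: the readout carries an L2 penalty (otherwise it absorbs
all feature weighting itself and the softmax stays uniform), and the
score-path parameters take a learning-rate multiplier of d to undo the
~1/d gradient dilution of the softmax Jacobian. A dot-product scoring
variant ((Wq q)·(Wk k_u)/√h) is available via ``AttentionConfig.score``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoders import FeatureMatrix
from .errors import DivergenceError, FitError, NotFittedError, ParameterError

__all__ = [
    "AttentionConfig",
    "AttentionTransformer",
    "AttentionMap",
    "additive_score",
    "softmax_weights",
    "fit_attention",
    "transform_attention",
    "export_attention_map",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Hyperparameters of the attention fusion step.

    n_heads
        Number of independent attention heads (default 4).
    hidden_dim
        Width h of the tanh layer in the additive score (default 16).
    epochs, learning_rate
        Full-batch gradient-descent schedule (defaults 200, 0.3; features
        are standardized internally, which makes this scale-free).
    query_dim, embed_dim
        Sizes of the learned query vector and of the positional embedding
        in the key (defaults 8 each).
    weight_decay
        L2 penalty on the logistic-readout coefficients (default 0.1).
        Without it the readout alone can absorb all feature weighting and
        the attention weights stay near uniform; penalizing the readout
        makes concentrating softmax mass on informative positions the
        cheaper route to a large logit, so the learned weights reflect
        feature relevance.
    score
        'additive' (default) or 'dot'.
    seed
        Parameter-initialisation seed.
    """

    n_heads: int = 4
    hidden_dim: int = 16
    epochs: int = 200
    learning_rate: float = 0.3
    query_dim: int = 8
    embed_dim: int = 8
    weight_decay: float = 0.1
    score: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_heads", "hidden_dim", "epochs", "query_dim", "embed_dim"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ParameterError("weight_decay must be non-negative")
        if self.score not in ("additive", "dot"):
            raise ParameterError(f"score must be 'additive' or 'dot', got {self.score!r}")

    def to_dict(self) -> dict:
        return {
            "n_heads": self.n_heads, "hidden_dim": self.hidden_dim,
            "epochs": self.epochs, "learning_rate": self.learning_rate,
            "query_dim": self.query_dim, "embed_dim": self.embed_dim,
            "weight_decay": self.weight_decay,
            "score": self.score, "seed": self.seed,
        }


def additive_score(q: np.ndarray, k: np.ndarray, Wq: np.ndarray, Wk: np.ndarray,
                   Wv: np.ndarray) -> float:
    """Scalar additive attention score Wvᵀ tanh(Wq q + Wk k)."""
    q, k = np.asarray(q, float).ravel(), np.asarray(k, float).ravel()
    Wq, Wk = np.atleast_2d(np.asarray(Wq, float)), np.atleast_2d(np.asarray(Wk, float))
    Wv = np.asarray(Wv, float).ravel()
    if Wq.shape[1] != q.size or Wk.shape[1] != k.size or Wq.shape[0] != Wk.shape[0] \
            or Wv.size != Wq.shape[0]:
        raise ParameterError(
            f"incompatible shapes: Wq{Wq.shape}, q({q.size},), Wk{Wk.shape}, "
            f"k({k.size},), Wv({Wv.size},)"
        )
    return float(Wv @ np.tanh(Wq @ q + Wk @ k))


def softmax_weights(scores: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax along the last axis."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ParameterError("softmax of an empty score vector is undefined")
    if not np.all(np.isfinite(scores)):
        raise ParameterError("softmax requires finite scores")
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class AttentionTransformer:
    """Trained attention parameters plus the logistic readout.

    Per-head arrays are stacked on a leading head axis: ``q`` (H, q_dim),
    ``Wq`` (H, h, q_dim), ``Wk`` (H, h, 1+embed_dim), ``Wv`` (H, h). The
    positional embedding ``E`` (d, embed_dim) is shared across heads;
    ``beta``/``intercept`` form the logistic readout on the re-weighted
    features. ``transform`` is refused until ``trained`` is set.
    """

    config: AttentionConfig
    n_features: int
    q: np.ndarray
    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    E: np.ndarray
    beta: np.ndarray
    intercept: float
    trained: bool = False
    loss_trajectory: list[float] = field(default_factory=list)
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    # -- forward pieces -----------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        """Training-set column standardization (keys and readout operate on
        standardized values; constant columns pass through centered)."""
        if self.mu is None:
            return X
        return (X - self.mu) / self.sd

    def _scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Per-head scores (H, n, d) from *standardized* features; second
        element is the tanh cache (additive scoring only)."""
        X = self._standardize(np.asarray(X, float))
        H, h = self.config.n_heads, self.config.hidden_dim
        wk0 = self.Wk[:, :, 0]                       # (H, h): key slot for x_u
        EWk = np.einsum("up,ahp->auh", self.E, self.Wk[:, :, 1:])  # (H, d, h)
        uq = np.einsum("ahd,ad->ah", self.Wq, self.q)              # (H, h)
        if self.config.score == "additive":
            T = (uq[:, None, None, :]
                 + X[None, :, :, None] * wk0[:, None, None, :]
                 + EWk[:, None, :, :])               # (H, n, d, h)
            A = np.tanh(T)
            s = np.einsum("anuh,ah->anu", A, self.Wv)
            return s, A
        kproj = X[None, :, :, None] * wk0[:, None, None, :] + EWk[:, None, :, :]
        s = np.einsum("anuh,ah->anu", kproj, uq) / np.sqrt(h)
        return s, None

    def head_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-head softmax attention weights, shape (H, n, d)."""
        s, _ = self._scores(np.asarray(X, float))
        return softmax_weights(s)

    def weights(self, X: np.ndarray) -> np.ndarray:
        """Head-averaged attention weights, shape (n, d); rows sum to 1."""
        return self.head_weights(X).mean(axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability from the internal logistic readout
        (a training diagnostic; the pipeline's classifier is downstream)."""
        X = np.asarray(X, float)
        out = X.shape[1] * self.weights(X) * self._standardize(X)
        return _sigmoid(out @ self.beta + self.intercept)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "n_features": self.n_features,
            "q": self.q.tolist(), "Wq": self.Wq.tolist(), "Wk": self.Wk.tolist(),
            "Wv": self.Wv.tolist(), "E": self.E.tolist(),
            "beta": self.beta.tolist(), "intercept": self.intercept,
            "trained": self.trained,
            "loss_trajectory": [float(x) for x in self.loss_trajectory],
            "mu": None if self.mu is None else self.mu.tolist(),
            "sd": None if self.sd is None else self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AttentionTransformer":
        return cls(
            config=AttentionConfig(**payload["config"]),
            n_features=int(payload["n_features"]),
            q=np.asarray(payload["q"], float),
            Wq=np.asarray(payload["Wq"], float),
            Wk=np.asarray(payload["Wk"], float),
            Wv=np.asarray(payload["Wv"], float),
            E=np.asarray(payload["E"], float),
            beta=np.asarray(payload["beta"], float),
            intercept=float(payload["intercept"]),
            trained=bool(payload["trained"]),
            loss_trajectory=list(payload.get("loss_trajectory", [])),
            mu=None if payload.get("mu") is None else np.asarray(payload["mu"], float),
            sd=None if payload.get("sd") is None else np.asarray(payload["sd"], float),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "AttentionTransformer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _init_transformer(cfg: AttentionConfig, d: int) -> AttentionTransformer:
    rng = np.random.default_rng(cfg.seed)
    H, h, dq, p = cfg.n_heads, cfg.hidden_dim, cfg.query_dim, cfg.embed_dim
    scale = 0.1
    return AttentionTransformer(
        config=cfg, n_features=d,
        q=rng.normal(0, scale, (H, dq)),
        Wq=rng.normal(0, scale, (H, h, dq)),
        Wk=rng.normal(0, scale, (H, h, 1 + p)),
        Wv=rng.normal(0, scale, (H, h)),
        E=rng.normal(0, scale, (d, p)),
        beta=np.zeros(d), intercept=0.0,
    )


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


def fit_attention(X, y, cfg: AttentionConfig | None = None) -> AttentionTransformer:
    """Jointly train attention parameters and the logistic readout.

    Full-batch gradient descent on the mean binary cross-entropy of
    ``sigmoid(beta · (d·w̄∘x) + b)`` against the labels. Deterministic for a
    fixed config (seed included); the per-epoch loss is recorded in
    ``loss_trajectory``.
    """
    cfg = cfg or AttentionConfig()
    Xv = _as_values(X)
    y = np.asarray(y, float).ravel()
    if Xv.ndim != 2 or Xv.shape[0] != y.size:
        raise ParameterError("X must be (n_samples, n_features) matching y")
    if Xv.shape[0] < 2 or len(np.unique(y)) < 2:
        raise FitError("attention training requires >= 2 samples with both classes present")

    t = _init_transformer(cfg, Xv.shape[1])
    n, d = Xv.shape
    H, h = cfg.n_heads, cfg.hidden_dim
    lr, eps = cfg.learning_rate, 1e-12
    sqrt_h = np.sqrt(h)

    # column standardization decouples the (fixed) learning rate from the
    # encoder's feature scale; constant columns pass through centered
    t.mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    t.sd = sd
    Xv = (Xv - t.mu) / t.sd

    xflat = Xv.reshape(n * d)                                    # view, reused below
    for epoch in range(cfg.epochs):
        wk0, Wk1 = t.Wk[:, :, 0], t.Wk[:, :, 1:]
        uq = np.einsum("ahd,ad->ah", t.Wq, t.q)                  # (H, h)
        EWk = np.einsum("up,ahp->auh", t.E, Wk1)                 # (H, d, h)
        # scores flattened to (H, n*d, h) so every contraction is a batched GEMM
        T = Xv.reshape(1, n, d, 1) * wk0[:, None, None, :]
        T += EWk[:, None, :, :]
        if cfg.score == "additive":
            T += uq[:, None, None, :]
            A = np.tanh(T.reshape(H, n * d, h))
            s = (A @ t.Wv[:, :, None]).reshape(H, n, d)
        else:
            kproj = T.reshape(H, n * d, h)
            s = (kproj @ uq[:, :, None]).reshape(H, n, d) / sqrt_h
        if not np.all(np.isfinite(s)):
            raise DivergenceError(
                f"attention scores became non-finite at epoch {epoch}; "
                f"reduce learning_rate (currently {lr})"
            )
        w = softmax_weights(s)                                   # (H, n, d)
        wbar = w.mean(axis=0)                                    # (n, d)
        o = d * wbar * Xv
        z = o @ t.beta + t.intercept
        p = _sigmoid(z)
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        if not np.isfinite(loss):
            raise DivergenceError(
                f"training loss became non-finite at epoch {epoch}; "
                f"reduce learning_rate (currently {lr})"
            )
        t.loss_trajectory.append(float(loss))

        # backward
        dz = (p - y) / n                                         # (n,)
        dbeta = o.T @ dz + cfg.weight_decay * t.beta
        dintercept = dz.sum()
        do = dz[:, None] * t.beta[None, :]                       # (n, d)
        dwbar = d * Xv * do
        g = dwbar / H                                            # shared across heads
        ds = w * (g[None] - (g[None] * w).sum(axis=2, keepdims=True))  # (H, n, d)
        ds_flat = ds.reshape(H, 1, n * d)
        if cfg.score == "additive":
            dT = ds.reshape(H, n * d, 1) * t.Wv[:, None, :]
            dT *= 1.0 - A ** 2                                   # (H, n*d, h)
            dWv = (ds_flat @ A)[:, 0, :]
            duq = dT.reshape(H, n, d, h).sum(axis=(1, 2))
        else:
            duq = (ds_flat @ kproj)[:, 0, :] / sqrt_h
            dT = ds.reshape(H, n * d, 1) * (uq[:, None, :] / sqrt_h)
            dWv = np.zeros_like(t.Wv)
        dwk0 = (xflat[None, None, :] @ dT)[:, 0, :]              # (H, h)
        dT_u = dT.reshape(H, n, d, h).sum(axis=1)                # (H, d, h)
        dWk1 = np.einsum("auh,up->ahp", dT_u, t.E)
        dE = np.einsum("auh,ahp->up", dT_u, Wk1)
        dWq = np.einsum("ah,ad->ahd", duq, t.q)
        dq = np.einsum("ahd,ah->ad", t.Wq, duq)

        t.beta -= lr * dbeta
        t.intercept -= lr * dintercept
        # the softmax Jacobian scales score-path gradients by the attention
        # weights (~1/d near uniform); the d multiplier undoes that dilution
        # so scores and readout learn on comparable timescales
        lr_s = lr * d
        t.Wv -= lr_s * dWv
        t.Wk[:, :, 0] -= lr_s * dwk0
        t.Wk[:, :, 1:] -= lr_s * dWk1
        t.E -= lr_s * dE
        t.Wq -= lr_s * dWq
        t.q -= lr_s * dq
        # runaway parameters keep the loss finite for a while (tanh and the
        # clipped logs saturate), so divergence is caught on magnitude too
        if not np.isfinite(t.beta).all() or np.abs(t.beta).max() > 1e100:
            raise DivergenceError(
                f"readout coefficients diverged at epoch {epoch}; "
                f"reduce learning_rate (currently {lr})"
            )

    t.trained = True
    return t


def transform_attention(t: AttentionTransformer, X) -> FeatureMatrix:
    """Re-weight features by head-averaged attention: out_u = d·w̄_u·x_u.

    The d rescaling makes a uniform-weight transformer the identity, so the
    downstream classifier never has to undo a blanket 1/d shrinkage.
    """
    if not t.trained:
        raise NotFittedError("transform requested from an untrained AttentionTransformer")
    Xv = _as_values(X)
    if Xv.shape[1] != t.n_features:
        raise ParameterError(
            f"X has {Xv.shape[1]} features but the transformer was trained on {t.n_features}"
        )
    out = Xv.shape[1] * t.weights(Xv) * Xv
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(out, list(X.feature_names), X.encoder_id + "+attention",
                             dict(X.params))
    return FeatureMatrix(out, [f"f{i + 1}" for i in range(Xv.shape[1])], "attention", {})


@dataclass
class AttentionMap:
    """Head-averaged attention weights, one row per sample (rows sum to 1)."""

    weights: np.ndarray
    feature_names: list[str]

    def column_means(self) -> np.ndarray:
        return self.weights.mean(axis=0)


def export_attention_map(t: AttentionTransformer, X, tsv_path=None,
                         png_path=None) -> AttentionMap:
    """Compute (and optionally write) the attention map for a feature matrix.

    The TSV has feature names as header and one weight row per sample; the
    optional PNG renders the same matrix as a heat map.
    """
    if not t.trained:
        raise NotFittedError("attention map requested from an untrained AttentionTransformer")
    Xv = _as_values(X)
    names = (list(X.feature_names) if isinstance(X, FeatureMatrix)
             else [f"f{i + 1}" for i in range(Xv.shape[1])])
    amap = AttentionMap(t.weights(Xv), names)
    if tsv_path is not None:
        import pandas as pd

        pd.DataFrame(amap.weights, columns=names).to_csv(tsv_path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(amap.weights, aspect="auto", cmap="viridis")
        ax.set_xlabel("feature position")
        ax.set_ylabel("sample")
        fig.colorbar(im, ax=ax, label="attention weight")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return amap
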