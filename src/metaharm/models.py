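"""Pair classifiers: cosine logistic-regression baseline, siamese FCN, and a
contrastive-learning variant.

All three map a pair of description embeddings (e1, e2) to a probability that
the two descriptions name the same harmonized concept.

Baseline
    p = sigmoid(slope * cos(e1, e2) + intercept) — a one-feature logistic
    regression on the raw embedding cosine, fit by cross-entropy.

Siamese FCN
    A single ReLU projection shared by both inputs, then a cosine head:
    u = ReLU(W e1 + c), v = ReLU(W e2 + c), p = sigmoid(w * cos(u, v) + b).
    Weight sharing makes the score exactly symmetric in its arguments. Trained
    by binary cross-entropy with Adam and early stopping on validation loss.

Contrastive FCN
    The same architecture trained in two stages: first the projection is
    learned with an InfoNCE loss — matched pairs (plus coordinate-permutation
    augmented views) are positives, other in-batch pairs are negatives,
    -log[ exp(cos(u_i, v_i)/tau) / sum_j exp(cos(u_i, v_j)/tau) ] — then the
    scalar head (w, b) is calibrated by logistic regression with the
    projection frozen, so inference is identical across the three models.

Implemented directly in numpy: the networks are small (one shared projection
plus a two-parameter head) and the closed-form gradients are given inline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.linear_model import LogisticRegression

from .embeddings import EmbeddingProvider, cosine_rows
from .errors import ModelFormatError, ValidationError
from .pairing import PairDataset

MODEL_FORMAT_VERSION = "metaharm-model-1"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class TrainConfig:
    """Optimization settings shared by the three fitting routines."""

    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 64
    seed: int = 0
    loss: str = "bce"  # "bce" or "nce"
    temperature: float = 0.07  # nce only
    permute_fraction: float = 0.1  # nce augmentation strength
    hidden_dim: int = 256

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValidationError("patience must be smaller than max_epochs")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if not 0.0 <= self.permute_fraction <= 1.0:
            raise ValidationError("permute_fraction must lie in [0, 1]")
        if self.loss not in ("bce", "nce"):
            raise ValidationError(f"unknown loss {self.loss!r}")


@dataclass
class BaselineLR:
    """Logistic regression on the raw embedding cosine."""

    slope: float
    intercept: float
    dimension: int

    def scores(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        cos = cosine_rows(E1, E2)
        return _sigmoid(self.slope * cos + self.intercept)

    def scores_one_vs_many(self, q: np.ndarray, R: np.ndarray) -> np.ndarray:
        nq = np.linalg.norm(q)
        nr = np.linalg.norm(R, axis=1)
        if nq == 0 or (nr == 0).any():
            raise ValidationError("zero embedding vector")
        cos = R @ q / (nr * nq)
        return _sigmoid(self.slope * cos + self.intercept)


@dataclass(eq=False)
class SiameseFCN:
    """Shared ReLU projection + rescaled-cosine sigmoid head."""

    W: np.ndarray  # (h, d)
    c: np.ndarray  # (h,)
    w: float
    b: float

    @property
    def dimension(self) -> int:
        return self.W.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W.shape[0]

    def project(self, E: np.ndarray) -> np.ndarray:
        return np.maximum(E @ self.W.T + self.c, 0.0)

    def scores(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        # a ReLU output can be all-zero; its cosine is defined as 0 at the head
        cos = cosine_rows(self.project(E1), self.project(E2), zero_as=0.0)
        return _sigmoid(self.w * cos + self.b)

    def scores_one_vs_many(self, q: np.ndarray, R_proj: np.ndarray) -> np.ndarray:
        u = self.project(q[None, :])[0]
        nu = np.linalg.norm(u)
        nr = np.linalg.norm(R_proj, axis=1)
        cos = np.zeros(len(R_proj))
        ok = nr > 0
        if nu > 0:
            cos[ok] = R_proj[ok] @ u / (nr[ok] * nu)
        return _sigmoid(self.w * cos + self.b)


@dataclass(eq=False)
class TrainedScorer:
    """A fitted pair model plus its provenance (provider, config, history)."""

    model: Union[BaselineLR, SiameseFCN]
    config: TrainConfig
    history: dict
    provider_name: str
    dimension: int
    best_epoch: int = 0
    kind: str = "baseline"

    def _check_dim(self, *arrays: np.ndarray) -> None:
        for a in arrays:
            if a.shape[-1] != self.dimension:
                raise ValidationError(
                    f"embedding dimension {a.shape[-1]} does not match model "
                    f"dimension {self.dimension}"
                )

    def score_pair(self, e1: np.ndarray, e2: np.ndarray) -> float:
        e1 = np.asarray(e1, dtype=np.float64)
        e2 = np.asarray(e2, dtype=np.float64)
        self._check_dim(e1, e2)
        return float(self.model.scores(e1[None, :], e2[None, :])[0])

    def score_batch(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        E1 = np.asarray(E1, dtype=np.float64)
        E2 = np.asarray(E2, dtype=np.float64)
        self._check_dim(E1, E2)
        return self.model.scores(E1, E2)


@dataclass(eq=False)
class EmbeddedPairs:
    """A pair dataset materialized as embedding arrays (X1, X2, y)."""

    X1: np.ndarray
    X2: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.X1) == len(self.X2) == len(self.y)):
            raise ValidationError("X1, X2 and y must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_pairs(cls, dataset: PairDataset, provider: EmbeddingProvider) -> "EmbeddedPairs":
        texts: list[str] = []
        index: dict[str, int] = {}
        for p in dataset.pairs:
            for r in (p.x1, p.x2):
                if r.description not in index:
                    index[r.description] = len(texts)
                    texts.append(r.description)
        E = provider.embed(texts)
        i1 = [index[p.x1.description] for p in dataset.pairs]
        i2 = [index[p.x2.description] for p in dataset.pairs]
        y = np.array([p.label for p in dataset.pairs], dtype=np.float64)
        return cls(X1=E[i1], X2=E[i2], y=y)


def fit_baseline(
    train: EmbeddedPairs,
    val: Optional[EmbeddedPairs],
    config: TrainConfig,
    provider_name: str = "unknown",
) -> TrainedScorer:
    """One-feature logistic regression on cosine similarity (cross-entropy fit)."""
    if len(np.unique(train.y)) < 2:
        raise ValidationError("training labels contain a single class")
    cos = cosine_rows(train.X1, train.X2).reshape(-1, 1)
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(cos, train.y)
    model = BaselineLR(
        slope=float(lr.coef_[0, 0]),
        intercept=float(lr.intercept_[0]),
        dimension=train.X1.shape[1],
    )
    history = {"train_loss": [_bce(model.scores(train.X1, train.X2), train.y)]}
    if val is not None and len(val):
        history["val_loss"] = [_bce(model.scores(val.X1, val.X2), val.y)]
    return TrainedScorer(
        model=model, config=config, history=history,
        provider_name=provider_name, dimension=model.dimension,
        best_epoch=0, kind="baseline",
    )


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _init_fcn(d: int, h: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        "W": rng.standard_normal((h, d)) * np.sqrt(2.0 / d),  # He init for ReLU
        "c": np.zeros(h),
        "w": np.array([3.0]),  # start with a confident positive cosine scale
        "b": np.array([-1.0]),
    }


def _fcn_forward_backward(
    params: dict[str, np.ndarray], E1: np.ndarray, E2: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """BCE loss and exact gradients for the siamese cosine-head network."""
    W, c = params["W"], params["c"]
    w, b = params["w"][0], params["b"][0]
    B = len(y)
    P1 = E1 @ W.T + c
    P2 = E2 @ W.T + c
    U = np.maximum(P1, 0.0)
    V = np.maximum(P2, 0.0)
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    ok = (nu > 0) & (nv > 0)
    s = np.zeros(B)
    nu_safe = np.where(nu > 0, nu, 1.0)
    nv_safe = np.where(nv > 0, nv, 1.0)
    Uh = U / nu_safe[:, None]
    Vh = V / nv_safe[:, None]
    s[ok] = np.einsum("ij,ij->i", Uh[ok], Vh[ok])
    z = w * s + b
    p = _sigmoid(z)
    loss = _bce(p, y)

    dz = (p - y) / B
    dw = float(dz @ s)
    db = float(dz.sum())
    ds = dz * w
    ds = np.where(ok, ds, 0.0)
    # d cos / dU = (Vh - s*Uh)/|U|  (and symmetrically for V)
    dU = ds[:, None] * (Vh - s[:, None] * Uh) / nu_safe[:, None]
    dV = ds[:, None] * (Uh - s[:, None] * Vh) / nv_safe[:, None]
    dP1 = dU * (P1 > 0)
    dP2 = dV * (P2 > 0)
    grads = {
        "W": dP1.T @ E1 + dP2.T @ E2,
        "c": dP1.sum(axis=0) + dP2.sum(axis=0),
        "w": np.array([dw]),
        "b": np.array([db]),
    }
    return loss, grads


def _nce_forward_backward(
    params: dict[str, np.ndarray], A: np.ndarray, Bv: np.ndarray, tau: float
) -> tuple[float, dict[str, np.ndarray]]:
    """InfoNCE loss over a batch of positive pairs with in-batch negatives."""
    W, c = params["W"], params["c"]
    B = len(A)
    P1 = A @ W.T + c
    P2 = Bv @ W.T + c
    U = np.maximum(P1, 0.0)
    V = np.maximum(P2, 0.0)
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    nu_safe = np.where(nu > 0, nu, 1.0)
    nv_safe = np.where(nv > 0, nv, 1.0)
    Uh = U / nu_safe[:, None]
    Vh = V / nv_safe[:, None]
    S = Uh @ Vh.T  # (B, B); zero rows give 0 similarity, consistent with the head
    logits = S / tau
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    softmax = expl / expl.sum(axis=1, keepdims=True)
    loss = float(np.mean(-np.log(softmax[np.arange(B), np.arange(B)] + 1e-300)))

    G = (softmax - np.eye(B)) / (B * tau)  # dL/dS
    dUh = G @ Vh
    dVh = G.T @ Uh
    # back through row normalization: d/du (u/|u|) applied to gradient g:
    # (g - (g.uh) uh)/|u| ; zero rows get zero gradient
    gu = np.einsum("ij,ij->i", dUh, Uh)
    gv = np.einsum("ij,ij->i", dVh, Vh)
    dU = (dUh - gu[:, None] * Uh) / nu_safe[:, None]
    dV = (dVh - gv[:, None] * Vh) / nv_safe[:, None]
    dU[nu == 0] = 0.0
    dV[nv == 0] = 0.0
    dP1 = dU * (P1 > 0)
    dP2 = dV * (P2 > 0)
    grads = {
        "W": dP1.T @ A + dP2.T @ Bv,
        "c": dP1.sum(axis=0) + dP2.sum(axis=0),
        "w": np.zeros(1),
        "b": np.zeros(1),
    }
    return loss, grads


def permute_augment(
    X: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Positive-view augmentation: shuffle a random ``fraction`` of coordinate
    positions within each vector. fraction=0 returns the input unchanged."""
    X = np.array(X, dtype=np.float64, copy=True)
    d = X.shape[-1]
    k = int(round(fraction * d))
    if k < 2:
        return X
    for row in X.reshape(-1, d):
        pos = rng.choice(d, size=k, replace=False)
        row[pos] = row[rng.permutation(pos)]
    return X


@dataclass
class _EarlyStopper:
    patience: int
    best: float = np.inf
    best_epoch: int = -1
    stale: int = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record epoch; return True when training should stop."""
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale > self.patience


def _clone(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in params.items()}


def fit_fcn(
    train: EmbeddedPairs,
    val: EmbeddedPairs,
    config: TrainConfig,
    provider_name: str = "unknown",
) -> TrainedScorer:
    """Train the siamese FCN with Adam + early stopping on validation BCE."""
    if len(np.unique(train.y)) < 2:
        raise ValidationError("training labels contain a single class")
    if not len(val):
        raise ValidationError("validation set is empty")
    rng = np.random.default_rng(config.seed)
    d = train.X1.shape[1]
    params = _init_fcn(d, config.hidden_dim, rng)
    opt = _Adam(params, config.learning_rate)
    stopper = _EarlyStopper(config.patience)
    history: dict = {"train_loss": [], "val_loss": []}
    best_params = _clone(params)
    n = len(train)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = _fcn_forward_backward(
                params, train.X1[idx], train.X2[idx], train.y[idx]
            )
            if not np.isfinite(loss):
                raise ValidationError(
                    f"non-finite training loss at epoch {epoch}; "
                    "try a smaller learning rate"
                )
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)
        model = SiameseFCN(W=params["W"], c=params["c"], w=float(params["w"][0]), b=float(params["b"][0]))
        val_loss = _bce(model.scores(val.X1, val.X2), val.y)
        history["val_loss"].append(val_loss)
        stop = stopper.update(epoch, val_loss)
        if stopper.best_epoch == epoch:
            best_params = _clone(params)
        if stop:
            break

    bp = best_params
    model = SiameseFCN(W=bp["W"], c=bp["c"], w=float(bp["w"][0]), b=float(bp["b"][0]))
    return TrainedScorer(
        model=model, config=config, history=history,
        provider_name=provider_name, dimension=d,
        best_epoch=stopper.best_epoch, kind="fcn",
    )


def nce_loss(cos_matrix: np.ndarray, tau: float = 0.07) -> float:
    """InfoNCE loss given a (B, B) cosine matrix with positives on the diagonal."""
    logits = np.asarray(cos_matrix, dtype=np.float64) / tau
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    softmax = expl / expl.sum(axis=1, keepdims=True)
    return float(np.mean(-np.log(np.diag(softmax))))


def fit_contrastive(
    train: EmbeddedPairs,
    val: EmbeddedPairs,
    config: TrainConfig,
    provider_name: str = "unknown",
) -> TrainedScorer:
    """Two-stage contrastive training: InfoNCE projection, then BCE head.

    Stage 1 draws batches from the matched pairs of the training set,
    augmented with coordinate-permutation positive views of each anchor, and
    minimizes InfoNCE with in-batch negatives. Stage 2 freezes the projection
    and fits the scalar head (w, b) by logistic regression on the projected
    cosines of the full labeled pair set, so the inference contract matches
    the BCE-trained FCN exactly.
    """
    if config.loss != "nce":
        raise ValidationError("fit_contrastive requires config.loss == 'nce'")
    if len(np.unique(train.y)) < 2:
        raise ValidationError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    d = train.X1.shape[1]

    pos = train.y == 1
    A_pos = train.X1[pos]
    B_pos = train.X2[pos]
    if not len(A_pos):
        raise ValidationError("no matched pairs in training data")
    # augmented positive views of each anchor join the positive-pair pool
    if config.permute_fraction > 0:
        aug = permute_augment(A_pos, config.permute_fraction, rng)
        A_all = np.concatenate([A_pos, A_pos])
        B_all = np.concatenate([B_pos, aug])
    else:
        A_all, B_all = A_pos, B_pos

    vpos = val.y == 1
    VA, VB = val.X1[vpos], val.X2[vpos]

    params = _init_fcn(d, config.hidden_dim, rng)
    opt = _Adam(params, config.learning_rate)
    stopper = _EarlyStopper(config.patience)
    history: dict = {"train_loss": [], "val_loss": []}
    best_params = _clone(params)
    n = len(A_all)
    tau = config.temperature

    def val_nce(prm: dict[str, np.ndarray]) -> float:
        if len(VA) < 2:
            return np.nan
        model = SiameseFCN(W=prm["W"], c=prm["c"], w=1.0, b=0.0)
        U = model.project(VA)
        V = model.project(VB)
        nu = np.linalg.norm(U, axis=1)
        nv = np.linalg.norm(V, axis=1)
        Uh = U / np.where(nu > 0, nu, 1.0)[:, None]
        Vh = V / np.where(nv > 0, nv, 1.0)[:, None]
        return nce_loss(Uh @ Vh.T, tau)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_used = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                warnings.warn("skipping contrastive batch without in-batch negatives")
                continue
            loss, grads = _nce_forward_backward(params, A_all[idx], B_all[idx], tau)
            if not np.isfinite(loss):
                raise ValidationError(f"non-finite contrastive loss at epoch {epoch}")
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
            n_used += len(idx)
        history["train_loss"].append(epoch_loss / max(n_used, 1))
        vl = val_nce(params)
        history["val_loss"].append(vl)
        monitor = vl if np.isfinite(vl) else history["train_loss"][-1]
        stop = stopper.update(epoch, monitor)
        if stopper.best_epoch == epoch:
            best_params = _clone(params)
        if stop:
            break

    # stage 2: calibrate the scalar head on projected cosines, projection frozen
    frozen = SiameseFCN(
        W=best_params["W"], c=best_params["c"], w=1.0, b=0.0
    )
    cos = cosine_rows(frozen.project(train.X1), frozen.project(train.X2), zero_as=0.0)
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(cos.reshape(-1, 1), train.y)
    model = SiameseFCN(
        W=best_params["W"], c=best_params["c"],
        w=float(lr.coef_[0, 0]), b=float(lr.intercept_[0]),
    )
    history["head_train_loss"] = [_bce(model.scores(train.X1, train.X2), train.y)]
    return TrainedScorer(
        model=model, config=config, history=history,
        provider_name=provider_name, dimension=d,
        best_epoch=stopper.best_epoch, kind="contrastive",
    )


def save_model(scorer: TrainedScorer, path: str | Path) -> None:
    """Serialize to a self-describing JSON container (full float precision)."""
    payload: dict = {
        "format": MODEL_FORMAT_VERSION,
        "kind": scorer.kind,
        "provider_name": scorer.provider_name,
        "dimension": scorer.dimension,
        "best_epoch": scorer.best_epoch,
        "config": asdict(scorer.config),
        "history": scorer.history,
    }
    m = scorer.model
    if isinstance(m, BaselineLR):
        payload["model"] = {"type": "baseline_lr", "slope": m.slope, "intercept": m.intercept}
    else:
        payload["model"] = {
            "type": "siamese_fcn",
            "W": m.W.tolist(), "c": m.c.tolist(), "w": m.w, "b": m.b,
        }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> TrainedScorer:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format "
            f"{payload.get('format') if isinstance(payload, dict) else type(payload)}"
            f" (expected {MODEL_FORMAT_VERSION})"
        )
    spec = payload["model"]
    model: Union[BaselineLR, SiameseFCN]
    if spec["type"] == "baseline_lr":
        model = BaselineLR(
            slope=spec["slope"], intercept=spec["intercept"],
            dimension=payload["dimension"],
        )
    elif spec["type"] == "siamese_fcn":
        model = SiameseFCN(
            W=np.array(spec["W"]), c=np.array(spec["c"]),
            w=spec["w"], b=spec["b"],
        )
    else:
        raise ModelFormatError(f"{path}: unknown model type {spec['type']!r}")
    return TrainedScorer(
        model=model,
        config=TrainConfig(**payload["config"]),
        history=payload["history"],
        provider_name=payload["provider_name"],
        dimension=payload["dimension"],
        best_epoch=payload["best_epoch"],
        kind=payload["kind"],
    )
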