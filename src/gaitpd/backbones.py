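"""Three small sequence classifiers over the 18-token x 2-feature inputs.

All three architectures — a temporal convolutional network (TCN), a
bidirectional GRU with additive attention pooling (BiGRU-Attn), and a
per-token embedding with transformer encoder layers (FCNN-Transformer) —
share one contract: a batch of (B, 18, 2) windows in, one PD logit per
window out, differentiable end to end so the same training loop, evaluation
and Integrated Gradients code serve all of them.  The 18-token axis is the
sequence dimension.

Training uses AdamW (decoupled weight decay), weighted binary cross-entropy
with positive-class weight n_neg/n_pos, and early stopping on validation
AUC with restoration of the best-epoch parameters.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .autodiff import Tensor, concat, sigmoid, softmax, softplus
from .evaluate import window_auc
from .windowing import TokenizedWindow, feature_matrix, labels_of

N_TOKENS, N_DIMS = 18, 2
ARCHS = ("tcn", "bigru_attn", "fcnn_transformer")


@dataclasses.dataclass
class ModelSpec:
    arch: str
    hidden: int = 32
    depth: int = 3          # conv blocks / GRU layers / encoder layers
    dropout: float = 0.0
    heads: int = 4          # transformer only

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; choose from {ARCHS}")
        if self.hidden <= 0 or self.depth <= 0:
            raise ValueError("hidden and depth must be positive")
        if self.arch == "fcnn_transformer" and self.hidden % self.heads:
            raise ValueError("attention heads must divide hidden width")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclasses.dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10      # epochs without val-AUC improvement
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("rates and sizes must be positive")


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    scale = np.sqrt(2.0 / sum(shape))
    return rng.normal(0.0, scale, size=shape)


class _Model:
    """Base: a named parameter dict plus a logits-forward."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.params: dict[str, Tensor] = {}

    def _add(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self.params[name] = t
        return t

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()

    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        p = self.spec.dropout
        if not train or p <= 0:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def forward(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        raise NotImplementedError

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(X)).data

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode probabilities in (0, 1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (N_TOKENS, N_DIMS):
            raise ValueError(f"expected (B, {N_TOKENS}, {N_DIMS}) input, got {X.shape}")
        if X.shape[0] == 0:
            return np.empty(0)
        return 1.0 / (1.0 + np.exp(-self.predict_logits(X)))


def _causal_shift(x: Tensor, s: int) -> Tensor:
    """Shift a (B, T, C) sequence right by s steps, zero-padding the front."""
    if s == 0:
        return x
    B, T, C = x.shape
    zeros = Tensor(np.zeros((B, s, C)))
    return concat([zeros, x[:, : T - s, :]], axis=1)


class TCN(_Model):
    """Dilated causal convolutions (kernel 3, dilations 1, 2, 4, ...)."""

    KERNEL = 3

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__(spec)
        rng = np.random.default_rng(seed)
        h = spec.hidden
        c_in = N_DIMS
        for b in range(spec.depth):
            for j in range(self.KERNEL):
                self._add(f"conv{b}_w{j}", _glorot(rng, c_in, h))
            self._add(f"conv{b}_b", np.zeros(h))
            if c_in != h:
                self._add(f"conv{b}_proj", _glorot(rng, c_in, h))
            c_in = h
        self._add("head_w", _glorot(rng, h, 1))
        self._add("head_b", np.zeros(1))

    def forward(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        p = self.params
        for b in range(self.spec.depth):
            dilation = 2**b
            y = None
            for j in range(self.KERNEL):
                term = _causal_shift(x, j * dilation) @ p[f"conv{b}_w{j}"]
                y = term if y is None else y + term
            y = y + p[f"conv{b}_b"]
            res = x @ p[f"conv{b}_proj"] if f"conv{b}_proj" in p else x
            x = (y + res).relu()
            x = self._dropout(x, train, rng)
        pooled = x.mean(axis=1)                      # (B, h)
        return (pooled @ p["head_w"] + p["head_b"]).reshape(-1)


class BiGRUAttn(_Model):
    """Bidirectional GRU with additive attention pooling."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__(spec)
        rng = np.random.default_rng(seed)
        h = spec.hidden
        for d in ("fwd", "bwd"):
            for gate in ("z", "r", "n"):
                self._add(f"{d}_W{gate}", _glorot(rng, N_DIMS, h))
                self._add(f"{d}_U{gate}", _glorot(rng, h, h))
                self._add(f"{d}_b{gate}", np.zeros(h))
        self._add("attn_w", _glorot(rng, 2 * h, h))
        self._add("attn_b", np.zeros(h))
        self._add("attn_v", _glorot(rng, h, 1))
        self._add("head_w", _glorot(rng, 2 * h, 1))
        self._add("head_b", np.zeros(1))

    def _gru_pass(self, x: Tensor, direction: str) -> list[Tensor]:
        p = self.params
        B = x.shape[0]
        h = Tensor(np.zeros((B, self.spec.hidden)))
        steps = range(N_TOKENS) if direction == "fwd" else range(N_TOKENS - 1, -1, -1)
        out: list[Tensor | None] = [None] * N_TOKENS
        for t in steps:
            xt = x[:, t, :]
            z = sigmoid(xt @ p[f"{direction}_Wz"] + h @ p[f"{direction}_Uz"] + p[f"{direction}_bz"])
            r = sigmoid(xt @ p[f"{direction}_Wr"] + h @ p[f"{direction}_Ur"] + p[f"{direction}_br"])
            n = (xt @ p[f"{direction}_Wn"] + (r * h) @ p[f"{direction}_Un"] + p[f"{direction}_bn"]).tanh()
            h = (1.0 - z) * n + z * h
            out[t] = h
        return out  # type: ignore[return-value]

    def forward(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        p = self.params
        fwd = self._gru_pass(x, "fwd")
        bwd = self._gru_pass(x, "bwd")
        B = x.shape[0]
        h2 = 2 * self.spec.hidden
        H = concat(
            [concat([f, b], axis=-1).reshape(B, 1, h2) for f, b in zip(fwd, bwd)],
            axis=1,
        )                                            # (B, 18, 2h)
        H = self._dropout(H, train, rng)
        scores = (H @ p["attn_w"] + p["attn_b"]).tanh() @ p["attn_v"]   # (B, 18, 1)
        alpha = softmax(scores, axis=1)
        pooled = (alpha * H).sum(axis=1)             # (B, 2h)
        return (pooled @ p["head_w"] + p["head_b"]).reshape(-1)


class FCNNTransformer(_Model):
    """Per-token linear embedding + transformer encoder layers + MLP head."""

    LN_EPS = 1e-5

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__(spec)
        rng = np.random.default_rng(seed)
        h = spec.hidden
        self._add("embed_w", _glorot(rng, N_DIMS, h))
        self._add("embed_b", np.zeros(h))
        self._add("pos", 0.02 * rng.standard_normal((N_TOKENS, h)))
        for layer in range(spec.depth):
            for name in ("q", "k", "v", "o"):
                self._add(f"l{layer}_W{name}", _glorot(rng, h, h))
            self._add(f"l{layer}_ff1_w", _glorot(rng, h, 2 * h))
            self._add(f"l{layer}_ff1_b", np.zeros(2 * h))
            self._add(f"l{layer}_ff2_w", _glorot(rng, 2 * h, h))
            self._add(f"l{layer}_ff2_b", np.zeros(h))
            for ln in ("ln1", "ln2"):
                self._add(f"l{layer}_{ln}_g", np.ones(h))
                self._add(f"l{layer}_{ln}_b", np.zeros(h))
        self._add("head1_w", _glorot(rng, h, h))
        self._add("head1_b", np.zeros(h))
        self._add("head2_w", _glorot(rng, h, 1))
        self._add("head2_b", np.zeros(1))

    def _layernorm(self, x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.LN_EPS).pow(-0.5) * gamma + beta

    def forward(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        p = self.params
        h, heads = self.spec.hidden, self.spec.heads
        hd = h // heads
        B = x.shape[0]
        x = x @ p["embed_w"] + p["embed_b"] + p["pos"]          # (B, 18, h)
        for layer in range(self.spec.depth):

            def split_heads(t: Tensor) -> Tensor:
                return t.reshape(B, N_TOKENS, heads, hd).swapaxes(1, 2)

            q = split_heads(x @ p[f"l{layer}_Wq"])
            k = split_heads(x @ p[f"l{layer}_Wk"])
            v = split_heads(x @ p[f"l{layer}_Wv"])
            att = softmax(q @ k.swapaxes(-1, -2) * (hd**-0.5), axis=-1)
            ctx = (att @ v).swapaxes(1, 2).reshape(B, N_TOKENS, h)
            ctx = self._dropout(ctx @ p[f"l{layer}_Wo"], train, rng)
            x = self._layernorm(x + ctx, p[f"l{layer}_ln1_g"], p[f"l{layer}_ln1_b"])
            ff = (x @ p[f"l{layer}_ff1_w"] + p[f"l{layer}_ff1_b"]).relu()
            ff = self._dropout(ff @ p[f"l{layer}_ff2_w"] + p[f"l{layer}_ff2_b"], train, rng)
            x = self._layernorm(x + ff, p[f"l{layer}_ln2_g"], p[f"l{layer}_ln2_b"])
        pooled = x.mean(axis=1)
        hidden = (pooled @ p["head1_w"] + p["head1_b"]).relu()
        return (hidden @ p["head2_w"] + p["head2_b"]).reshape(-1)


_BUILDERS = {"tcn": TCN, "bigru_attn": BiGRUAttn, "fcnn_transformer": FCNNTransformer}


def build_model(spec: ModelSpec, seed: int = 0) -> _Model:
    """Construct an untrained model; same seed gives identical initialization."""
    return _BUILDERS[spec.arch](spec, seed=seed)


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.wd * p.data)


@dataclasses.dataclass
class TrainedModel:
    model: _Model
    spec: ModelSpec
    history: list[dict]     # per-epoch: loss, val_auc
    best_epoch: int
    best_val_auc: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        X, y = dataset
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    if dataset and isinstance(dataset[0], TokenizedWindow):
        return feature_matrix(dataset), labels_of(dataset)
    raise ValueError("dataset must be (X, y) arrays or a list of TokenizedWindow")


def positive_class_weight(y: np.ndarray) -> float:
    """n_neg / n_pos over the training windows."""
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")
    return n_neg / n_pos


def _weighted_bce(logits: Tensor, y: np.ndarray, pos_weight: float) -> Tensor:
    """mean of w_i * BCE_i with w_i = pos_weight for PD windows, 1 for CO."""
    y_t = Tensor(y.astype(float))
    weights = Tensor(np.where(y == 1, pos_weight, 1.0))
    per_sample = y_t * softplus(-logits) + (1.0 - y_t) * softplus(logits)
    return (weights * per_sample).mean()


def train_classifier(model: _Model, train_data, val_data, config: TrainingConfig) -> TrainedModel:
    """Train with AdamW + weighted BCE; early-stop and restore on best val AUC."""
    X_tr, y_tr = _as_arrays(train_data)
    X_val, y_val = _as_arrays(val_data)
    if len(set(y_val.tolist())) < 2:
        raise ValueError("validation data must contain both classes")
    pos_weight = positive_class_weight(y_tr)
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.params, lr=config.learning_rate, weight_decay=config.weight_decay)
    history: list[dict] = []
    best_auc, best_epoch, best_state = -np.inf, -1, model.state()
    stale = 0
    n = X_tr.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            logits = model.forward(Tensor(X_tr[idx]), train=True, rng=rng)
            loss = _weighted_bce(logits, y_tr[idx], pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
        val_auc = window_auc(model.predict_proba(X_val), y_val)
        history.append({"epoch": epoch, "loss": epoch_loss / n, "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc, best_epoch, best_state = val_auc, epoch, model.state()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.load_state(best_state)
    return TrainedModel(
        model=model, spec=model.spec, history=history,
        best_epoch=best_epoch, best_val_auc=float(best_auc),
    )


def predict_proba(trained: TrainedModel, windows) -> np.ndarray:
    """Evaluation-mode window probabilities for TokenizedWindows or arrays."""
    if isinstance(windows, np.ndarray):
        X = windows
    elif len(windows) == 0:
        return np.empty(0)
    else:
        X, _ = _as_arrays(windows)
    return trained.model.predict_proba(X)


def save_model(trained: TrainedModel, path_prefix: str) -> None:
    """Checkpoint: .npz parameters plus a JSON sidecar (spec + history)."""
    np.savez(path_prefix + ".npz", **trained.model.state())
    sidecar = {
        "spec": dataclasses.asdict(trained.spec),
        "history": trained.history,
        "best_epoch": trained.best_epoch,
        "best_val_auc": trained.best_val_auc,
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path_prefix: str) -> TrainedModel:
    with open(path_prefix + ".json") as fh:
        sidecar = json.load(fh)
    spec = ModelSpec(**sidecar["spec"])
    model = build_model(spec)
    with np.load(path_prefix + ".npz") as archive:
        model.load_state({k: archive[k] for k in archive.files})
    return TrainedModel(
        model=model, spec=spec, history=sidecar["history"],
        best_epoch=sidecar["best_epoch"], best_val_auc=sidecar["best_val_auc"],
    )
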