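"""Recurrent and attention networks for the two detection branches.

Implements, on the numpy autodiff core in :mod:`nightfall._autodiff`:

* a stacked-LSTM sequence autoencoder (encoder LSTMs -> latent vector formed
  by concatenating the final hidden states -> symmetric decoder LSTMs driven
  by the repeated latent -> dense read-out back to the input channels);
* a Transformer encoder classifier over fixed-length pose-feature sequences
  (learned input projection, sinusoidal positional encoding, pre-norm
  multi-head self-attention blocks, mean pooling, softmax head);
* Adam, the training loops (mini-batching, validation split, early stopping,
  optional cosine annealing) and parameter (de)serialization.

All randomness flows through an explicit ``numpy.random.Generator`` seeded by
the caller, so identical data + seed give identical parameters and losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, log_softmax, softmax

__all__ = [
    "LstmAutoencoderNet",
    "TransformerClassifierNet",
    "Adam",
    "TrainRecipe",
    "fit_autoencoder",
    "fit_classifier",
]


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class _Module:
    """Base with named-parameter bookkeeping."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def _register(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self._params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r}")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            v.data = np.asarray(state[k], dtype=np.float64).copy()


class _LstmLayer:
    """One LSTM layer; gate order (input, forget, cell, output)."""

    def __init__(self, module: _Module, tag: str, d_in: int, d_hidden: int,
                 rng: np.random.Generator):
        self.h = d_hidden
        s = 1.0 / math.sqrt(d_hidden)
        self.wx = module._register(f"{tag}.wx", _param(rng, (d_in, 4 * d_hidden), s))
        self.wh = module._register(f"{tag}.wh", _param(rng, (d_hidden, 4 * d_hidden), s))
        b0 = np.zeros(4 * d_hidden)
        b0[d_hidden:2 * d_hidden] = 1.0  # forget-gate bias: retain memory early
        b = Tensor(b0, requires_grad=True)
        self.b = module._register(f"{tag}.b", b)

    def run(self, xs: list[Tensor], batch: int) -> tuple[list[Tensor], Tensor]:
        """Consume a list of (B, d_in) inputs; return per-step hidden states
        and the final hidden state."""
        H = self.h
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        out = []
        for x in xs:
            z = x @ self.wx + h @ self.wh + self.b
            i = z[:, 0 * H:1 * H].sigmoid()
            f = z[:, 1 * H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out, h


class LstmAutoencoderNet(_Module):
    """Sequence-to-sequence LSTM autoencoder.

    Parameters
    ----------
    n_channels : input/output channels per timestep (6 for a 6-axis IMU).
    hidden_sizes : hidden units of the stacked encoder LSTMs; the decoder
        mirrors them.  The latent dimension is ``sum(hidden_sizes)`` (the
        concatenated final hidden states), e.g. (128, 128) -> 256.
    seed : initialization seed.
    """

    def __init__(self, n_channels: int = 6, hidden_sizes: tuple[int, ...] = (128, 128),
                 seed: int = 0):
        super().__init__()
        if n_channels <= 0:
            raise ValueError("n_channels must be positive")
        self.n_channels = int(n_channels)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive")
        self.latent_dim = sum(self.hidden_sizes)
        rng = np.random.default_rng(seed)
        self.enc = []
        d = self.n_channels
        for li, h in enumerate(self.hidden_sizes):
            self.enc.append(_LstmLayer(self, f"enc{li}", d, h, rng))
            d = h
        self.dec = []
        d = self.latent_dim
        for li, h in enumerate(self.hidden_sizes):
            self.dec.append(_LstmLayer(self, f"dec{li}", d, h, rng))
            d = h
        s = 1.0 / math.sqrt(self.latent_dim)
        self.w_out = self._register("out.w", _param(rng, (self.latent_dim, self.n_channels), s))
        self.b_out = self._register("out.b", Tensor(np.zeros(self.n_channels), requires_grad=True))

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """(B, T, C) -> (B, T, C) reconstruction."""
        x = Tensor._lift(x)
        B, T, C = x.shape
        if C != self.n_channels:
            raise ValueError(f"expected {self.n_channels} channels, got {C}")
        steps = [x[:, t, :] for t in range(T)]
        finals = []
        for layer in self.enc:
            steps, h_last = layer.run(steps, B)
            finals.append(h_last)
        z = concat(finals, axis=1)  # (B, latent)
        dec_in = [z] * T
        layer_outs = []
        for layer in self.dec:
            dec_in, _ = layer.run(dec_in, B)
            layer_outs.append(dec_in)
        # concatenate the per-step hidden states of every decoder layer
        rows = []
        for t in range(T):
            ht = concat([outs[t] for outs in layer_outs], axis=1)
            rows.append((ht @ self.w_out + self.b_out).reshape(B, 1, C))
        return concat(rows, axis=1)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Inference-only reconstruction of (B, T, C) or (T, C)."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        out = self.forward(Tensor(x)).data
        return out[0] if single else out


def _sinusoidal_encoding(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.zeros((T, d))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class TransformerClassifierNet(_Module):
    """Pre-norm Transformer encoder with a softmax classification head.

    Input (B, T, d_in) -> class probabilities (B, n_classes).  Feed-forward
    width is 4x the model dimension; the sequence embedding is the mean over
    timesteps of the final encoder output.
    """

    def __init__(self, d_in: int = 66, d_model: int = 256, n_layers: int = 4,
                 n_heads: int = 8, seq_len: int = 30, n_classes: int = 2,
                 seed: int = 0, input_center: float = 0.5,
                 input_scale: float = 4.0, pe_scale: float = 0.3):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_in, self.d_model = int(d_in), int(d_model)
        self.n_layers, self.n_heads = int(n_layers), int(n_heads)
        self.seq_len, self.n_classes = int(seq_len), int(n_classes)
        # normalized pose coordinates live in [0, 1] with small dynamic
        # range; recentre and rescale them so the projected signal is not
        # drowned by the positional encoding
        self.input_center = float(input_center)
        self.input_scale = float(input_scale)
        self.pe_scale = float(pe_scale)
        rng = np.random.default_rng(seed)
        s_in = 1.0 / math.sqrt(d_in)
        s_d = 1.0 / math.sqrt(d_model)
        self.w_in = self._register("in.w", _param(rng, (d_in, d_model), s_in))
        self.b_in = self._register("in.b", Tensor(np.zeros(d_model), requires_grad=True))
        self.pe = _sinusoidal_encoding(self.seq_len, d_model)
        self.layers = []
        for li in range(n_layers):
            lp = {}
            for nm in ("wq", "wk", "wv", "wo"):
                lp[nm] = self._register(f"l{li}.{nm}", _param(rng, (d_model, d_model), s_d))
                lp[nm + "_b"] = self._register(f"l{li}.{nm}_b",
                                               Tensor(np.zeros(d_model), requires_grad=True))
            lp["w1"] = self._register(f"l{li}.w1", _param(rng, (d_model, 4 * d_model), s_d))
            lp["b1"] = self._register(f"l{li}.b1",
                                      Tensor(np.zeros(4 * d_model), requires_grad=True))
            lp["w2"] = self._register(f"l{li}.w2",
                                      _param(rng, (4 * d_model, d_model), 0.5 / math.sqrt(d_model)))
            lp["b2"] = self._register(f"l{li}.b2",
                                      Tensor(np.zeros(d_model), requires_grad=True))
            for ln in ("ln1", "ln2"):
                lp[ln + "_g"] = self._register(f"l{li}.{ln}_g",
                                               Tensor(np.ones(d_model), requires_grad=True))
                lp[ln + "_b"] = self._register(f"l{li}.{ln}_b",
                                               Tensor(np.zeros(d_model), requires_grad=True))
            self.layers.append(lp)
        self.lnf_g = self._register("lnf.g", Tensor(np.ones(d_model), requires_grad=True))
        self.lnf_b = self._register("lnf.b", Tensor(np.zeros(d_model), requires_grad=True))
        self.w_head = self._register("head.w", _param(rng, (d_model, n_classes), s_d))
        self.b_head = self._register("head.b", Tensor(np.zeros(n_classes), requires_grad=True))

    @staticmethod
    def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + eps) ** -0.5 * g + b

    def _attention(self, x: Tensor, lp: dict) -> Tensor:
        B, T, d = x.shape
        h, dh = self.n_heads, self.d_model // self.n_heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose(0, 2, 1, 3)  # (B, h, T, dh)

        q = split(x @ lp["wq"] + lp["wq_b"])
        k = split(x @ lp["wk"] + lp["wk_b"])
        v = split(x @ lp["wv"] + lp["wv_b"])
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        att = softmax(scores, axis=-1) @ v  # (B, h, T, dh)
        merged = att.transpose(0, 2, 1, 3).reshape(B, T, d)
        return merged @ lp["wo"] + lp["wo_b"]

    def logits(self, x: np.ndarray | Tensor) -> Tensor:
        x = Tensor._lift(x)
        B, T, d_in = x.shape
        if d_in != self.d_in:
            raise ValueError(f"expected feature dim {self.d_in}, got {d_in}")
        if T != self.seq_len:
            raise ValueError(f"expected sequence length {self.seq_len}, got {T}")
        x = (x - self.input_center) * self.input_scale
        hx = x @ self.w_in + self.b_in + Tensor(self.pe_scale * self.pe[None, :, :])
        for lp in self.layers:
            hx = hx + self._attention(self._layer_norm(hx, lp["ln1_g"], lp["ln1_b"]), lp)
            ff = self._layer_norm(hx, lp["ln2_g"], lp["ln2_b"])
            ff = (ff @ lp["w1"] + lp["b1"]).relu() @ lp["w2"] + lp["b2"]
            hx = hx + ff
        pooled = self._layer_norm(hx, self.lnf_g, self.lnf_b).mean(axis=1)
        return pooled @ self.w_head + self.b_head

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        p = softmax(self.logits(Tensor(x)), axis=-1).data
        return p[0] if single else p


class Adam:
    """Adam with optional per-step learning-rate schedule."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainRecipe:
    """Optimization hyper-parameters for a training run."""

    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    patience: int = 10
    val_frac: float = 0.15
    test_frac: float = 0.0   # classifier default is a 70/15/15 split
    cosine_annealing: bool = False
    history: list = field(default_factory=list, repr=False)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield idx[lo:lo + batch_size]


def fit_autoencoder(net: LstmAutoencoderNet, windows: np.ndarray,
                    recipe: TrainRecipe, seed: int = 0) -> dict:
    """Train the autoencoder on (N, T, C) windows with MSE loss.

    A validation split (``recipe.val_frac``) is held out for early stopping;
    the best-validation parameters are restored.  Returns a dict with the
    loss ``history`` (per-epoch train/val MSE) and ``n_epochs`` actually run.
    """
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim != 3 or len(windows) == 0:
        raise ValueError("windows must be a non-empty (N, T, C) array")
    rng = np.random.default_rng(seed)
    n = len(windows)
    perm = rng.permutation(n)
    n_val = max(1, int(round(recipe.val_frac * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm
    Xtr, Xval = windows[tr_idx], windows[val_idx]
    opt = Adam(net.parameters(), lr=recipe.lr)
    best_val = np.inf
    best_state = net.state_dict()
    stall = 0
    history = []
    for epoch in range(recipe.epochs):
        lr = recipe.lr
        if recipe.cosine_annealing and recipe.epochs > 1:
            lr = recipe.lr * 0.5 * (1 + math.cos(math.pi * epoch / (recipe.epochs - 1)))
        tr_losses = []
        for bidx in _batches(len(Xtr), recipe.batch_size, rng):
            xb = Tensor(Xtr[bidx])
            xhat = net.forward(xb)
            resid = xhat - xb
            loss = (resid * resid).mean()
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            tr_losses.append(float(loss.data))
        if len(Xval):
            val_resid = net.reconstruct(Xval) - Xval
            val_loss = float(np.mean(val_resid ** 2))
        else:
            val_loss = float(np.mean(tr_losses))
        history.append({"epoch": epoch, "train": float(np.mean(tr_losses)), "val": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= recipe.patience:
                break
    net.load_state_dict(best_state)
    return {"history": history, "n_epochs": len(history), "best_val": best_val}


def _classifier_epilogue(net, Xte, yte, history, best_val, Xtr, Xval):
    info = {"history": history, "n_epochs": len(history), "best_val": best_val,
            "split_sizes": (len(Xtr), len(Xval), len(Xte))}
    if len(Xte):
        pred = softmax(net.logits(Tensor(Xte)), axis=-1).data.argmax(axis=1)
        info["test_accuracy"] = float((pred == yte).mean())
    return info


def fit_classifier(net: TransformerClassifierNet, X: np.ndarray, y: np.ndarray,
                   recipe: TrainRecipe, seed: int = 0) -> dict:
    """Train the Transformer classifier with cross-entropy.

    The data are split class-stratified into train / validation / held-out
    test partitions (fractions 1 - val_frac - test_frac / val_frac /
    test_frac); early stopping monitors validation loss, the best checkpoint
    is restored, and test accuracy (when a test split exists) is reported.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) != len(y) or len(X) == 0:
        raise ValueError("X and y must be non-empty and aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)

    def _allocate(frac: float) -> dict:
        """Per-class counts summing exactly to round(frac * n): floors plus
        largest-remainder top-up."""
        classes = np.unique(y)
        target = int(round(frac * len(y)))
        ideal = {c: frac * int((y == c).sum()) for c in classes}
        counts = {c: int(np.floor(v)) for c, v in ideal.items()}
        order = sorted(classes, key=lambda c: ideal[c] - counts[c], reverse=True)
        for c in order:
            if sum(counts.values()) >= target:
                break
            counts[c] += 1
        return counts

    n_val_c = _allocate(recipe.val_frac)
    n_test_c = _allocate(recipe.test_frac)
    val_idx, test_idx = [], []
    for cls in np.unique(y):
        cls_idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = n_val_c[cls]
        if len(cls_idx) > 1 and recipe.val_frac > 0:
            n_val = max(1, n_val)
        val_idx.extend(cls_idx[:n_val])
        test_idx.extend(cls_idx[n_val:n_val + n_test_c[cls]])
    val_mask = np.zeros(len(y), bool)
    val_mask[val_idx] = True
    test_mask = np.zeros(len(y), bool)
    test_mask[test_idx] = True
    Xtr, ytr = X[~val_mask & ~test_mask], y[~val_mask & ~test_mask]
    Xval, yval = X[val_mask], y[val_mask]
    Xte, yte = X[test_mask], y[test_mask]
    if len(np.unique(ytr)) < 2:
        Xtr, ytr = X, y
    opt = Adam(net.parameters(), lr=recipe.lr)
    best_val = np.inf
    best_state = net.state_dict()
    stall = 0
    history = []

    def nll(logits: Tensor, labels: np.ndarray) -> Tensor:
        lp = log_softmax(logits, axis=-1)
        return -lp[np.arange(len(labels)), labels].mean()

    for epoch in range(recipe.epochs):
        lr = recipe.lr
        if recipe.cosine_annealing and recipe.epochs > 1:
            lr = recipe.lr * 0.5 * (1 + math.cos(math.pi * epoch / (recipe.epochs - 1)))
        tr_losses = []
        for bidx in _batches(len(Xtr), recipe.batch_size, rng):
            logits = net.logits(Tensor(Xtr[bidx]))
            loss = nll(logits, ytr[bidx])
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            tr_losses.append(float(loss.data))
        if len(Xval):
            val_loss = float(nll(net.logits(Tensor(Xval)), yval).data)
        else:
            val_loss = float(np.mean(tr_losses))
        history.append({"epoch": epoch, "train": float(np.mean(tr_losses)), "val": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= recipe.patience:
                break
    net.load_state_dict(best_state)
    return _classifier_epilogue(net, Xte, yte, history, best_val, Xtr, Xval)
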