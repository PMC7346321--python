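"""Deep pyramid character-level CNN (EnDCNN) for CVD prediction.

Architecture: a text region embedding (``W x + b`` over the concatenated
one-hot vectors of a k-token window, no nonlinearity — activation is
delayed to the next layer's pre-activation), followed by convolution
blocks. Each block is two same-length convolutions with *pre-activation*
(``W sigma(x) + b`` with the rectifier applied before weighting) wrapped in
an identity shortcut ``z + f(z)``. Between blocks, size-3 stride-2 max
pooling halves the representation length while the number of feature maps
stays fixed, so per-block computation halves at every level and the total
is bounded by about twice the first block. A final max pool aggregates the
document into one feature vector, and a linear + normalized-exponential
head yields the (no-CVD, CVD) probability pair.

All representations are ``m x length`` arrays (feature maps x positions).
Gradients are hand-written and verified against finite differences in the
test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np

from .optim import Adam, clip_gradients, learning_rate


@dataclass
class EnDCNNConfig:
    """Hyperparameters. Defaults: region size k=7 (one mention+label unit),
    250 feature maps, kernel 3, stride 2, depth 15 weight layers
    (1 region embedding + 7 blocks x 2 convolutions), lr 0.001 decayed by
    0.99 every 500 steps, batch 64, keep rate 0.5, 30 epochs."""

    region_size: int = 7
    feature_maps: int = 250
    kernel_size: int = 3
    pool_stride: int = 2
    depth: int = 15
    lr: float = 0.001
    decay_rate: float = 0.99
    decay_steps: int = 500
    batch_size: int = 64
    keep_prob: float = 0.5
    epochs: int = 30
    clip_norm: float = 5.0
    #: where inverted dropout (keep rate ``keep_prob``) is applied during
    #: training; any subset of {"region", "final"}
    dropout_sites: tuple[str, ...] = ("region", "final")
    #: width of one (mention, label) unit in the input sequence
    unit_width: int = 7
    #: shuffle whole units per training example: the document label is a
    #: function of the mention multiset, so unit order is an invariance the
    #: training should exploit (set False for order-sensitive inputs)
    unit_permute: bool = True
    #: probability of replacing an input token with UNK during training
    #: (word dropout); discourages reliance on co-occurring surface tokens
    token_dropout: float = 0.15
    #: decoupled L2 weight decay per update
    weight_decay: float = 1e-4
    #: Polyak/EMA averaging factor for the returned weights (0 disables)
    ema_decay: float = 0.995

    @property
    def num_blocks(self) -> int:
        # depth counts weight layers: 1 region embedding + 2 per block
        if self.depth < 3 or (self.depth - 1) % 2:
            raise ValueError("depth must be odd and >= 3 (1 + 2 per block)")
        return (self.depth - 1) // 2


def _padded_indices(indices: np.ndarray, k: int) -> np.ndarray:
    # centered window (an even k takes one extra position to the right);
    # positions beyond the edges hold the PAD index 0
    left = (k - 1) // 2
    padded = np.zeros(len(indices) + k - 1, dtype=np.int64)
    padded[left : left + len(indices)] = indices
    return padded


def region_embed(
    indices: np.ndarray, W: np.ndarray, b: np.ndarray, k: int, v: int
) -> np.ndarray:
    """Region embedding: one ``m``-vector per position from the ``k*v``-dim
    concatenation of the k one-hot vectors around it (PAD index 0 beyond
    the edges). No activation is applied here."""
    m = W.shape[0]
    if W.shape[1] != k * v:
        raise ValueError(f"W columns {W.shape[1]} != k*v = {k * v}")
    n = len(indices)
    W3 = W.reshape(m, k, v)
    padded = _padded_indices(indices, k)
    out = np.tile(b[:, None], (1, n)).astype(np.float64)
    for j in range(k):
        out += W3[:, j, padded[j : j + n]]
    return out


def _region_embed_backward(
    dout: np.ndarray, indices: np.ndarray, W: np.ndarray, k: int, v: int
) -> tuple[np.ndarray, np.ndarray]:
    m = W.shape[0]
    n = len(indices)
    dW3 = np.zeros((m, k, v))
    padded = _padded_indices(indices, k)
    for j in range(k):
        np.add.at(dW3.transpose(1, 2, 0)[j], padded[j : j + n], dout.T)
    return dW3.reshape(m, k * v), dout.sum(axis=1)


def _im2col(a: np.ndarray, ks: int) -> np.ndarray:
    """Zero-padded same-length column matrix: (ks*m, L) from (m, L)."""
    m, L = a.shape
    left = (ks - 1) // 2
    pad = np.zeros((m, L + ks - 1))
    pad[:, left : left + L] = a
    return np.concatenate([pad[:, j : j + L] for j in range(ks)], axis=0)


def _col2im(dcol: np.ndarray, m: int, ks: int, L: int) -> np.ndarray:
    left = (ks - 1) // 2
    dpad = np.zeros((m, L + ks - 1))
    for j in range(ks):
        dpad[:, j : j + L] += dcol[j * m : (j + 1) * m]
    return dpad[:, left : left + L]


def conv_preact(
    x: np.ndarray, W: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Pre-activation convolution ``W sigma(x) + b`` at every position;
    same-length with zero padding, rectifier sigma applied before
    weighting."""
    m = x.shape[0]
    ks = W.shape[1] // m
    if W.shape[1] != ks * m or W.shape[0] != m:
        raise ValueError("conv weight shape does not match feature maps")
    a = np.maximum(x, 0.0)
    return W @ _im2col(a, ks) + b[:, None]


def conv_block(x: np.ndarray, W1, b1, W2, b2) -> np.ndarray:
    """Identity-shortcut block: ``z + f(z)`` with f two pre-activation
    convolutions. Output shape always equals input shape."""
    return x + conv_preact(conv_preact(x, W1, b1), W2, b2)


def _pool_pad(x: np.ndarray) -> tuple[np.ndarray, int]:
    # size-3 windows centered at positions 0, 2, 4, ...; -inf padding on
    # both edges so the output length is exactly ceil(L / 2)
    m, L = x.shape
    out_len = ceil(L / 2)
    pad = np.full((m, L + 2), -np.inf)
    pad[:, 1 : 1 + L] = x
    return pad, out_len


def downsample(x: np.ndarray) -> np.ndarray:
    """Size-3 stride-2 max pooling over positions, halving the length
    (``ceil(L / 2)``) while the feature-map count stays fixed."""
    pad, out_len = _pool_pad(x)
    wins = np.stack([pad[:, 2 * t : 2 * t + 3] for t in range(out_len)], axis=2)
    return wins.max(axis=1)


def final_pool(x: np.ndarray) -> np.ndarray:
    """Component-wise max over all positions -> one m-vector per document."""
    if x.shape[1] < 1:
        raise ValueError("empty representation")
    return x.max(axis=1)


class EnDCNNModel:
    """EnDCNN parameters over a unit-token vocabulary."""

    def __init__(
        self,
        vocab_size: int,
        config: EnDCNNConfig | None = None,
        seed: int = 0,
        zero_blocks: bool = False,
        init_scale: float = 0.05,
    ) -> None:
        self.config = config or EnDCNNConfig()
        self.vocab_size = vocab_size
        c = self.config
        rng = np.random.default_rng(seed)
        m, k, ks = c.feature_maps, c.region_size, c.kernel_size

        # region embedding sees a k-hot input; head sees an m-vector
        self.params: dict[str, np.ndarray] = {
            "Wr": rng.normal(0.0, init_scale, (m, k * vocab_size)),
            "br": np.zeros(m),
            "Wh": rng.normal(0.0, np.sqrt(1.0 / m), (2, m)),
            "bh": np.zeros(2),
        }
        for i in range(c.num_blocks):
            if zero_blocks:
                self.params[f"W{i}a"] = np.zeros((m, ks * m))
                self.params[f"W{i}b"] = np.zeros((m, ks * m))
            else:
                # He init for the rectified convolution layers
                std = np.sqrt(2.0 / (ks * m))
                self.params[f"W{i}a"] = rng.normal(0.0, std, (m, ks * m))
                self.params[f"W{i}b"] = rng.normal(0.0, std, (m, ks * m))
            self.params[f"b{i}a"] = np.zeros(m)
            self.params[f"b{i}b"] = np.zeros(m)

    # --- forward ------------------------------------------------------------

    def forward(
        self,
        units: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        trace: list | None = None,
    ) -> np.ndarray:
        """Probability pair (no-CVD, CVD) for one unit-index sequence.

        With ``train=True`` inverted dropout (keep rate ``kp``) is applied
        after the region embedding and on the final pooled vector. If
        ``trace`` is a list, the shapes of every shortcut addition's two
        operands are appended to it.
        """
        probs, _ = self._forward_cache(units, train=train, rng=rng, trace=trace)
        return probs

    def _forward_cache(self, units, train=False, rng=None, trace=None):
        c = self.config
        units = np.asarray(units, dtype=np.int64)
        if units.size == 0:
            raise ValueError("empty unit sequence")
        p = self.params
        cache: dict = {"units": units, "train": train}
        x = region_embed(units, p["Wr"], p["br"], c.region_size, self.vocab_size)
        if train and "region" in c.dropout_sites:
            mask = (rng.random(x.shape) < c.keep_prob) / c.keep_prob
            cache["drop0"] = mask
            x = x * mask
        reps = []
        for i in range(c.num_blocks):
            if i > 0 and x.shape[1] >= 2:
                cache.setdefault("pooled", []).append(i)
                reps.append(("pre_pool", x))
                x = downsample(x)
            z = x
            h1 = conv_preact(z, p[f"W{i}a"], p[f"b{i}a"])
            fz = conv_preact(h1, p[f"W{i}b"], p[f"b{i}b"])
            if trace is not None:
                trace.append((z.shape, fz.shape))
            reps.append((f"block{i}", z, h1, fz))
            x = z + fz
        cache["reps"] = reps
        cache["pre_final"] = x
        vpool = final_pool(x)
        cache["argmax"] = x.argmax(axis=1)
        if train and "final" in c.dropout_sites:
            mask2 = (rng.random(vpool.shape) < c.keep_prob) / c.keep_prob
            cache["drop1"] = mask2
            vpool = vpool * mask2
        cache["v"] = vpool
        logits = p["Wh"] @ vpool + p["bh"]
        logits -= logits.max()
        e = np.exp(logits)
        probs = e / e.sum()
        cache["probs"] = probs
        return probs, cache

    # --- backward -----------------------------------------------------------

    def _backward(self, cache: dict, label: int) -> dict[str, np.ndarray]:
        """Gradients of -log p(label) w.r.t. all parameters."""
        c = self.config
        p = self.params
        m = c.feature_maps
        ks = c.kernel_size
        probs = cache["probs"]
        dlogits = probs.copy()
        dlogits[label] -= 1.0
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wh"] = np.outer(dlogits, cache["v"])
        grads["bh"] = dlogits
        dv = p["Wh"].T @ dlogits
        if "drop1" in cache:
            dv = dv * cache["drop1"]
        # final max pool: route into argmax positions
        dx = np.zeros_like(cache["pre_final"])
        dx[np.arange(m), cache["argmax"]] = dv

        def conv_backward(dout, x, W, name_w, name_b):
            a = np.maximum(x, 0.0)
            col = _im2col(a, ks)
            grads[name_w] += dout @ col.T
            grads[name_b] += dout.sum(axis=1)
            da = _col2im(W.T @ dout, m, ks, x.shape[1])
            return da * (x > 0)

        for rep in reversed(cache["reps"]):
            if rep[0] == "pre_pool":
                # max-pool backward: scatter to argmax within each window
                x_in = rep[1]
                L = x_in.shape[1]
                pad, out_len = _pool_pad(x_in)
                dpad = np.zeros_like(pad)
                for t in range(out_len):
                    win = pad[:, 2 * t : 2 * t + 3]
                    am = win.argmax(axis=1)
                    dpad[np.arange(m), 2 * t + am] += dx[:, t]
                dx = dpad[:, 1 : 1 + L]
                continue
            name, z, h1, fz = rep
            i = int(name.removeprefix("block"))
            dz_shortcut = dx  # identity path
            dh1 = conv_backward(dx, h1, p[f"W{i}b"], f"W{i}b", f"b{i}b")
            dz_conv = conv_backward(dh1, z, p[f"W{i}a"], f"W{i}a", f"b{i}a")
            dx = dz_shortcut + dz_conv
        if "drop0" in cache:
            dx = dx * cache["drop0"]
        dWr, dbr = _region_embed_backward(
            dx, cache["units"], p["Wr"], c.region_size, self.vocab_size
        )
        grads["Wr"] += dWr
        grads["br"] += dbr
        return grads

    # --- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        header = json.dumps({"vocab_size": self.vocab_size,
                             "config": vars(self.config)})
        np.savez(path, _header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "EnDCNNModel":
        data = np.load(path)
        header = json.loads(bytes(data["_header"]).decode())
        model = cls(header["vocab_size"], EnDCNNConfig(**header["config"]))
        for k in model.params:
            model.params[k] = data[k]
        return model


def train_classifier(
    dataset: list[tuple[np.ndarray, int]],
    config: EnDCNNConfig | None = None,
    vocab_size: int | None = None,
    seed: int = 0,
    log_every: int = 0,
) -> tuple[EnDCNNModel, list[float]]:
    """Train an EnDCNN on (unit-index sequence, label) pairs.

    Mini-batch gradient descent with Adam: gradients are averaged over
    batches of ``B`` documents, the learning rate decays as
    ``lr * dr ** (step / ds)``, and the global gradient norm is clipped.
    Regularization beyond the two dropout sites: per-example unit
    permutation (the label is multiset-valued over mentions), uniform
    input-token dropout to UNK, decoupled L2 weight decay, and an
    exponential moving average of the weights which becomes the returned
    model. Returns (model, per-epoch mean cross-entropy).
    """
    if not dataset:
        raise ValueError("empty dataset")
    labels = {int(lbl) for _, lbl in dataset}
    if len(labels) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    config = config or EnDCNNConfig()
    if vocab_size is None:
        vocab_size = int(max(int(np.max(u)) for u, _ in dataset)) + 1
    model = EnDCNNModel(vocab_size, config, seed=seed)
    opt = Adam(model.params, lr=config.lr, decay_rate=config.decay_rate,
               decay_steps=config.decay_steps)
    ema = {k: v.copy() for k, v in model.params.items()}
    rng = np.random.default_rng(seed + 1)
    losses: list[float] = []
    n = len(dataset)
    w = config.unit_width
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for bstart in range(0, n, config.batch_size):
            batch = order[bstart : bstart + config.batch_size]
            acc: dict[str, np.ndarray] | None = None
            for j in batch:
                units, label = dataset[j]
                if config.unit_permute and len(units) % w == 0:
                    cells = units.reshape(len(units) // w, w)
                    units = cells[rng.permutation(len(cells))].reshape(-1)
                if config.token_dropout > 0:
                    drop = rng.random(len(units)) < config.token_dropout
                    units = np.where(drop, 1, units)  # UNK index
                probs, cache = model._forward_cache(units, train=True, rng=rng)
                total += -float(np.log(max(probs[label], 1e-12)))
                g = model._backward(cache, int(label))
                if acc is None:
                    acc = g
                else:
                    for k in acc:
                        acc[k] += g[k]
            assert acc is not None
            for k in acc:
                acc[k] /= len(batch)
            clip_gradients(acc, config.clip_norm)
            opt.step(acc)
            for k, p in model.params.items():
                if config.weight_decay:
                    p *= 1.0 - config.weight_decay
                if config.ema_decay:
                    ema[k] = config.ema_decay * ema[k] + (1 - config.ema_decay) * p
        losses.append(total / n)
        if log_every and (epoch + 1) % log_every == 0:
            print(f"[classifier] epoch {epoch + 1}/{config.epochs} "
                  f"mean CE {losses[-1]:.4f}")
    if config.ema_decay:
        model.params = ema
    return model, losses


def reduced_synthetic_config() -> EnDCNNConfig:
    """Down-scaled configuration for the synthetic planted-rule study:
    32 feature maps, 3 blocks (depth 7), 150 epochs with a faster
    learning-rate anneal. All regularizers keep their defaults."""
    return EnDCNNConfig(
        feature_maps=32, depth=7, epochs=150, decay_rate=0.9, decay_steps=200
    )


# --- analytic instrumentation ---------------------------------------------


def count_macs(config: EnDCNNConfig, doc_length: int) -> list[int]:
    """Analytic multiply-accumulate count per convolution block.

    Block ``l`` (0-based) runs at length ``ceil(doc_length / 2**l)`` after
    ``l`` stride-2 poolings, with ``2 * ks * m**2`` MACs per position (two
    convolution layers). Halving the length halves per-block cost, so the
    series is bounded by about twice the first block.
    """
    if doc_length < 1:
        raise ValueError("doc_length must be >= 1")
    c = config
    per_pos = 2 * c.kernel_size * c.feature_maps**2
    return [per_pos * ceil(doc_length / 2**level) for level in range(c.num_blocks)]


def receptive_field(config: EnDCNNConfig, num_pools: int) -> int:
    """Receptive field (positions of the original document covered by one
    final-layer feature) after ``num_pools`` pool+block stages.

    Exact recurrence with cumulative stride ``j``: start at the region size
    ``k``; each convolution layer adds ``(ks - 1) * j``; each pool adds
    ``(3 - 1) * j`` and then doubles ``j``. Grows like 2**num_pools.
    """
    if num_pools < 0:
        raise ValueError("num_pools must be >= 0")
    c = config
    r, j = c.region_size, 1
    r += 2 * (c.kernel_size - 1) * j  # first block
    for _ in range(num_pools):
        r += 2 * j  # pool, size 3
        j *= 2
        r += 2 * (c.kernel_size - 1) * j  # following block
    return r


def cumulative_stride(num_pools: int) -> int:
    """Product of pool strides after ``num_pools`` stride-2 poolings."""
    return 2**num_pools


def classifier_learning_rate(config: EnDCNNConfig, step: int) -> float:
    """lr at global step under the configured exponential decay."""
    return learning_rate(config.lr, config.decay_rate, config.decay_steps, step)
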