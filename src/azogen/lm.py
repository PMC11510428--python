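"""Decoder-only attention sequence model for SMILES, in pure numpy.

A small causal language model: token + position embeddings, pre-LayerNorm
transformer blocks (multi-head causal self-attention and a GELU MLP), a
final LayerNorm and a linear head.  Forward, backward (manual
backpropagation), AdamW with cosine learning-rate annealing, likelihood
evaluation and ancestral sampling are all implemented here so the whole
pipeline runs on a CPU with no deep-learning framework.

Weight matrices may carry low-rank adapters (see :mod:`azogen.dpo`): a
target matrix W is used as W + A·B with A (d_in×r) and B (r×d_out).  The
forward/backward paths here account for adapters transparently; with B
initialized to zero the adapted model is exactly the base model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from azogen.chem import has_bonded_nn, parse_smiles, SmilesError
from azogen.tokenizer import Tokenizer

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ModelState",
    "GenerationReport",
    "init_model",
    "train",
    "evaluate_nll",
    "sequence_logprob",
    "next_token_logprobs",
    "sample",
]

_DTYPE = np.float32


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    context_length: int = 64
    embedding_dim: int = 128
    n_layers: int = 2
    n_heads: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.embedding_dim % self.n_heads != 0:
            raise ValueError("embedding_dim must be divisible by n_heads")
        if self.vocab_size < 4 or self.context_length < 4:
            raise ValueError("degenerate model configuration")


@dataclass
class TrainConfig:
    """Optimization settings: decoupled-weight-decay Adam with cosine
    annealing of the learning rate between the configured endpoints."""

    initial_lr: float = 5e-4
    final_lr: float = 5e-8
    batch_size: int = 64
    epochs: int = 10
    weight_decay: float = 0.01
    grad_clip: float = 1.0
    seed: int = 0


@dataclass
class ModelState:
    """Parameters + config (+ optional low-rank adapters and training log)."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    adapters: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    frozen_base: bool = False
    training_log: list[tuple[int, float, float]] = field(default_factory=list)
    tokenizer_fingerprint: str | None = None

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            adapters=None
            if self.adapters is None
            else {k: (a.copy(), b.copy()) for k, (a, b) in self.adapters.items()},
            frozen_base=self.frozen_base,
            training_log=list(self.training_log),
            tokenizer_fingerprint=self.tokenizer_fingerprint,
        )

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def n_adapter_parameters(self) -> int:
        if not self.adapters:
            return 0
        return int(sum(a.size + b.size for a, b in self.adapters.values()))

    # --- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.params)
        if self.adapters:
            for k, (a, b) in self.adapters.items():
                arrays[f"adapter:{k}:A"] = a
                arrays[f"adapter:{k}:B"] = b
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "config": self.config.__dict__,
            "frozen_base": self.frozen_base,
            "tokenizer_fingerprint": self.tokenizer_fingerprint,
            "training_log": self.training_log,
            "adapter_targets": sorted(self.adapters) if self.adapters else [],
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    def save_adapters(self, path: str | Path) -> None:
        """Serialize the low-rank adapters alone (without base weights)."""
        if not self.adapters:
            raise ValueError("model has no adapters")
        arrays = {}
        for k, (a, b) in self.adapters.items():
            arrays[f"{k}:A"] = a
            arrays[f"{k}:B"] = b
        np.savez(Path(path).with_suffix(".npz"), **arrays)

    def load_adapters(self, path: str | Path) -> "ModelState":
        """Return a copy of this state carrying adapters read from ``path``."""
        data = np.load(Path(path).with_suffix(".npz"))
        adapters: dict[str, list] = {}
        for k in data.files:
            name, which = k.rsplit(":", 1)
            adapters.setdefault(name, [None, None])
            adapters[name][0 if which == "A" else 1] = data[k]
        state = self.copy()
        state.adapters = {k: (a, b) for k, (a, b) in adapters.items()}
        state.frozen_base = True
        return state

    @staticmethod
    def load(path: str | Path) -> "ModelState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        params, adapters = {}, {}
        for k in data.files:
            if k.startswith("adapter:"):
                _, name, which = k.split(":")
                adapters.setdefault(name, [None, None])
                adapters[name][0 if which == "A" else 1] = data[k]
            else:
                params[k] = data[k]
        return ModelState(
            config=ModelConfig(**meta["config"]),
            params=params,
            adapters={k: (a, b) for k, (a, b) in adapters.items()} or None,
            frozen_base=meta["frozen_base"],
            training_log=[tuple(t) for t in meta["training_log"]],
            tokenizer_fingerprint=meta["tokenizer_fingerprint"],
        )


def init_model(cfg: ModelConfig) -> ModelState:
    """Randomly initialized model; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    d, V, T = cfg.embedding_dim, cfg.vocab_size, cfg.context_length
    std = 0.02

    def w(*shape):
        return (rng.standard_normal(shape) * std).astype(_DTYPE)

    p: dict[str, np.ndarray] = {
        "tok_emb": w(V, d),
        "pos_emb": w(T, d),
        "lnf_g": np.ones(d, dtype=_DTYPE),
        "lnf_b": np.zeros(d, dtype=_DTYPE),
        "head": w(d, V),
    }
    for i in range(cfg.n_layers):
        p[f"l{i}.ln1_g"] = np.ones(d, dtype=_DTYPE)
        p[f"l{i}.ln1_b"] = np.zeros(d, dtype=_DTYPE)
        p[f"l{i}.wq"] = w(d, d)
        p[f"l{i}.wk"] = w(d, d)
        p[f"l{i}.wv"] = w(d, d)
        p[f"l{i}.wo"] = w(d, d)
        p[f"l{i}.ln2_g"] = np.ones(d, dtype=_DTYPE)
        p[f"l{i}.ln2_b"] = np.zeros(d, dtype=_DTYPE)
        p[f"l{i}.w1"] = w(d, 4 * d)
        p[f"l{i}.b1"] = np.zeros(4 * d, dtype=_DTYPE)
        p[f"l{i}.w2"] = w(4 * d, d)
        p[f"l{i}.b2"] = np.zeros(d, dtype=_DTYPE)
    return ModelState(config=cfg, params=p)


# ---------------------------------------------------------------------------
# forward / backward primitives
# ---------------------------------------------------------------------------

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def _gelu(x):
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
    return 0.5 * x * (1.0 + np.tanh(inner))


def _gelu_grad(x):
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * _SQRT_2_OVER_PI * (
        1.0 + 3 * 0.044715 * x**2
    )


def _layernorm(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    ivar = 1.0 / np.sqrt((xc**2).mean(-1, keepdims=True) + eps)
    xhat = xc * ivar
    return g * xhat + b, (xhat, ivar)

def _layernorm_bwd(dy, g, cache):
    xhat, ivar = cache
    red = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=red)
    db = dy.sum(axis=red)
    dxhat = dy * g
    dx = ivar * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _eff_weight(state: ModelState, name: str) -> np.ndarray:
    W = state.params[name]
    if state.adapters and name in state.adapters:
        A, B = state.adapters[name]
        return W + A @ B
    return W


def _forward(state: ModelState, ids: np.ndarray, want_cache: bool = False):
    """Logits (B,T,V) for a padded id batch; optional cache for backward."""
    cfg = state.config
    p = state.params
    B, T = ids.shape
    if T > cfg.context_length:
        raise ValueError(f"sequence length {T} exceeds context {cfg.context_length}")
    d, nh = cfg.embedding_dim, cfg.n_heads
    hd = d // nh
    x = p["tok_emb"][ids] + p["pos_emb"][:T]
    mask = np.triu(np.full((T, T), -1e9, dtype=_DTYPE), k=1)
    cache: dict = {"ids": ids, "layers": []}
    for i in range(cfg.n_layers):
        pre = f"l{i}."
        h, ln1c = _layernorm(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
        h2 = h.reshape(B * T, d)
        q = (h2 @ _eff_weight(state, pre + "wq")).reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        k = (h2 @ _eff_weight(state, pre + "wk")).reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        v = (h2 @ _eff_weight(state, pre + "wv")).reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(hd) + mask
        scores -= scores.max(-1, keepdims=True)
        e = np.exp(scores)
        att = e / e.sum(-1, keepdims=True)
        o = att @ v  # (B,nh,T,hd)
        om = o.transpose(0, 2, 1, 3).reshape(B * T, d)
        proj = (om @ _eff_weight(state, pre + "wo")).reshape(B, T, d)
        x1 = x + proj
        hm, ln2c = _layernorm(x1, p[pre + "ln2_g"], p[pre + "ln2_b"])
        z1 = hm.reshape(B * T, d) @ p[pre + "w1"] + p[pre + "b1"]
        a1 = _gelu(z1)
        m_out = (a1 @ p[pre + "w2"] + p[pre + "b2"]).reshape(B, T, d)
        x2 = x1 + m_out
        if want_cache:
            cache["layers"].append(
                dict(x=x, h=h, ln1c=ln1c, q=q, k=k, v=v, att=att, om=om,
                     x1=x1, hm=hm, ln2c=ln2c, z1=z1, a1=a1)
            )
        x = x2
    xf, lnfc = _layernorm(x, p["lnf_g"], p["lnf_b"])
    logits = xf.reshape(B * T, d) @ _eff_weight(state, "head")
    logits = logits.reshape(B, T, cfg.vocab_size)
    if want_cache:
        cache["x_final"] = x
        cache["xf"] = xf
        cache["lnfc"] = lnfc
    return logits, cache if want_cache else None


def _matmul_bwd(state, grads, agrads, name, x2d, dy2d, frozen):
    """Accumulate gradient for a (possibly adapted) weight; return dx."""
    dW = x2d.T @ dy2d
    if state.adapters and name in state.adapters:
        A, B = state.adapters[name]
        agrads[name] = (dW @ B.T, A.T @ dW)
    if not frozen:
        grads[name] = grads.get(name, 0) + dW
    return dy2d @ _eff_weight(state, name).T


def _backward(state: ModelState, cache: dict, dlogits: np.ndarray):
    """Gradients of a scalar loss given d(loss)/d(logits).

    Returns ``(param_grads, adapter_grads)``; ``param_grads`` is empty when
    the base is frozen.
    """
    cfg = state.config
    p = state.params
    ids = cache["ids"]
    B, T = ids.shape
    d, nh = cfg.embedding_dim, cfg.n_heads
    hd = d // nh
    frozen = state.frozen_base
    grads: dict[str, np.ndarray] = {}
    agrads: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    dl2 = dlogits.reshape(B * T, cfg.vocab_size).astype(_DTYPE)
    xf2 = cache["xf"].reshape(B * T, d)
    dxf2 = _matmul_bwd(state, grads, agrads, "head", xf2, dl2, frozen)
    dx, dg, db = _layernorm_bwd(dxf2.reshape(B, T, d), p["lnf_g"], cache["lnfc"])
    if not frozen:
        grads["lnf_g"], grads["lnf_b"] = dg, db

    for i in reversed(range(cfg.n_layers)):
        pre = f"l{i}."
        c = cache["layers"][i]
        # MLP
        dm = dx  # grad wrt m_out (and x1 via residual)
        da1 = dm.reshape(B * T, d) @ p[pre + "w2"].T
        if not frozen:
            grads[pre + "w2"] = c["a1"].T @ dm.reshape(B * T, d)
            grads[pre + "b2"] = dm.reshape(B * T, d).sum(0)
        dz1 = da1 * _gelu_grad(c["z1"])
        dhm2 = dz1 @ p[pre + "w1"].T
        if not frozen:
            grads[pre + "w1"] = c["hm"].reshape(B * T, d).T @ dz1
            grads[pre + "b1"] = dz1.sum(0)
        dx1_ln, dg2, db2 = _layernorm_bwd(dhm2.reshape(B, T, d), p[pre + "ln2_g"], c["ln2c"])
        if not frozen:
            grads[pre + "ln2_g"], grads[pre + "ln2_b"] = dg2, db2
        dx1 = dx + dx1_ln
        # attention out-projection
        dproj2 = dx1.reshape(B * T, d)
        dom2 = _matmul_bwd(state, grads, agrads, pre + "wo", c["om"], dproj2, frozen)
        do = dom2.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        datt = do @ c["v"].transpose(0, 1, 3, 2)
        dv = c["att"].transpose(0, 1, 3, 2) @ do
        a = c["att"]
        dscores = (datt - (datt * a).sum(-1, keepdims=True)) * a / math.sqrt(hd)
        dq = dscores @ c["k"]
        dk = dscores.transpose(0, 1, 3, 2) @ c["q"]
        h2 = c["h"].reshape(B * T, d)
        dq2 = dq.transpose(0, 2, 1, 3).reshape(B * T, d)
        dk2 = dk.transpose(0, 2, 1, 3).reshape(B * T, d)
        dv2 = dv.transpose(0, 2, 1, 3).reshape(B * T, d)
        dh2 = _matmul_bwd(state, grads, agrads, pre + "wq", h2, dq2, frozen)
        dh2 += _matmul_bwd(state, grads, agrads, pre + "wk", h2, dk2, frozen)
        dh2 += _matmul_bwd(state, grads, agrads, pre + "wv", h2, dv2, frozen)
        dx_ln, dg1, db1 = _layernorm_bwd(dh2.reshape(B, T, d), p[pre + "ln1_g"], c["ln1c"])
        if not frozen:
            grads[pre + "ln1_g"], grads[pre + "ln1_b"] = dg1, db1
        dx = dx1 + dx_ln

    if not frozen:
        grads["pos_emb"] = np.zeros_like(p["pos_emb"])
        grads["pos_emb"][:T] = dx.sum(0)
        grads["tok_emb"] = np.zeros_like(p["tok_emb"])
        np.add.at(grads["tok_emb"], ids, dx)
    return grads, agrads


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class AdamW:
    """Decoupled-weight-decay adaptive gradient optimizer over an array dict."""

    def __init__(self, shapes: dict[str, np.ndarray], weight_decay=0.01,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            upd = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if params[k].ndim >= 2:  # decay weight matrices only
                params[k] -= lr * self.wd * params[k]
            params[k] -= (lr * upd).astype(params[k].dtype)


def cosine_lr(step: int, total: int, initial: float, final: float) -> float:
    """Cosine annealing from ``initial`` to ``final`` over ``total`` steps."""
    if total <= 1:
        return final
    frac = min(step, total - 1) / (total - 1)
    return final + 0.5 * (initial - final) * (1 + math.cos(math.pi * frac))


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------


def _encode_corpus(corpus, tok: Tokenizer, context: int) -> list[list[int]]:
    strings = corpus.smiles() if hasattr(corpus, "smiles") else list(corpus)
    enc = []
    for s in strings:
        ids = tok.encode(s)
        if len(ids) > context:
            raise ValueError(
                f"encoded sequence of length {len(ids)} exceeds context {context} "
                f"for SMILES {s!r}"
            )
        enc.append(ids)
    return enc


def _pad_batch(seqs: list[list[int]], pad_id: int) -> np.ndarray:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def _ce_loss_and_dlogits(logits: np.ndarray, ids: np.ndarray, pad_id: int):
    """Mean next-token NLL (nats/token) over non-pad targets + d(loss)/d(logits)."""
    B, T, V = logits.shape
    targets = ids[:, 1:]
    lg = logits[:, :-1].astype(np.float64)
    lg -= lg.max(-1, keepdims=True)
    lse = np.log(np.exp(lg).sum(-1, keepdims=True))
    logp = lg - lse
    mask = targets != pad_id
    n = int(mask.sum())
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    loss = -(picked * mask).sum() / n
    dlogits = np.zeros((B, T, V), dtype=_DTYPE)
    soft = np.exp(logp)
    grad = soft
    np.put_along_axis(grad, targets[..., None],
                      np.take_along_axis(grad, targets[..., None], -1) - 1.0, -1)
    grad *= (mask[..., None] / n)
    dlogits[:, :-1] = grad
    return float(loss), dlogits


def train(m: ModelState, corpus, tok: Tokenizer, cfg: TrainConfig) -> ModelState:
    """Minimize mean next-token NLL; cosine-annealed AdamW.

    Returns a new state carrying the (step, loss, lr) trace.  Raises on a
    non-finite loss.
    """
    state = m.copy()
    state.tokenizer_fingerprint = tok.fingerprint()
    enc = _encode_corpus(corpus, tok, state.config.context_length)
    rng = np.random.default_rng(cfg.seed)
    n = len(enc)
    bs = min(cfg.batch_size, n)
    n_batches = math.ceil(n / bs)
    total = cfg.epochs * n_batches
    opt = AdamW(state.params, weight_decay=cfg.weight_decay)
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for b in range(n_batches):
            batch = [enc[i] for i in order[b * bs : (b + 1) * bs]]
            ids = _pad_batch(batch, tok.pad_id)
            logits, cache = _forward(state, ids, want_cache=True)
            loss, dlogits = _ce_loss_and_dlogits(logits, ids, tok.pad_id)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at step {step} (lr={cosine_lr(step, total, cfg.initial_lr, cfg.final_lr):g}); "
                    "lower the learning rate"
                )
            grads, _ = _backward(state, cache, dlogits)
            if cfg.grad_clip:
                gn = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if gn > cfg.grad_clip:
                    sc = cfg.grad_clip / gn
                    for g in grads.values():
                        g *= sc
            lr = cosine_lr(step, total, cfg.initial_lr, cfg.final_lr)
            opt.step(state.params, grads, lr)
            state.training_log.append((step, loss, lr))
            step += 1
    return state


def evaluate_nll(m: ModelState, corpus, tok: Tokenizer) -> float:
    """Mean per-token NLL (nats) of a corpus under the model."""
    enc = _encode_corpus(corpus, tok, m.config.context_length)
    total, count = 0.0, 0
    bs = 128
    for b in range(0, len(enc), bs):
        ids = _pad_batch(enc[b : b + bs], tok.pad_id)
        logits, _ = _forward(m, ids)
        loss, _ = _ce_loss_and_dlogits(logits, ids, tok.pad_id)
        nmask = int((ids[:, 1:] != tok.pad_id).sum())
        total += loss * nmask
        count += nmask
    return total / count


def sequence_logprob(m: ModelState, ids: list[int], bos_id: int = 1) -> float:
    """Sum over positions of log p(token | prefix), in nats (≤ 0)."""
    if ids[0] != bos_id:
        raise ValueError("sequence must begin with BOS")
    arr = np.asarray([ids], dtype=np.int64)
    if arr.shape[1] > m.config.context_length:
        raise ValueError("sequence exceeds context length")
    logits, _ = _forward(m, arr)
    lg = logits[0, :-1].astype(np.float64)
    lg -= lg.max(-1, keepdims=True)
    logp = lg - np.log(np.exp(lg).sum(-1, keepdims=True))
    picked = logp[np.arange(len(ids) - 1), ids[1:]]
    return float(picked.sum())


def next_token_logprobs(m: ModelState, prefix_ids: list[int]) -> np.ndarray:
    """Log distribution over the next token given a prefix."""
    logits, _ = _forward(m, np.asarray([prefix_ids], dtype=np.int64))
    lg = logits[0, -1].astype(np.float64)
    lg -= lg.max()
    return lg - np.log(np.exp(lg).sum())


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


@dataclass
class GenerationReport:
    n_raw: int
    n_parseable: int
    n_unique_canonical: int
    n_relaxed: int
    n_strict: int
    temperature: float
    seed: int

    @property
    def validity_rate(self) -> float:
        return self.n_parseable / self.n_raw if self.n_raw else 0.0

    @property
    def relaxed_rate(self) -> float:
        return self.n_relaxed / self.n_raw if self.n_raw else 0.0

    @property
    def strict_rate(self) -> float:
        return self.n_strict / self.n_raw if self.n_raw else 0.0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d.update(validity_rate=self.validity_rate, relaxed_rate=self.relaxed_rate,
                 strict_rate=self.strict_rate)
        return d


def _sample_ids(m: ModelState, n: int, temperature: float, seed: int,
                bos_id: int, eos_id: int, pad_id: int, max_len: int | None) -> np.ndarray:
    """Ancestral sampling with a per-layer KV cache; deterministic given seed."""
    cfg = m.config
    p = m.params
    d, nh = cfg.embedding_dim, cfg.n_heads
    hd = d // nh
    T = min(max_len or cfg.context_length, cfg.context_length)
    rng = np.random.default_rng(seed)
    ids = np.full((n, T), pad_id, dtype=np.int64)
    ids[:, 0] = bos_id
    alive = np.ones(n, dtype=bool)
    K = [np.zeros((n, nh, T, hd), dtype=_DTYPE) for _ in range(cfg.n_layers)]
    V = [np.zeros((n, nh, T, hd), dtype=_DTYPE) for _ in range(cfg.n_layers)]
    x_tok = ids[:, 0]
    for t in range(T - 1):
        x = p["tok_emb"][x_tok] + p["pos_emb"][t]  # (n,d)
        for i in range(cfg.n_layers):
            pre = f"l{i}."
            h, _ = _layernorm(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            q = (h @ _eff_weight(m, pre + "wq")).reshape(n, nh, hd)
            K[i][:, :, t] = (h @ _eff_weight(m, pre + "wk")).reshape(n, nh, hd)
            V[i][:, :, t] = (h @ _eff_weight(m, pre + "wv")).reshape(n, nh, hd)
            scores = np.einsum("bhd,bhtd->bht", q, K[i][:, :, : t + 1]) / math.sqrt(hd)
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            att = e / e.sum(-1, keepdims=True)
            o = np.einsum("bht,bhtd->bhd", att, V[i][:, :, : t + 1]).reshape(n, d)
            x = x + o @ _eff_weight(m, pre + "wo")
            hm, _ = _layernorm(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            x = x + _gelu(hm @ p[pre + "w1"] + p[pre + "b1"]) @ p[pre + "w2"] + p[pre + "b2"]
        xf, _ = _layernorm(x, p["lnf_g"], p["lnf_b"])
        logits = (xf @ _eff_weight(m, "head")).astype(np.float64)
        if temperature < 1e-8:
            nxt = logits.argmax(-1)
        else:
            lg = logits / temperature
            lg -= lg.max(-1, keepdims=True)
            prob = np.exp(lg)
            prob /= prob.sum(-1, keepdims=True)
            u = rng.random(n)
            nxt = (prob.cumsum(-1) < u[:, None]).sum(-1)
        nxt = np.where(alive, nxt, pad_id)
        ids[:, t + 1] = nxt
        alive &= nxt != eos_id
        x_tok = np.where(alive, nxt, pad_id)
        if not alive.any():
            break
    return ids


def sample(
    m: ModelState,
    tok: Tokenizer,
    n: int,
    temperature: float = 1.0,
    seed: int = 0,
    max_len: int | None = None,
) -> tuple[list[str], GenerationReport]:
    """Draw ``n`` SMILES by ancestral sampling and tally the generation report.

    Unparseable outputs are counted, never raised.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    ids = _sample_ids(m, n, temperature, seed, tok.bos_id, tok.eos_id, tok.pad_id, max_len)
    texts = [tok.decode(list(row)) for row in ids]
    uniq: set[str] = set()
    n_parse = n_relax = n_strict = 0
    for s in texts:
        try:
            mol = parse_smiles(s)
        except SmilesError:
            continue
        n_parse += 1
        uniq.add(mol.canonical_smiles)
        if has_bonded_nn(mol):
            n_relax += 1
            if has_bonded_nn(mol, strict=True):
                n_strict += 1
    report = GenerationReport(
        n_raw=n, n_parseable=n_parse, n_unique_canonical=len(uniq),
        n_relaxed=n_relax, n_strict=n_strict, temperature=temperature, seed=seed,
    )
    return texts, report
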