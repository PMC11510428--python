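"""Chemist-instruction training: preference pairs, DPO loss, LoRA.

The chemist criterion (an acyclic N–N bond, the photoswitch motif) is
turned into a training signal by pairing criterion-positive molecules
(*chosen*) with criterion-negative ones (*rejected*).  Direct preference
optimization treats the policy's log-probability ratio against a frozen
reference model as an implicit reward and minimizes

    loss = −log σ( β · [(log πθ(c) − log πref(c)) − (log πθ(r) − log πref(r))] )

over pairs (c, r).  Low-rank adapters (ΔW = A·B, B zero-initialized) are
attached to the attention projection matrices and are the only trainable
parameters; the base model stays frozen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from azogen.chem import has_bonded_nn, parse_smiles, SmilesError
from azogen.lm import (
    AdamW,
    ModelState,
    _backward,
    _ce_loss_and_dlogits,
    _forward,
    _pad_batch,
    cosine_lr,
    sequence_logprob,
)
from azogen.tokenizer import Tokenizer

__all__ = [
    "PreferencePair",
    "DPOConfig",
    "build_preference_pairs",
    "dpo_loss",
    "dpo_margin",
    "apply_lora",
    "train_dpo",
    "write_preference_jsonl",
    "read_preference_jsonl",
]

LORA_TARGET_SUFFIXES = ("wq", "wk", "wv", "wo")


@dataclass(frozen=True)
class PreferencePair:
    """prompt / chosen / rejected record encoding the chemist criterion."""

    prompt: str
    chosen: str
    rejected: str


@dataclass
class DPOConfig:
    beta: float = 0.1  # preference temperature β
    lora_rank: int = 8
    steps: int = 300
    batch_size: int = 16
    lr: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.beta <= 0 and self.beta != 0.0:
            raise ValueError("beta must be >= 0")
        if self.lora_rank < 1:
            raise ValueError("lora_rank must be >= 1")


def build_preference_pairs(
    samples: list[str], n_pairs: int, seed: int, prompt: str = ""
) -> list[PreferencePair]:
    """Pair criterion-positive molecules with randomly drawn negatives.

    Both sides must parse; positives satisfy the relaxed acyclic N–N
    criterion, negatives do not.  Sampling is with replacement, so
    ``n_pairs`` may exceed the number of positives.
    """
    positives: list[str] = []
    negatives: list[str] = []
    for s in samples:
        try:
            m = parse_smiles(s)
        except SmilesError:
            continue
        (positives if has_bonded_nn(m) else negatives).append(s)
    if not positives or not negatives:
        raise ValueError(
            "preference pairs need at least one criterion-positive and one "
            "criterion-negative valid molecule; raise motif_fraction in the "
            "corpus (or sample more molecules) to obtain positives"
        )
    rng = np.random.default_rng(seed)
    pairs = [
        PreferencePair(
            prompt=prompt,
            chosen=positives[int(rng.integers(len(positives)))],
            rejected=negatives[int(rng.integers(len(negatives)))],
        )
        for _ in range(n_pairs)
    ]
    return pairs


def write_preference_jsonl(pairs: list[PreferencePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(json.dumps({"prompt": p.prompt, "chosen": p.chosen,
                                 "rejected": p.rejected}) + "\n")


def read_preference_jsonl(path: str | Path) -> list[PreferencePair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            pairs.append(PreferencePair(prompt=d.get("prompt", ""),
                                        chosen=d["chosen"], rejected=d["rejected"]))
    return pairs


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def dpo_margin(policy: ModelState, reference: ModelState, pair: PreferencePair,
               tok: Tokenizer) -> float:
    """Implicit-reward margin: chosen log-ratio minus rejected log-ratio."""
    enc_c = tok.encode(pair.prompt + pair.chosen)
    enc_r = tok.encode(pair.prompt + pair.rejected)
    lp_c = sequence_logprob(policy, enc_c, tok.bos_id)
    lp_r = sequence_logprob(policy, enc_r, tok.bos_id)
    lref_c = sequence_logprob(reference, enc_c, tok.bos_id)
    lref_r = sequence_logprob(reference, enc_r, tok.bos_id)
    return (lp_c - lref_c) - (lp_r - lref_r)


def dpo_loss(policy: ModelState, reference: ModelState, pair: PreferencePair,
             tok: Tokenizer, beta: float) -> float:
    """−log σ(β · margin); ln 2 when policy ≡ reference or β = 0."""
    z = beta * dpo_margin(policy, reference, pair, tok)
    # -log sigmoid(z), computed stably
    return math.log1p(math.exp(-abs(z))) + max(-z, 0.0)


def apply_lora(m: ModelState, cfg: DPOConfig) -> ModelState:
    """Attach zero-initialized low-rank adapters to the attention projections.

    The returned state has ``frozen_base=True``; because B = 0 at init,
    its outputs equal the base model's exactly.
    """
    d = m.config.embedding_dim
    if cfg.lora_rank > d:
        raise ValueError(f"lora_rank {cfg.lora_rank} exceeds matrix dimension {d}")
    rng = np.random.default_rng(cfg.seed)
    state = m.copy()
    adapters: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(m.config.n_layers):
        for suf in LORA_TARGET_SUFFIXES:
            name = f"l{i}.{suf}"
            din, dout = m.params[name].shape
            A = (rng.standard_normal((din, cfg.lora_rank)) / math.sqrt(cfg.lora_rank)
                 ).astype(m.params[name].dtype)
            B = np.zeros((cfg.lora_rank, dout), dtype=m.params[name].dtype)
            adapters[name] = (A, B)
    state.adapters = adapters
    state.frozen_base = True
    return state


def _batched_logprobs_cached(state: ModelState, ids: np.ndarray, pad_id: int):
    """Per-sequence log-probabilities plus the forward cache and log-softmax."""
    logits, cache = _forward(state, ids, want_cache=True)
    lg = logits[:, :-1].astype(np.float64)
    lg -= lg.max(-1, keepdims=True)
    logp = lg - np.log(np.exp(lg).sum(-1, keepdims=True))
    targets = ids[:, 1:]
    mask = targets != pad_id
    picked = np.take_along_axis(logp, targets[..., None], -1)[..., 0]
    seq_lp = (picked * mask).sum(-1)
    return seq_lp, logp, mask, cache


def batch_logprobs(state: ModelState, seqs: list[list[int]], pad_id: int,
                   batch_size: int = 64) -> np.ndarray:
    """Length-unnormalized sequence log-probabilities, batched."""
    out = np.empty(len(seqs), dtype=np.float64)
    for b in range(0, len(seqs), batch_size):
        ids = _pad_batch(seqs[b : b + batch_size], pad_id)
        lp, _, _, _ = _batched_logprobs_cached(state, ids, pad_id)
        out[b : b + len(lp)] = lp
    return out


def train_dpo(policy: ModelState, pairs: list[PreferencePair], tok: Tokenizer,
              cfg: DPOConfig) -> ModelState:
    """Minimize mean DPO loss over preference pairs, updating adapters only.

    The reference model is a frozen copy of the policy at entry (its
    per-pair log-probabilities are precomputed once).  Returns the adapted
    policy; its ``training_log`` carries (step, mean loss, lr).
    """
    if policy.adapters is None:
        raise ValueError("policy has no adapters; call apply_lora first")
    state = policy.copy()
    ctx = state.config.context_length

    def enc(text: str) -> list[int]:
        ids = tok.encode(text)
        if len(ids) > ctx:
            raise ValueError(f"pair sequence exceeds context length {ctx}")
        return ids

    chosen = [enc(p.prompt + p.chosen) for p in pairs]
    rejected = [enc(p.prompt + p.rejected) for p in pairs]

    # frozen reference = policy at entry (adapters are zero-effect only at
    # B=0; evaluate through the current effective weights either way)
    reference = state.copy()
    ref_c = batch_logprobs(reference, chosen, tok.pad_id)
    ref_r = batch_logprobs(reference, rejected, tok.pad_id)

    flat_params = {}
    for name, (A, B) in state.adapters.items():
        flat_params[f"{name}:A"] = A
        flat_params[f"{name}:B"] = B
    opt = AdamW(flat_params, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = len(pairs)
    bs = min(cfg.batch_size, n)

    for step in range(cfg.steps):
        sel = rng.integers(0, n, size=bs)
        batch_c = [chosen[i] for i in sel]
        batch_r = [rejected[i] for i in sel]
        ids = _pad_batch(batch_c + batch_r, tok.pad_id)
        seq_lp, logp, mask, cache = _batched_logprobs_cached(state, ids, tok.pad_id)
        lp_c, lp_r = seq_lp[:bs], seq_lp[bs:]
        z = cfg.beta * ((lp_c - ref_c[sel]) - (lp_r - ref_r[sel]))
        loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(-z, 0.0)))
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite DPO loss at step {step}")
        # d loss / d lp_chosen = −β σ(−z) / bs ; rejected gets the opposite sign
        sig = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        coeff = np.concatenate([-cfg.beta * sig, cfg.beta * sig]) / bs
        targets = ids[:, 1:]
        soft = np.exp(logp)
        grad = soft.copy()
        np.put_along_axis(grad, targets[..., None],
                          np.take_along_axis(grad, targets[..., None], -1) - 1.0, -1)
        grad *= mask[..., None]
        # grad = (softmax − onehot) = −d(lp)/d(logits); so
        # d(loss)/d(logits) = coeff · d(lp)/d(logits) = −coeff · grad
        grad *= -coeff[:, None, None]
        dlogits = np.zeros(
            (ids.shape[0], ids.shape[1], state.config.vocab_size), dtype=np.float32
        )
        dlogits[:, :-1] = grad
        _, agrads = _backward(state, cache, dlogits)
        flat_grads = {}
        for name, (gA, gB) in agrads.items():
            flat_grads[f"{name}:A"] = gA
            flat_grads[f"{name}:B"] = gB
        lr = cosine_lr(step, cfg.steps, cfg.lr, cfg.lr * 1e-2)
        opt.step(flat_params, flat_grads, lr)
        state.training_log.append((step, loss, lr))

    return state
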