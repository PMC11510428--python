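"""Byte-pair-encoding tokenizer over SMILES strings.

Training iteratively merges the most frequent adjacent symbol pair; ties
are broken lexicographically on the concatenated pair string so training
is deterministic across platforms.  The default configuration is a
72-symbol base alphabet plus a budget of 1000 merges, giving a printed
tokenizer size of 72 + 1000 = 1072; the three special tokens (BOS, EOS,
PAD) are tracked separately and not counted in that size.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["SMILES_ALPHABET_72", "Tokenizer", "train_bpe", "load_tokenizer"]

# Versioned 72-symbol SMILES character alphabet: 26 uppercase + 26
# lowercase letters (atoms, including two-character element halves such
# as 'l' of Cl), 10 digits (ring closures), and 10 punctuation marks
# (branches, bonds, brackets, charges, cis/trans slashes).
SMILES_ALPHABET_72: tuple[str, ...] = tuple(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
    "0123456789"
    "()[]=#+-/\\"
)
assert len(SMILES_ALPHABET_72) == 72

BOS, EOS, PAD = "<bos>", "<eos>", "<pad>"
DEFAULT_N_MERGES = 1000


@dataclass
class Tokenizer:
    """Base alphabet + ordered merge rules + vocabulary.

    ``size`` is the conventional printed tokenizer size, |alphabet| +
    |merges|; ``n_symbols`` additionally counts the three specials and is
    the embedding-table size a sequence model needs.
    """

    base_alphabet: tuple[str, ...] = SMILES_ALPHABET_72
    merges: list[tuple[str, str]] = field(default_factory=list)
    vocab: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vocab:
            self.vocab = self._build_vocab()

    def _build_vocab(self) -> dict[str, int]:
        vocab = {PAD: 0, BOS: 1, EOS: 2}
        for sym in self.base_alphabet:
            vocab[sym] = len(vocab)
        for a, b in self.merges:
            vocab[a + b] = len(vocab)
        return vocab

    # --- sizes -----------------------------------------------------------
    @property
    def size(self) -> int:
        """Printed tokenizer size: base alphabet + learned merges."""
        return len(self.base_alphabet) + len(self.merges)

    @property
    def n_symbols(self) -> int:
        """Total id count including BOS/EOS/PAD (embedding-table size)."""
        return len(self.vocab)

    @property
    def pad_id(self) -> int:
        return self.vocab[PAD]

    @property
    def bos_id(self) -> int:
        return self.vocab[BOS]

    @property
    def eos_id(self) -> int:
        return self.vocab[EOS]

    # --- encode / decode -------------------------------------------------
    def _apply_merges(self, toks: list[str], s: str) -> list[str]:
        for a, b in self.merges:
            ab = a + b
            if ab not in s:  # cheap substring prune
                continue
            out: list[str] = []
            i = 0
            while i < len(toks):
                if i + 1 < len(toks) and toks[i] == a and toks[i + 1] == b:
                    out.append(ab)
                    i += 2
                else:
                    out.append(toks[i])
                    i += 1
            toks = out
        return toks

    def tokenize(self, s: str) -> list[str]:
        unknown = set(s) - set(self.base_alphabet)
        if unknown:
            raise KeyError(f"symbols outside base alphabet: {sorted(unknown)}")
        return self._apply_merges(list(s), s)

    def encode(self, s: str) -> list[int]:
        """Token ids for ``s``, wrapped with BOS/EOS."""
        return [self.bos_id] + [self.vocab[t] for t in self.tokenize(s)] + [self.eos_id]

    def decode(self, ids: list[int]) -> str:
        """Inverse of :meth:`encode`; specials are stripped."""
        inv = self.id_to_symbol
        out: list[str] = []
        for i in ids:
            if i not in inv:
                raise KeyError(f"unknown token id {i}")
            sym = inv[i]
            if sym in (BOS, EOS, PAD):
                continue
            out.append(sym)
        return "".join(out)

    @property
    def id_to_symbol(self) -> dict[int, str]:
        return {i: s for s, i in self.vocab.items()}

    # --- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "base_alphabet": list(self.base_alphabet),
            "merges": [list(m) for m in self.merges],
            "specials": {"bos": BOS, "eos": EOS, "pad": PAD},
            "size": self.size,
            "size_counts_specials": False,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update("|".join(self.base_alphabet).encode())
        for a, b in self.merges:
            h.update(f"{a}+{b}".encode())
        return h.hexdigest()[:16]


def load_tokenizer(path: str | Path) -> Tokenizer:
    payload = json.loads(Path(path).read_text())
    return Tokenizer(
        base_alphabet=tuple(payload["base_alphabet"]),
        merges=[tuple(m) for m in payload["merges"]],
    )


def train_bpe(
    corpus,
    base_alphabet: tuple[str, ...] = SMILES_ALPHABET_72,
    n_merges: int = DEFAULT_N_MERGES,
) -> Tokenizer:
    """Train BPE merges on a corpus of SMILES strings.

    ``corpus`` is a :class:`~azogen.corpus.SmilesCorpus` or an iterable of
    strings.  The most frequent adjacent pair is merged ``n_merges``
    times, stopping early once no pair occurs twice.  Ties are broken
    lexicographically by the concatenated pair, making training
    deterministic given the corpus.
    """
    strings = list(corpus.smiles()) if hasattr(corpus, "smiles") else list(corpus)
    if not strings:
        raise ValueError("empty corpus")
    alpha = set(base_alphabet)
    for s in strings:
        bad = set(s) - alpha
        if bad:
            raise ValueError(f"corpus character(s) outside base alphabet: {sorted(bad)}")

    seqs: list[list[str]] = [list(s) for s in strings]
    merges: list[tuple[str, str]] = []
    for _ in range(n_merges):
        counts: Counter[tuple[str, str]] = Counter()
        for toks in seqs:
            for i in range(len(toks) - 1):
                counts[(toks[i], toks[i + 1])] += 1
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break  # no recurring pair left
        best = min((p for p, c in counts.items() if c == best_count),
                   key=lambda p: p[0] + p[1])
        a, b = best
        merges.append(best)
        for k, toks in enumerate(seqs):
            if a not in toks:
                continue
            out: list[str] = []
            i = 0
            while i < len(toks):
                if i + 1 < len(toks) and toks[i] == a and toks[i + 1] == b:
                    out.append(a + b)
                    i += 2
                else:
                    out.append(toks[i])
                    i += 1
            seqs[k] = out
    return Tokenizer(base_alphabet=tuple(base_alphabet), merges=merges)
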