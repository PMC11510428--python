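"""Synthetic SMILES corpora and .smi/CSV file I/O.

The generator stands in for two training corpora: a broad
pretraining set of small valid organic molecules (PubChem-like) and a
fine-tuning subset restricted to at most 7 heavy atoms drawn from
{C, N, O, S, Cl} (QM7b-like constitution).  Molecules are assembled as
random spanning trees with an optional single ring closure and bond-order
upgrades under per-element valence caps, so every emitted string is valid
by construction — no rejection sampling against a parser.

A requested fraction of molecules carries the photoswitch motif: a
pendant N–N (mostly N=N) unit attached outside any ring, which makes the
acyclic N–N criterion true by construction; the remaining molecules are
built with no N–N adjacency at all, making it false by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from azogen.chem import SmilesError, parse_smiles

__all__ = [
    "SmilesCorpus",
    "generate_corpus",
    "qm7b_like_subset",
    "read_smiles",
    "write_smiles",
]

# conservative valence caps used during construction
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "Cl": 1, "F": 1, "Br": 1, "I": 1, "P": 3}

QM7B_ELEMENTS = frozenset({"C", "N", "O", "S", "Cl"})
QM7B_MAX_HEAVY_ATOMS = 7


@dataclass
class SmilesCorpus:
    """A list of (canonical SMILES, split tag) records plus provenance."""

    records: list[tuple[str, str]]
    seed: int | None = None
    config_echo: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    def smiles(self, split: str | None = None) -> list[str]:
        if split is None:
            return [s for s, _ in self.records]
        return [s for s, tag in self.records if tag == split]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _build_molecule(
    rng: np.random.Generator,
    n_heavy: int,
    elements: list[str],
    weights: np.ndarray,
    with_motif: bool,
    ring_prob: float,
    double_prob: float,
) -> str | None:
    """Assemble one random molecule; returns canonical SMILES or None."""
    mol = Chem.RWMol()
    free: list[int] = []  # remaining valence per atom

    n_base = max(1, n_heavy - 2) if with_motif else n_heavy

    def pick_element(first: bool) -> str:
        if first:
            # the seed atom must be able to grow a tree
            choices = [e for e in elements if _VALENCE[e] >= 2]
            if not choices:
                choices = ["C"]
            idx = rng.integers(len(choices))
            return choices[int(idx)]
        return str(rng.choice(elements, p=weights))

    sym = pick_element(first=True)
    mol.AddAtom(Chem.Atom(sym))
    free.append(_VALENCE[sym])

    for _ in range(n_base - 1):
        sym = pick_element(first=False)
        # candidate parents: free valence >= 1; forbid N–N adjacency for
        # non-motif molecules so the criterion is false by construction
        cands = [
            i
            for i in range(mol.GetNumAtoms())
            if free[i] >= 1
            and not (
                not with_motif and sym == "N" and mol.GetAtomWithIdx(i).GetSymbol() == "N"
            )
        ]
        if not cands:
            break
        parent = int(rng.choice(cands))
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        free.append(_VALENCE[sym] - 1)
        free[parent] -= 1

    n_base_actual = mol.GetNumAtoms()

    # single optional ring closure among base atoms (pendant motif bonds
    # added later can therefore never lie on a ring)
    if n_base_actual >= 4 and rng.random() < ring_prob:
        open_atoms = [i for i in range(n_base_actual) if free[i] >= 1]
        pairs = [
            (i, j)
            for k, i in enumerate(open_atoms)
            for j in open_atoms[k + 1 :]
            if mol.GetBondBetweenAtoms(i, j) is None
            and not (
                not with_motif
                and mol.GetAtomWithIdx(i).GetSymbol() == "N"
                and mol.GetAtomWithIdx(j).GetSymbol() == "N"
            )
        ]
        # require a ring of size >= 3: i and j must not be directly bonded
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            mol.AddBond(i, j, Chem.BondType.SINGLE)
            free[i] -= 1
            free[j] -= 1

    # bond-order upgrades under remaining valence
    for bond in list(mol.GetBonds()):
        if rng.random() >= double_prob:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if free[i] >= 1 and free[j] >= 1:
            bond.SetBondType(Chem.BondType.DOUBLE)
            free[i] -= 1
            free[j] -= 1

    if with_motif:
        anchors = [i for i in range(mol.GetNumAtoms()) if free[i] >= 1]
        if not anchors:
            return None
        anchor = int(rng.choice(anchors))
        n1 = mol.AddAtom(Chem.Atom("N"))
        mol.AddBond(anchor, n1, Chem.BondType.SINGLE)
        free[anchor] -= 1
        free.append(_VALENCE["N"] - 1)
        n2 = mol.AddAtom(Chem.Atom("N"))
        # pendant azo (N=N) most of the time, plain N–N otherwise
        if free[n1] >= 2 and rng.random() < 0.7:
            mol.AddBond(n1, n2, Chem.BondType.DOUBLE)
        else:
            mol.AddBond(n1, n2, Chem.BondType.SINGLE)

    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def generate_corpus(
    n: int,
    seed: int,
    motif_fraction: float = 0.05,
    max_heavy_atoms: int = 16,
    min_heavy_atoms: int = 4,
    element_set: tuple[str, ...] = ("C", "C", "C", "N", "O", "S", "Cl", "F"),
    ring_prob: float = 0.45,
    double_prob: float = 0.25,
    split: str = "pretrain",
) -> SmilesCorpus:
    """Generate ``n`` unique valid SMILES, a ``motif_fraction`` of which
    (binomially) carry an acyclic N–N bond.

    ``element_set`` may repeat symbols to weight them (the default is
    carbon-rich, as in small-organic corpora).  Deterministic given
    ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0.0 <= motif_fraction <= 1.0):
        raise ValueError("motif_fraction must be in [0, 1]")
    if max_heavy_atoms < 2:
        raise ValueError("max_heavy_atoms must be >= 2")
    elements = list(element_set)
    unknown = set(elements) - set(_VALENCE)
    if unknown:
        raise ValueError(f"unsupported elements: {sorted(unknown)}")
    if motif_fraction > 0 and "N" not in elements:
        raise ValueError(
            "motif_fraction > 0 requires nitrogen in element_set "
            "(the N–N motif cannot be built without N)"
        )

    rng = np.random.default_rng(seed)
    uniq, weights = np.unique(elements, return_counts=True)
    w = weights / weights.sum()
    elements_u = [str(e) for e in uniq]

    seen: set[str] = set()
    records: list[tuple[str, str]] = []
    attempts = 0
    max_attempts = 200 * n
    while len(records) < n and attempts < max_attempts:
        attempts += 1
        with_motif = bool(rng.random() < motif_fraction)
        lo = max(min_heavy_atoms, 4 if with_motif else min_heavy_atoms)
        n_heavy = int(rng.integers(lo, max_heavy_atoms + 1))
        smi = _build_molecule(rng, n_heavy, elements_u, w, with_motif, ring_prob, double_prob)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        records.append((smi, split))
    if len(records) < n:
        raise RuntimeError(
            f"could only generate {len(records)}/{n} unique molecules; "
            "loosen max_heavy_atoms or element_set"
        )
    cfg = dict(
        n=n,
        seed=seed,
        motif_fraction=motif_fraction,
        max_heavy_atoms=max_heavy_atoms,
        min_heavy_atoms=min_heavy_atoms,
        element_set=list(element_set),
        ring_prob=ring_prob,
        double_prob=double_prob,
        split=split,
    )
    return SmilesCorpus(records=records, seed=seed, config_echo=cfg)


def qm7b_like_subset(c: SmilesCorpus) -> SmilesCorpus:
    """Retain molecules with ≤7 heavy atoms over {C,N,O,S,Cl}; retag ``finetune``."""
    if len(c) == 0:
        raise ValueError("empty corpus")
    kept: list[tuple[str, str]] = []
    seen: set[str] = set()
    for smi, _ in c.records:
        m = parse_smiles(smi)
        if m.n_heavy_atoms > QM7B_MAX_HEAVY_ATOMS:
            continue
        if not m.element_set() <= QM7B_ELEMENTS:
            continue
        if m.canonical_smiles in seen:
            continue
        seen.add(m.canonical_smiles)
        kept.append((m.canonical_smiles, "finetune"))
    if not kept:
        warnings.warn("qm7b_like_subset produced an empty corpus", stacklevel=2)
    cfg = dict(c.config_echo)
    cfg.update(subset="qm7b_like", max_heavy_atoms=QM7B_MAX_HEAVY_ATOMS,
               element_set=sorted(QM7B_ELEMENTS))
    return SmilesCorpus(records=kept, seed=c.seed, config_echo=cfg)


def write_smiles(c: SmilesCorpus, path: str | Path, sidecar: bool = True) -> None:
    """Write a corpus as .smi (one ``SMILES<space>split`` per line) or CSV.

    A JSON sidecar with the generation parameters is written alongside
    .smi output for provenance (``<path>.json``).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(c.records, columns=["smiles", "split"]).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for smi, tag in c.records:
                fh.write(f"{smi} {tag}\n")
    if sidecar and c.config_echo:
        with open(str(path) + ".json", "w") as fh:
            json.dump({"seed": c.seed, "config": c.config_echo}, fh, indent=2)


def read_smiles(path: str | Path, split: str = "pretrain") -> SmilesCorpus:
    """Read .smi (``SMILES [name/tag]`` lines) or CSV with a ``smiles`` column.

    Unparseable entries are collected into ``corpus.errors`` (with their
    text), not raised.  SMILES are canonicalized on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str]] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path} has no 'smiles' column")
        tags = df["split"] if "split" in df.columns else [split] * len(df)
        rows = [(str(s), str(t)) for s, t in zip(df["smiles"], tags)]
    else:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                rows.append((parts[0], parts[1] if len(parts) > 1 else split))
    records: list[tuple[str, str]] = []
    errors: list[str] = []
    for smi, tag in rows:
        try:
            records.append((parse_smiles(smi).canonical_smiles, tag))
        except SmilesError:
            errors.append(smi)
    if not records:
        warnings.warn(f"no valid SMILES read from {path}", stacklevel=2)
    return SmilesCorpus(records=records, seed=None,
                        config_echo={"source": str(path)}, errors=errors)
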