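"""Molecular substrate: SMILES parsing, canonicalization, descriptors,
Morgan fingerprints, and the acyclic N–N structural criterion.

The criterion encodes the chemist's working definition of a candidate
photoswitch motif: two nitrogen atoms chemically bonded to each other,
with the N–N bond not lying on any ring.  The *strict* variant demands a
localized azo double bond (-N=N-), the structural basis of cis/trans
photoisomerization; the *relaxed* variant accepts any acyclic N–N bond.
"Acyclic" qualifies the bond, not the atoms: an exocyclic N–N bond whose
nitrogens sit on rings still counts.

Parsing, ring perception, canonical SMILES, the eight drug-likeness
input descriptors and circular fingerprints are delegated to RDKit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import QED as _rdkit_qed
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")  # parse errors are raised as exceptions, not logged

__all__ = [
    "Molecule",
    "PropertyVector",
    "Fingerprint",
    "SmilesError",
    "SmilesSyntaxError",
    "ValenceError",
    "parse_smiles",
    "canonicalize",
    "has_bonded_nn",
    "descriptors",
    "morgan_fingerprint",
    "tanimoto",
]


class SmilesError(ValueError):
    """Base class for SMILES rejection."""


class SmilesSyntaxError(SmilesError):
    """Malformed SMILES text (unclosed ring or branch, unknown symbol)."""


class ValenceError(SmilesError):
    """Syntactically valid SMILES describing a chemically invalid molecule."""


@dataclass(frozen=True)
class Molecule:
    """Parsed molecular graph.

    ``atoms`` holds ``(element symbol, formal charge, aromatic flag)``
    per heavy atom; ``bonds`` holds ``(i, j, order, in_ring)`` where
    ``order`` is 1, 2, 3 or the string ``"aromatic"`` and ``in_ring`` is
    true iff the bond lies on at least one cycle.
    """

    source_smiles: str
    canonical_smiles: str
    atoms: tuple[tuple[str, int, bool], ...]
    bonds: tuple[tuple[int, int, object, bool], ...]
    _rdmol: Chem.Mol = field(repr=False, compare=False, hash=False)

    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_rings(self) -> int:
        return self._rdmol.GetRingInfo().NumRings()

    def element_set(self) -> frozenset[str]:
        return frozenset(sym for sym, _, _ in self.atoms)


@dataclass(frozen=True)
class PropertyVector:
    """The eight QED input descriptors (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM, ALERTS)."""

    molecular_weight: float  # Da
    logp_estimate: float  # Crippen ALOGP, unitless
    hbond_donors: int
    hbond_acceptors: int
    tpsa: float  # Å²
    rotatable_bonds: int
    aromatic_rings: int
    structural_alerts: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.molecular_weight,
                self.logp_estimate,
                self.hbond_acceptors,
                self.hbond_donors,
                self.tpsa,
                self.rotatable_bonds,
                self.aromatic_rings,
                self.structural_alerts,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class Fingerprint:
    """Folded binary circular (Morgan) fingerprint."""

    bits: np.ndarray  # uint8 0/1 vector of length n_bits
    radius: int
    n_bits: int

    def popcount(self) -> int:
        return int(self.bits.sum())


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "aromatic",
}


def _from_rdmol(mol: Chem.Mol, source: str) -> Molecule:
    Chem.GetSSSR(mol)  # ensure ring info is perceived
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic()) for a in mol.GetAtoms()
    )
    bonds = tuple(
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _BOND_ORDER.get(b.GetBondType(), 1),
            b.IsInRing(),
        )
        for b in mol.GetBonds()
    )
    return Molecule(
        source_smiles=source,
        canonical_smiles=Chem.MolToSmiles(mol),
        atoms=atoms,
        bonds=bonds,
        _rdmol=mol,
    )


def parse_smiles(s: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` with ring perception done.

    Raises :class:`SmilesSyntaxError` for malformed text and
    :class:`ValenceError` for syntactically valid strings describing
    chemically impossible atoms (valence violations, bad aromaticity).
    """
    if not isinstance(s, str) or not s.strip():
        raise SmilesSyntaxError("empty SMILES")
    s = s.strip()
    raw = Chem.MolFromSmiles(s, sanitize=False)
    if raw is None:
        raise SmilesSyntaxError(f"unparseable SMILES: {s!r}")
    try:
        Chem.SanitizeMol(raw)
    except Exception as exc:  # rdkit raises several sanitization error types
        raise ValenceError(f"chemically invalid SMILES {s!r}: {exc}") from exc
    if raw.GetNumHeavyAtoms() == 0:
        raise SmilesSyntaxError(f"no heavy atoms in SMILES: {s!r}")
    return _from_rdmol(raw, s)


def is_valid_smiles(s: str) -> bool:
    try:
        parse_smiles(s)
        return True
    except SmilesError:
        return False


def canonicalize(m: Molecule | str) -> str:
    """Canonical SMILES; all spellings of one molecule map to one string."""
    if isinstance(m, str):
        m = parse_smiles(m)
    return m.canonical_smiles


def has_bonded_nn(m: Molecule, strict: bool = False) -> bool:
    """True iff the molecule carries an acyclic N–N bond.

    relaxed (``strict=False``): any bond between two nitrogens whose
    bond is not part of a ring, regardless of order.
    strict (``strict=True``): additionally the bond must be a localized
    (non-aromatic) double bond — the -N=N- azo photoswitch motif.
    """
    for i, j, order, in_ring in m.bonds:
        if in_ring:
            continue
        if m.atoms[i][0] != "N" or m.atoms[j][0] != "N":
            continue
        if not strict:
            return True
        if order == 2:
            return True
    return False


def descriptors(m: Molecule) -> PropertyVector:
    """Compute the eight QED input descriptors for a molecule."""
    p = _rdkit_qed.properties(m._rdmol)
    return PropertyVector(
        molecular_weight=float(p.MW),
        logp_estimate=float(p.ALOGP),
        hbond_donors=int(p.HBD),
        hbond_acceptors=int(p.HBA),
        tpsa=float(p.PSA),
        rotatable_bonds=int(p.ROTB),
        aromatic_rings=int(p.AROM),
        structural_alerts=int(p.ALERTS),
    )


def _element_invariants(mol: Chem.Mol) -> list[int]:
    # Element-level initial invariants: radius-0 environments distinguish
    # atoms only by (element, charge, aromaticity), not degree or H count.
    inv = []
    for a in mol.GetAtoms():
        key = f"{a.GetSymbol()}|{a.GetFormalCharge()}|{int(a.GetIsAromatic())}"
        h = int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "little")
        inv.append(h & 0x7FFFFFFF)
    return inv


def morgan_fingerprint(m: Molecule, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Circular-substructure fingerprint folded to ``n_bits`` bits.

    Initial atom invariants are element-level (element, charge,
    aromaticity), so the radius-0 environments of a molecule are exactly
    its distinct atom types.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 64 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError("n_bits must be a power of two >= 64")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = gen.GetFingerprintAsNumPy(
        m._rdmol, customAtomInvariants=_element_invariants(m._rdmol)
    )
    return Fingerprint(bits=np.asarray(arr, dtype=np.uint8), radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity between two equally sized fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    inter = int(np.sum((a.bits & b.bits) > 0))
    union = int(np.sum((a.bits | b.bits) > 0))
    return 1.0 if union == 0 else inter / union
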