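"""Drug-likeness (QED) and synthetic-accessibility (SA) scoring.

QED is the geometric mean of eight desirability-transformed
physicochemical descriptors (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM,
ALERTS).  Each desirability is an asymmetric double sigmoid (ADS) with
published parameters, normalized by its maximum; this implementation
uses unit weights (plain geometric mean).

The SA score combines corpus-derived circular-fragment frequency
contributions with a structural complexity penalty (molecule size,
spiro atoms, bridgeheads, macrocycles) and is rescaled to [1, 10] where
1 = easiest to synthesize (``sa_raw``).  Because the literature also
reports the opposite orientation (higher = easier), both are carried:
``sa_ease = 11 − sa_raw``.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

from azogen.chem import Molecule, PropertyVector, descriptors, parse_smiles

__all__ = [
    "ScoreCard",
    "FragmentTable",
    "ADS_PARAMS",
    "qed",
    "qed_from_desirabilities",
    "desirabilities",
    "build_fragment_table",
    "sa_score",
    "score_molecules",
    "shortlist",
    "scorecards_to_csv",
]

# Asymmetric-double-sigmoid desirability parameters of the published QED
# model, one row (a, b, c, d, e, f, dmax) per descriptor.
ADS_PARAMS: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "MW": (2.817065973, 392.5754953, 290.7489764, 2.419764353, 49.22325677,
           65.37051707, 104.9805561),
    "ALOGP": (3.172690585, 137.8624751, 2.534937431, 4.581497897, 0.822739154,
              0.576295591, 131.3186604),
    "HBA": (2.948620388, 160.4605972, 3.615294657, 4.435986202, 0.290141953,
            1.300669958, 148.7763046),
    "HBD": (1.618662227, 1010.051101, 0.985094388, 0.000000001, 0.713820843,
            0.920922555, 258.1632616),
    "PSA": (1.876861559, 125.2232657, 62.90773554, 87.83366614, 12.01999824,
            28.51324732, 104.5686167),
    "ROTB": (0.010000000, 272.4121427, 2.558379970, 1.565547684, 1.271567166,
             2.758063707, 105.4420403),
    "AROM": (3.217788970, 957.7374108, 2.274627939, 0.000000001, 1.317690384,
             0.375760881, 312.3372610),
    "ALERTS": (0.010000000, 1199.094025, -0.09002883, 0.000000001, 0.185904477,
               0.875193782, 417.7253140),
}

_DESC_ORDER = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")
_QED_EPS = 1e-6


def _ads(x: float, p: tuple[float, ...]) -> float:
    a, b, c, d, e, f, dmax = p
    s1 = 1.0 + math.exp(-(x - c + d / 2.0) / e)
    s2 = 1.0 + math.exp(-(x - c - d / 2.0) / f)
    return (a + b / s1 * (1.0 - 1.0 / s2)) / dmax


def desirabilities(p: PropertyVector) -> np.ndarray:
    """The eight ADS desirabilities d1..d8, each clipped into (0, 1]."""
    values = {
        "MW": p.molecular_weight,
        "ALOGP": p.logp_estimate,
        "HBA": p.hbond_acceptors,
        "HBD": p.hbond_donors,
        "PSA": p.tpsa,
        "ROTB": p.rotatable_bonds,
        "AROM": p.aromatic_rings,
        "ALERTS": p.structural_alerts,
    }
    d = np.array([_ads(values[k], ADS_PARAMS[k]) for k in _DESC_ORDER])
    return np.clip(d, _QED_EPS, 1.0)


def qed_from_desirabilities(d) -> float:
    """Geometric mean of desirability values (unit weights)."""
    d = np.clip(np.asarray(d, dtype=float), _QED_EPS, 1.0)
    return float(np.exp(np.mean(np.log(d))))


def qed(p: PropertyVector) -> float:
    """Quantitative estimate of drug-likeness in (0, 1]."""
    return qed_from_desirabilities(desirabilities(p))


# ---------------------------------------------------------------------------
# synthetic accessibility
# ---------------------------------------------------------------------------


@dataclass
class FragmentTable:
    """Log-frequency contributions of circular fragments (radius ≤ 2).

    ``contributions`` maps a Morgan environment hash to its centered log
    relative frequency in the reference corpus; fragments never seen get
    ``floor`` (one nat below the rarest observed fragment).
    """

    contributions: dict[int, float]
    floor: float
    provenance: str  # hash of the corpus the table was built from

    def __getitem__(self, frag_hash: int) -> float:
        return self.contributions.get(frag_hash, self.floor)


_SA_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2)


def _fragment_counts(m: Molecule) -> dict[int, int]:
    fp = _SA_FP_GEN.GetSparseCountFingerprint(m._rdmol)
    return dict(fp.GetNonzeroElements())


def build_fragment_table(corpus) -> FragmentTable:
    """Count radius-≤2 circular environments across a corpus.

    Contribution of a fragment = log(relative frequency), centered so the
    mean contribution is zero; common fragments score positive, rare ones
    negative.  Deterministic and reproducible bit-exactly from the same
    corpus.
    """
    smiles = corpus.smiles() if hasattr(corpus, "smiles") else list(corpus)
    if len(smiles) < 100:
        warnings.warn(
            f"fragment table built from only {len(smiles)} molecules; "
            "contributions will be noisy", stacklevel=2,
        )
    counts: dict[int, int] = {}
    for s in smiles:
        for h, c in _fragment_counts(parse_smiles(s)).items():
            counts[h] = counts.get(h, 0) + c
    if not counts:
        raise ValueError("empty corpus")
    total = sum(counts.values())
    logrel = {h: math.log(c / total) for h, c in counts.items()}
    center = float(np.mean(list(logrel.values())))
    contributions = {h: v - center for h, v in logrel.items()}
    floor = min(contributions.values()) - 1.0
    prov = hashlib.sha256("\n".join(sorted(smiles)).encode()).hexdigest()[:16]
    return FragmentTable(contributions=contributions, floor=floor, provenance=prov)


# Affine anchors mapping the combined (fragment − complexity) score onto
# the 1–10 scale; chosen so a typical corpus molecule lands mid-scale and
# clamped at the ends.
_SA_SCORE_MAX = 2.5   # very common fragments, no complexity → sa_raw 1
_SA_SCORE_MIN = -6.5  # rare fragments + heavy complexity → sa_raw 10


def sa_score(m: Molecule, table: FragmentTable) -> tuple[float, float]:
    """(sa_raw, sa_ease): synthetic-accessibility on [1, 10].

    ``sa_raw`` follows the fragment-based convention (1 = easiest);
    ``sa_ease = 11 − sa_raw`` reports the opposite orientation (higher =
    easier).  Deterministic and invariant to SMILES re-spelling.
    """
    frags = _fragment_counts(m)
    total = sum(frags.values())
    frag_score = sum(table[h] * c for h, c in frags.items()) / total

    mol = m._rdmol
    n_atoms = mol.GetNumAtoms()
    size_penalty = n_atoms**1.005 - n_atoms
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    ring_info = mol.GetRingInfo()
    macro = any(len(r) > 8 for r in ring_info.AtomRings())
    complexity = (
        size_penalty
        + 2.0 * math.log10(n_spiro + 1)
        + 2.0 * math.log10(n_bridge + 1)
        + (math.log10(2.0) if macro else 0.0)
    )
    score = frag_score - complexity
    # affine map: score >= MAX → 1 (easiest), score <= MIN → 10 (hardest)
    sa_raw = 1.0 + 9.0 * (_SA_SCORE_MAX - score) / (_SA_SCORE_MAX - _SA_SCORE_MIN)
    sa_raw = float(min(10.0, max(1.0, sa_raw)))
    return sa_raw, 11.0 - sa_raw


# ---------------------------------------------------------------------------
# score cards and shortlists
# ---------------------------------------------------------------------------


@dataclass
class ScoreCard:
    """Per-molecule screening record."""

    canonical_smiles: str
    desirabilities: tuple[float, ...]  # d1..d8
    qed: float
    sa_raw: float
    sa_ease: float
    source_model: str = ""
    pagerank: float | None = None

    def sort_key(self, key: str) -> float:
        if key == "qed":
            return self.qed
        if key == "sa_ease":
            return self.sa_ease
        if key == "pagerank":
            if self.pagerank is None:
                raise KeyError("pagerank not set on this ScoreCard")
            return self.pagerank
        raise KeyError(f"unknown ranking key {key!r} (use qed, sa_ease or pagerank)")


def score_molecules(
    smiles: list[str], table: FragmentTable, source_models: list[str] | None = None
) -> list[ScoreCard]:
    """Build a ScoreCard per molecule (QED + SA)."""
    if source_models is None:
        source_models = [""] * len(smiles)
    cards = []
    for s, tag in zip(smiles, source_models):
        m = parse_smiles(s)
        d = desirabilities(descriptors(m))
        raw, ease = sa_score(m, table)
        cards.append(
            ScoreCard(
                canonical_smiles=m.canonical_smiles,
                desirabilities=tuple(float(x) for x in d),
                qed=qed_from_desirabilities(d),
                sa_raw=raw,
                sa_ease=ease,
                source_model=tag,
            )
        )
    return cards


def shortlist(cards: list[ScoreCard], key: str, k: int) -> tuple[list[ScoreCard], dict[str, int]]:
    """Top-``k`` cards by ``key`` (descending; ties broken by canonical
    SMILES), plus a tally of ``source_model`` among the selected."""
    if not cards:
        raise ValueError("empty score list")
    ranked = sorted(cards, key=lambda c: (-c.sort_key(key), c.canonical_smiles))
    top = ranked[: min(k, len(ranked))]
    tallies: dict[str, int] = {}
    for c in top:
        tallies[c.source_model] = tallies.get(c.source_model, 0) + 1
    return top, tallies


def scorecards_to_csv(cards: list[ScoreCard], path: str | Path) -> None:
    rows = []
    for c in cards:
        row = {"smiles": c.canonical_smiles, "qed": c.qed, "sa_raw": c.sa_raw,
               "sa_ease": c.sa_ease, "source_model": c.source_model,
               "pagerank": c.pagerank}
        row.update({f"d{i+1}": v for i, v in enumerate(c.desirabilities)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
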