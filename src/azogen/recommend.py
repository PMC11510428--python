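"""Molecule recommendation over a similarity knowledge graph.

Each molecule becomes a feature vector (Morgan fingerprint bits plus
standardized physicochemical properties).  Pairwise similarity is the
cosine between mean-centered PCA projections, giving edge weights in
[−1, 1] with 1 on the diagonal.  Nodes are ranked by PageRank — the
stationary distribution of a damped random walk whose transition
probabilities are the non-negative part of the edge weights — and the
top-k most central molecules are recommended.  t-SNE is available for
visualization only; the adjacency itself is deterministic (PCA-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from azogen.chem import Molecule, descriptors, morgan_fingerprint, parse_smiles

__all__ = [
    "FeatureMatrix",
    "SimilarityGraph",
    "RankingResult",
    "feature_matrix",
    "reduce",
    "adjacency",
    "pagerank",
    "recommend_top_k",
]


@dataclass
class FeatureMatrix:
    """Fingerprint block (0/1) plus standardized property columns."""

    node_ids: list[str]  # canonical SMILES, unique
    X: np.ndarray  # (n, n_bits + n_props)
    n_fp_bits: int
    property_names: list[str]
    property_means: np.ndarray
    property_stds: np.ndarray


@dataclass
class SimilarityGraph:
    node_ids: list[str]
    W: np.ndarray  # dense symmetric, entries in [-1, 1], diagonal 1

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.W, index=self.node_ids, columns=self.node_ids).to_csv(path)

    def to_edge_list(self, path) -> None:
        n = self.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        pd.DataFrame(
            {"source": [self.node_ids[i] for i in iu],
             "target": [self.node_ids[j] for j in ju],
             "weight": self.W[iu, ju]}
        ).to_csv(path, index=False)


@dataclass
class RankingResult:
    node_ids: list[str]
    scores: np.ndarray  # probabilities, sum to 1
    damping: float
    iterations: int
    converged: bool

    def top_k(self, k: int) -> list[tuple[str, float]]:
        return recommend_top_k(self, k)


_PROPERTY_NAMES = ["mw", "alogp", "hba", "hbd", "tpsa", "rotb", "arom", "alerts"]


def feature_matrix(mols: list[Molecule | str], radius: int = 2, n_bits: int = 256) -> FeatureMatrix:
    """Fingerprint + standardized-property features, one row per unique molecule.

    Duplicate canonical SMILES are dropped with a warning.  Property
    columns are z-scored over the set; constant columns are dropped.
    """
    parsed = [parse_smiles(m) if isinstance(m, str) else m for m in mols]
    seen: dict[str, Molecule] = {}
    for m in parsed:
        if m.canonical_smiles in seen:
            continue
        seen[m.canonical_smiles] = m
    if len(seen) < len(parsed):
        warnings.warn(
            f"dropped {len(parsed) - len(seen)} duplicate canonical SMILES", stacklevel=2
        )
    if len(seen) < 2:
        raise ValueError("need at least 2 distinct molecules")
    ids = list(seen)
    fps = np.stack(
        [morgan_fingerprint(seen[s], radius=radius, n_bits=n_bits).bits for s in ids]
    ).astype(float)
    props = np.stack([descriptors(seen[s]).as_array() for s in ids])
    means = props.mean(0)
    stds = props.std(0)
    keep = stds > 1e-12
    z = (props[:, keep] - means[keep]) / stds[keep]
    names = [n for n, k in zip(_PROPERTY_NAMES, keep) if k]
    return FeatureMatrix(
        node_ids=ids,
        X=np.hstack([fps, z]),
        n_fp_bits=n_bits,
        property_names=names,
        property_means=means[keep],
        property_stds=stds[keep],
    )


def reduce(fm: FeatureMatrix, method: str = "pca", dims: int = 2, seed: int = 0) -> np.ndarray:
    """Dimensionality reduction: exact PCA projection or a seeded t-SNE map."""
    n, p = fm.X.shape
    if dims >= min(n, p) and method == "pca":
        raise ValueError(f"dims={dims} too large for {n}x{p} features")
    if method == "pca":
        return PCA(n_components=dims, svd_solver="full").fit_transform(fm.X)
    if method == "tsne":
        if dims not in (2, 3):
            raise ValueError("t-SNE supports 2 or 3 output dimensions")
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
        ts = TSNE(n_components=dims, random_state=seed, init="pca",
                  perplexity=perplexity)
        return ts.fit_transform(fm.X)
    raise ValueError(f"unknown method {method!r}")


def adjacency(fm: FeatureMatrix, pca_dims: int | None = None,
              variance_covered: float = 0.95) -> SimilarityGraph:
    """Dense similarity graph: cosine of mean-centered PCA-space rows.

    ``pca_dims`` defaults to the number of leading components covering
    ``variance_covered`` of the variance.  Entries lie in [−1, 1]; the
    diagonal is exactly 1; zero-norm rows get similarity 0 to all others.
    """
    n = fm.X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 molecules")
    if pca_dims is None:
        pca = PCA(n_components=min(n - 1, fm.X.shape[1]), svd_solver="full").fit(fm.X)
        frac = np.cumsum(pca.explained_variance_ratio_)
        pca_dims = int(np.searchsorted(frac, variance_covered) + 1)
    Y = PCA(n_components=pca_dims, svd_solver="full").fit_transform(fm.X)
    Y = Y - Y.mean(0)
    norms = np.linalg.norm(Y, axis=1)
    zero = norms < 1e-12
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm rows assigned 0 similarity", stacklevel=2)
    norms[zero] = 1.0
    U = Y / norms[:, None]
    W = np.clip(U @ U.T, -1.0, 1.0)
    W[zero, :] = 0.0
    W[:, zero] = 0.0
    np.fill_diagonal(W, 1.0)
    return SimilarityGraph(node_ids=list(fm.node_ids), W=W)


def pagerank(g: SimilarityGraph, damping: float = 0.85, tol: float = 1e-10,
             max_iter: int = 1000) -> RankingResult:
    """PageRank by power iteration on the clipped, row-normalized weights.

    Negative edge weights are clipped to 0 (dissimilarity carries no
    recommendation flow); rows that become all-zero (dangling) are
    replaced by the uniform distribution over the *other* nodes (a
    molecule never recommends itself); teleport mass is (1 − damping)/n.
    Returns scores summing to 1.
    """
    n = g.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return RankingResult(list(g.node_ids), np.array([1.0]), damping, 0, True)
    P = np.clip(g.W, 0.0, None).astype(float)
    rowsums = P.sum(1)
    dangling = rowsums <= 0
    rowsums[dangling] = 1.0
    P /= rowsums[:, None]
    for i in np.flatnonzero(dangling):
        P[i] = 1.0 / (n - 1)
        P[i, i] = 0.0
    x = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x_new = damping * (x @ P) + (1.0 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        warnings.warn(f"PageRank did not converge in {max_iter} iterations", stacklevel=2)
    x = x / x.sum()
    return RankingResult(list(g.node_ids), x, damping, it, converged)


def recommend_top_k(r: RankingResult, k: int) -> list[tuple[str, float]]:
    """Top-``k`` (molecule, score), descending; ties broken by SMILES."""
    order = sorted(range(len(r.node_ids)), key=lambda i: (-r.scores[i], r.node_ids[i]))
    return [(r.node_ids[i], float(r.scores[i])) for i in order[:k]]
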