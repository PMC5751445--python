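"""Per-layer drug/disease similarities and their fusion.

Three layers feed the comprehensive similarities:

* **base layer** — Tanimoto similarity over 2D fingerprint bit sets for
  drugs; a precomputed phenotype similarity matrix for diseases.
* **gene layer** — an exponential-decay (Perlman) kernel over shortest-path
  distances in the gene interaction network, lifted to drugs/diseases by a
  kernel-cosine over their binary gene profiles.
* **treatment layer** — the same Perlman kernel over shortest-path distances
  in the drug-disease bipartite graph of known indications, projected onto
  the entities without any known indication.

Each layer can be thresholded (small scores are treated as noise) and the
layers are fused by a convex combination whose weights are chosen so every
layer contributes equally on average (inverse-mean weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .network_data import (
    AssociationMatrix,
    EntityRegistry,
    FingerprintSet,
    SimilarityMatrix,
)

__all__ = [
    "KernelParams",
    "LayerWeights",
    "DistanceMatrix",
    "tanimoto_similarity",
    "shortest_path_distances",
    "perlman_kernel",
    "profile_kernel_similarity",
    "treatment_similarity",
    "project_to_full",
    "apply_threshold",
    "weights_from_means",
    "equal_contribution_weights",
    "fuse_layers",
]


@dataclass(frozen=True)
class KernelParams:
    """Amplitude ``a`` in (0, 1] and decay rate ``b`` > 0 of the
    exponential-decay distance kernel ``a * exp(-b * d)``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a <= 1.0):
            raise ValueError("kernel amplitude a must be in (0, 1]")
        if not self.b > 0.0:
            raise ValueError("kernel decay b must be > 0")


GENE_KERNEL = KernelParams(a=0.3, b=1.0)
TREATMENT_KERNEL = KernelParams(a=0.9, b=1.0)


@dataclass(frozen=True)
class LayerWeights:
    """Convex combination weights over (base, gene, treatment)."""

    base: float
    gene: float
    treatment: float

    def __post_init__(self) -> None:
        w = (self.base, self.gene, self.treatment)
        if any(x < 0 for x in w):
            raise ValueError("layer weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ValueError("layer weights must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.base, self.gene, self.treatment)


@dataclass
class DistanceMatrix:
    """Hop-count distances over one entity set; +inf marks unreachable."""

    registry: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.registry.size, self.registry.size):
            raise ValueError("distance matrix shape does not match registry")
        self.values = v


# ---------------------------------------------------------------------------
# Base layer
# ---------------------------------------------------------------------------

def tanimoto_similarity(fps: FingerprintSet) -> SimilarityMatrix:
    """Pairwise Tanimoto coefficient |A∩B| / |A∪B| over fingerprint bits.

    The diagonal is forced to 1 (covering drugs with empty fingerprints);
    two distinct drugs with empty fingerprints get similarity 0.
    """
    m = fps.registry.size
    if m == 0:
        raise ValueError("at least one drug required")
    all_bits = sorted(set().union(*fps.bits)) if any(fps.bits) else []
    bit_pos = {b: k for k, b in enumerate(all_bits)}
    X = np.zeros((m, max(1, len(all_bits))))
    for i, b in enumerate(fps.bits):
        for x in b:
            X[i, bit_pos[x]] = 1.0
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix.from_raw(fps.registry, S, layer_tag="base/tanimoto")


# ---------------------------------------------------------------------------
# Graph distances and the Perlman kernel
# ---------------------------------------------------------------------------

def shortest_path_distances(
    adj: AssociationMatrix, mode: str = "unipartite"
) -> DistanceMatrix:
    """All-pairs hop distances.

    ``unipartite`` treats ``adj`` (square, symmetric) as the graph itself.
    ``bipartite-rows`` / ``bipartite-cols`` build the bipartite graph from a
    rectangular association matrix and return distances between the row
    (resp. column) entities through it; such distances are always even.
    Unreachable pairs are +inf; an empty graph is all +inf off-diagonal.
    """
    B = adj.values
    if mode == "unipartite":
        if B.shape[0] != B.shape[1]:
            raise ValueError("unipartite mode requires a square matrix")
        graph = sp.csr_matrix(B)
        D = shortest_path(graph, method="D", directed=False, unweighted=True)
        return DistanceMatrix(adj.rows, D)
    if mode not in ("bipartite-rows", "bipartite-cols"):
        raise ValueError(f"unknown mode {mode!r}")
    m, n = B.shape
    big = sp.bmat(
        [[None, sp.csr_matrix(B)], [sp.csr_matrix(B.T), None]], format="csr"
    )
    D = shortest_path(big, method="D", directed=False, unweighted=True)
    if mode == "bipartite-rows":
        return DistanceMatrix(adj.rows, D[:m, :m])
    return DistanceMatrix(adj.cols, D[m:, m:])


def perlman_kernel(D: DistanceMatrix, k: KernelParams) -> SimilarityMatrix:
    """Similarity ``a * exp(-b * d)`` with ``exp(-inf) = 0``; diagonal 1.

    The diagonal is forced to 1 even though ``a * exp(0) = a < 1`` would
    hold literally: self-similarity is unit by definition.
    """
    with np.errstate(over="ignore"):
        S = k.a * np.exp(-k.b * D.values)
    S[~np.isfinite(D.values)] = 0.0
    return SimilarityMatrix.from_raw(D.registry, S, layer_tag="perlman")


# ---------------------------------------------------------------------------
# Gene layer
# ---------------------------------------------------------------------------

def _kernel_gram(X: np.ndarray, Sg: np.ndarray, Ymat: np.ndarray | None = None):
    """Cross Gram matrix X Sg Y^T with per-row kernel norms."""
    Y = X if Ymat is None else Ymat
    SgYt = Sg @ Y.T
    G = X @ SgYt
    nx = np.sqrt(np.maximum(np.einsum("ij,ji->i", X, Sg @ X.T), 0.0))
    ny = nx if Ymat is None else np.sqrt(
        np.maximum(np.einsum("ij,ji->i", Y, Sg @ Y.T), 0.0)
    )
    return G, nx, ny


def kernel_cosine(
    X: np.ndarray, Sg: np.ndarray, Ymat: np.ndarray | None = None
) -> np.ndarray:
    """Kernel-cosine x^T Sg y / (sqrt(x^T Sg x) sqrt(y^T Sg y)).

    Rows with an all-zero profile map to 0 against everything. Values are
    clipped to [0, 1]: the exponential-decay gene kernel is not guaranteed
    positive semidefinite, so the ratio can marginally exceed 1.
    """
    G, nx, ny = _kernel_gram(X, Sg, Ymat)
    denom = np.outer(nx, ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(C, 0.0, 1.0)


def profile_kernel_similarity(
    profiles: AssociationMatrix, Sg: SimilarityMatrix
) -> SimilarityMatrix:
    """Drug (or disease) similarity as kernel-cosine of gene profiles.

    ``profiles`` rows are the entities, columns the genes of ``Sg``. An
    entity with an empty profile is 0 to every other entity and 1 to itself.
    """
    if profiles.cols.ids != Sg.registry.ids:
        raise ValueError("profile columns do not match gene registry")
    C = kernel_cosine(profiles.values, Sg.values)
    return SimilarityMatrix.from_raw(profiles.rows, C, layer_tag="gene/profile")


# ---------------------------------------------------------------------------
# Treatment layer
# ---------------------------------------------------------------------------

def treatment_similarity(
    Y_train: AssociationMatrix, k: KernelParams = TREATMENT_KERNEL
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Drug-drug and disease-disease similarity from known indications.

    Restricted to drugs (diseases) with at least one known indication:
    shortest-path hop distances in the drug-disease bipartite graph, pushed
    through the exponential-decay kernel, self-similarity 1. Entities in
    different connected components get similarity 0.
    """
    row_mask = Y_train.values.sum(axis=1) > 0
    col_mask = Y_train.values.sum(axis=0) > 0
    if not row_mask.any():
        raise ValueError("treatment layer requires at least one positive")
    sub = AssociationMatrix(
        Y_train.rows.subset(np.nonzero(row_mask)[0]),
        Y_train.cols.subset(np.nonzero(col_mask)[0]),
        Y_train.values[np.ix_(row_mask, col_mask)],
    )
    Dc = shortest_path_distances(sub, mode="bipartite-rows")
    Dd = shortest_path_distances(sub, mode="bipartite-cols")
    Sc = perlman_kernel(Dc, k)
    Sd = perlman_kernel(Dd, k)
    Sc.layer_tag = "treatment/drug"
    Sd.layer_tag = "treatment/disease"
    return Sc, Sd


def project_to_full(
    S_partial: SimilarityMatrix,
    reference: SimilarityMatrix,
    k_neighbors: int = 5,
) -> SimilarityMatrix:
    """Extend a similarity defined on a subset to the full entity set.

    Entries between two covered entities are copied from ``S_partial``. An
    uncovered entity borrows the rows of its ``k_neighbors`` most similar
    covered entities in the ``reference`` matrix, averaged with the
    reference similarities as weights (renormalized); a pair of uncovered
    entities is the corresponding double-weighted average. An uncovered
    entity with zero reference similarity to every covered entity gets 0 to
    all others. Diagonal 1; result symmetrized by averaging.
    """
    full = reference.registry
    covered_idx = [full.index(i) for i in S_partial.registry.ids]
    if not covered_idx:
        raise ValueError("projection requires a non-empty covered set")
    covered_set = set(covered_idx)
    N, c = full.size, len(covered_idx)

    # Pi maps covered-space rows to full-space rows: one-hot for covered
    # entities, k-NN reference weights for uncovered ones.
    Pi = np.zeros((N, c))
    pos_of = {g: k for k, g in enumerate(covered_idx)}
    for x in range(N):
        if x in covered_set:
            Pi[x, pos_of[x]] = 1.0
            continue
        sims = reference.values[x, covered_idx].copy()
        k_eff = min(k_neighbors, c)
        nn = np.argsort(-sims, kind="stable")[:k_eff]
        w = sims[nn]
        tot = w.sum()
        if tot > 0:
            Pi[x, nn] = w / tot
    S_full = Pi @ S_partial.values @ Pi.T
    out = SimilarityMatrix.from_raw(full, S_full, layer_tag=S_partial.layer_tag)
    return out


# ---------------------------------------------------------------------------
# Thresholding and fusion
# ---------------------------------------------------------------------------

def apply_threshold(S: SimilarityMatrix, tau: float) -> SimilarityMatrix:
    """Zero out off-diagonal entries strictly below ``tau``.

    Entries equal to ``tau`` survive; the diagonal is never touched.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    v = S.values.copy()
    off = ~np.eye(v.shape[0], dtype=bool)
    v[off & (v < tau)] = 0.0
    return SimilarityMatrix(S.registry, v, S.layer_tag)


def off_diagonal_mean(S: SimilarityMatrix) -> float:
    """Mean of the off-diagonal entries (the diagonal is constant 1 and
    carries no layer information)."""
    n = S.values.shape[0]
    if n < 2:
        raise ValueError("off-diagonal mean undefined for size < 2")
    off = ~np.eye(n, dtype=bool)
    return float(S.values[off].mean())


def weights_from_means(means: tuple[float, float, float]) -> LayerWeights:
    """Inverse-mean weights: weight_k proportional to 1 / mean_k, so that
    weight_k * mean_k is constant — every layer contributes equally to the
    fused similarity on average."""
    if any(x <= 0 for x in means):
        raise ValueError("layer means must be positive for equal contribution")
    inv = np.array([1.0 / x for x in means])
    w = inv / inv.sum()
    return LayerWeights(*w)


def equal_contribution_weights(
    S_b: SimilarityMatrix, S_g: SimilarityMatrix, S_t: SimilarityMatrix
) -> LayerWeights:
    """Weights making each layer's average off-diagonal contribution equal."""
    for S in (S_g, S_t):
        if S.registry.ids != S_b.registry.ids:
            raise ValueError("layers must share a registry")
    means = tuple(off_diagonal_mean(S) for S in (S_b, S_g, S_t))
    if any(x == 0 for x in means):
        raise ValueError("a layer with all-zero off-diagonal has undefined weight")
    return weights_from_means(means)  # type: ignore[arg-type]


def fuse_layers(
    S_b: SimilarityMatrix,
    S_g: SimilarityMatrix,
    S_t: SimilarityMatrix,
    w: LayerWeights,
) -> SimilarityMatrix:
    """Entrywise convex combination of the three layer similarities."""
    for S in (S_g, S_t):
        if S.registry.ids != S_b.registry.ids:
            raise ValueError("layers must share a registry")
    v = w.base * S_b.values + w.gene * S_g.values + w.treatment * S_t.values
    return SimilarityMatrix.from_raw(S_b.registry, v, layer_tag="fused")
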