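"""Shared fixtures and independent dense oracles for the pair-graph tests.

The oracles here rebuild the q x q pair-graph objects entry by entry from
the definitions (pair weights are products of drug-drug and disease-disease
similarities; degrees are row sums), deliberately avoiding the package's
implicit-operator code paths so the two routes stay independent.
"""

from __future__ import annotations

import numpy as np
import pytest

from ssgc.network_data import EntityRegistry, PairField, SimilarityMatrix


def make_registry(kind: str, size: int, prefix: str | None = None) -> EntityRegistry:
    prefix = prefix or kind[:2].upper()
    return EntityRegistry.from_ids(kind, (f"{prefix}{k}" for k in range(size)))


def random_similarity(rng: np.random.Generator, registry: EntityRegistry) -> SimilarityMatrix:
    """Random valid similarity: symmetric, unit diagonal, entries in [0, 1]."""
    k = registry.size
    A = rng.random((k, k))
    S = 0.5 * (A + A.T)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(registry, S)


def random_instance(rng: np.random.Generator, m: int, n: int, pos_rate: float = 0.2):
    """Random (Sc, Sd, Y, P) problem instance with at least one positive."""
    drugs = make_registry("drug", m)
    diseases = make_registry("disease", n)
    Sc = random_similarity(rng, drugs)
    Sd = random_similarity(rng, diseases)
    Yv = (rng.random((m, n)) < pos_rate).astype(float)
    if Yv.sum() == 0:
        Yv[rng.integers(m), rng.integers(n)] = 1.0
    Pv = np.where(Yv > 0, 0.0, rng.random((m, n)))
    Y = PairField(drugs, diseases, Yv)
    P = PairField(drugs, diseases, Pv)
    return Sc, Sd, Y, P


def dense_pair_weights(Sc: np.ndarray, Sd: np.ndarray, self_loops: bool = False) -> np.ndarray:
    """Entry-by-entry q x q pair weight matrix W_st = Sc(i,i') Sd(j,j')
    (zero diagonal unless self_loops), under s = i * n + j."""
    m, n = Sc.shape[0], Sd.shape[0]
    q = m * n
    W = np.empty((q, q))
    for s in range(q):
        i, j = divmod(s, n)
        for t in range(q):
            ip, jp = divmod(t, n)
            W[s, t] = Sc[i, ip] * Sd[j, jp]
    if not self_loops:
        np.fill_diagonal(W, 0.0)
    return W


def dense_normalized_operator(
    Sc: np.ndarray,
    Sd: np.ndarray,
    degree_floor: float = 1e-12,
    self_loops: bool = False,
) -> np.ndarray:
    """S = A^{-1/2} W A^{-1/2} built from the explicit dense W."""
    W = dense_pair_weights(Sc, Sd, self_loops=self_loops)
    a = np.maximum(W.sum(axis=1), degree_floor)
    d = 1.0 / np.sqrt(a)
    return d[:, None] * W * d[None, :]


def dense_loss(
    f: np.ndarray,
    Sc: np.ndarray,
    Sd: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    mu: float,
    xi: float,
) -> float:
    """Loss evaluated with the explicit normalized Laplacian."""
    S = dense_normalized_operator(Sc, Sd)
    q = f.size
    Lbar = np.eye(q) - S
    lam_l = y > 0
    fit_l = np.where(lam_l, f, 0.0) - y
    fit_u = np.where(lam_l, 0.0, f) - p
    return float(
        0.5 * f @ Lbar @ f + 0.5 * mu * fit_l @ fit_l + 0.5 * xi * fit_u @ fit_u
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
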