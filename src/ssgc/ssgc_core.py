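"""Semi-supervised graph cut over the implicit drug-disease pair graph.

The pair graph has one node per drug-disease pair ``s = (i, j)`` and edge
weights ``W_st = Sc(i, i') * Sd(j, j')`` for ``s != t`` (no self-loops),
i.e. ``W = kron(Sc, Sd) - I_q`` under the row-major flattening
``s = i * n + j``. The method minimizes

    Loss(f) = 1/2 f^T Lbar f + mu/2 ||Lam_L f - y||^2 + xi/2 ||Lam_U f - p||^2

where ``Lbar = I_q - S`` is the normalized pair-graph Laplacian with
``S = A^{-1/2} W A^{-1/2}`` (``A`` the degree matrix), ``y`` the observed
treatment labels, ``p`` a gene-overlap prior on the unlabeled pairs, and
``mu > xi > 0`` weight fidelity to observations above fidelity to the prior.

The fixed-point iteration

    f^(k+1) = alpha * [(mu - xi) Lam_U + S] f^(k) + (1 - alpha) * yhat

with ``alpha = 1/(1 + mu)``, ``yhat = y + (xi/mu) p`` and ``f^(0) = yhat``
converges to the minimizer. The product ``S f`` is evaluated through the
m x n matrix identity

    (S f)_s = [Sc (F / Ahat) Sd / Ahat - F / Atilde]_{ij}

so the q x q pair matrices are never materialized; memory stays at
Theta(max(m^2, n^2)).

``closed_form_solve`` builds the dense q x q system and serves as the
independent oracle for small problems; ``hgbi_mode_solve`` runs the
reduction with self-loop weights, no prior, and ``mu = xi``, under which the
method coincides with HGBI-style network propagation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network_data import (
    AssociationMatrix,
    PairField,
    SimilarityMatrix,
)
from .layer_similarity import kernel_cosine

__all__ = [
    "SSGCParams",
    "PredictionResult",
    "compute_prior",
    "pair_degrees",
    "apply_S",
    "loss",
    "ssgc_solve",
    "closed_form_solve",
    "hgbi_mode_solve",
    "threshold_cut",
]

logger = logging.getLogger(__name__)

DENSE_CAP_DEFAULT = 2500


@dataclass(frozen=True)
class SSGCParams:
    """Scalars of the solver.

    mu weights fidelity to the observed labels, xi fidelity to the prior;
    the method assumes mu > xi > 0 (violating an observation costs more than
    contradicting the prior). ``allow_mu_eq_xi`` relaxes the strict
    inequality to a warning for the HGBI reduction where mu == xi.
    """

    mu: float = 4.0
    xi: float = 0.67
    tol: float = 1e-6
    max_iter: int = 1000
    degree_floor: float = 1e-12
    allow_mu_eq_xi: bool = False

    def __post_init__(self) -> None:
        if not (self.xi > 0 and self.mu > 0):
            raise ValueError("mu and xi must be positive")
        if self.mu < self.xi:
            raise ValueError("mu must be >= xi (observations outrank the prior)")
        if self.mu == self.xi and not self.allow_mu_eq_xi:
            warnings.warn(
                "mu == xi relaxes the observation-over-prior ordering; "
                "proceeding (HGBI reduction uses this setting)",
                stacklevel=2,
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if not (self.tol > 0 and self.degree_floor > 0):
            raise ValueError("tol and degree_floor must be positive")

    @property
    def alpha(self) -> float:
        return 1.0 / (1.0 + self.mu)


@dataclass
class PredictionResult:
    """Converged score field plus convergence diagnostics."""

    scores: PairField
    iterations: int
    converged: bool
    final_loss: float
    loss_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------

def compute_prior(
    C: AssociationMatrix,
    D: AssociationMatrix,
    Sg: SimilarityMatrix,
    Y: PairField,
) -> PairField:
    """Gene-overlap prior for unlabeled pairs.

    P_ij is the kernel-cosine between drug i's and disease j's gene profiles
    under the gene kernel Sg when Y_ij = 0, and 0 when Y_ij = 1 (known pairs
    need no prior). Empty profiles on either side give 0.
    """
    if C.cols.ids != Sg.registry.ids or D.cols.ids != Sg.registry.ids:
        raise ValueError("profile columns must match the gene registry")
    if Y.drugs.ids != C.rows.ids or Y.diseases.ids != D.rows.ids:
        raise ValueError("label field registries must match the profiles")
    P = kernel_cosine(C.values, Sg.values, D.values)
    P = np.where(Y.values > 0, 0.0, P)
    return PairField(Y.drugs, Y.diseases, P)


# ---------------------------------------------------------------------------
# Implicit pair-graph operator
# ---------------------------------------------------------------------------

def pair_degrees(
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    degree_floor: float = 1e-12,
    *,
    self_loops: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair-node degrees as m x n fields.

    The degree of pair s = (i, j) is
    ``a_s = sum_{i'} Sc(i, i') * sum_{j'} Sd(j, j') - 1`` (the -1 removes
    the self-loop; with ``self_loops=True``, HGBI mode, it is kept).
    Degrees below ``degree_floor`` — isolated pair nodes, possible after
    aggressive thresholding — are floored with a logged warning.

    Returns ``(A_hat, A_tilde)`` with ``A_hat = sqrt(a)`` and
    ``A_tilde = A_hat * A_hat = a`` elementwise.
    """
    rc = Sc.values.sum(axis=1)
    rd = Sd.values.sum(axis=1)
    a = np.outer(rc, rd)
    if not self_loops:
        a = a - 1.0
    n_floored = int((a < degree_floor).sum())
    if n_floored:
        logger.warning(
            "flooring %d isolated pair-node degrees at %g", n_floored, degree_floor
        )
        a = np.maximum(a, degree_floor)
    return np.sqrt(a), a


def apply_S(
    F: np.ndarray | PairField,
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    A_hat: np.ndarray,
    A_tilde: np.ndarray,
    *,
    self_loops: bool = False,
) -> np.ndarray:
    """Evaluate ``S f`` with ``S = A^{-1/2} W A^{-1/2}`` without forming the
    q x q matrices.

    ``(S f)_s = [Sc (F / A_hat) Sd / A_hat - F / A_tilde]_{ij}``; the
    subtracted term removes the self-loop contribution and is dropped in
    HGBI mode (``self_loops=True``).
    """
    if isinstance(F, PairField):
        F = F.values
    G = (Sc.values @ (F / A_hat) @ Sd.values) / A_hat
    if not self_loops:
        G = G - F / A_tilde
    return G


def loss(
    F: PairField,
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    Y: PairField,
    P: PairField,
    params: SSGCParams,
    *,
    degrees: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Normalized-Laplacian smoothness plus the two fidelity terms:
    ``1/2 f^T (I - S) f + mu/2 ||Lam_L f - y||^2 + xi/2 ||Lam_U f - p||^2``.
    """
    if degrees is None:
        degrees = pair_degrees(Sc, Sd, params.degree_floor)
    A_hat, A_tilde = degrees
    f = F.values
    Sf = apply_S(f, Sc, Sd, A_hat, A_tilde)
    smooth = 0.5 * (np.vdot(f, f) - np.vdot(f, Sf))
    labeled = Y.values > 0
    fit_l = np.where(labeled, f, 0.0) - Y.values
    fit_u = np.where(labeled, 0.0, f) - P.values
    return float(
        smooth
        + 0.5 * params.mu * np.vdot(fit_l, fit_l)
        + 0.5 * params.xi * np.vdot(fit_u, fit_u)
    )


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def _iterate(
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    Y: PairField,
    P: PairField,
    params: SSGCParams,
    *,
    self_loops: bool = False,
    track_loss: bool = True,
) -> PredictionResult:
    A_hat, A_tilde = pair_degrees(
        Sc, Sd, params.degree_floor, self_loops=self_loops
    )
    labeled = Y.values > 0
    yhat = Y.values + (params.xi / params.mu) * P.values
    alpha = params.alpha
    mu_minus_xi = params.mu - params.xi

    f = yhat.copy()
    trace: list[float] = []

    def _loss(fv: np.ndarray) -> float:
        Sf = apply_S(fv, Sc, Sd, A_hat, A_tilde, self_loops=self_loops)
        smooth = 0.5 * (np.vdot(fv, fv) - np.vdot(fv, Sf))
        fit_l = np.where(labeled, fv, 0.0) - Y.values
        fit_u = np.where(labeled, 0.0, fv) - P.values
        return float(
            smooth
            + 0.5 * params.mu * np.vdot(fit_l, fit_l)
            + 0.5 * params.xi * np.vdot(fit_u, fit_u)
        )

    if track_loss:
        trace.append(_loss(f))
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        Sf = apply_S(f, Sc, Sd, A_hat, A_tilde, self_loops=self_loops)
        f_next = alpha * (mu_minus_xi * np.where(labeled, 0.0, f) + Sf) + (
            1.0 - alpha
        ) * yhat
        if not np.isfinite(f_next).all():
            raise FloatingPointError(
                "non-finite values in the propagation iterate; check degrees "
                "and input similarities"
            )
        delta = np.abs(f_next - f).max(initial=0.0)
        f = f_next
        if track_loss:
            trace.append(_loss(f))
        if delta < params.tol:
            converged = True
            break
    scores = PairField(Y.drugs, Y.diseases, f)
    final_loss = trace[-1] if trace else _loss(f)
    return PredictionResult(scores, iterations, converged, final_loss, trace)


def ssgc_solve(
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    Y: PairField,
    P: PairField | None = None,
    params: SSGCParams | None = None,
    *,
    track_loss: bool = True,
) -> PredictionResult:
    """Run the propagation to its fixed point.

    Iterates ``f <- alpha[(mu - xi) Lam_U + S] f + (1 - alpha) yhat`` from
    ``f = yhat`` until the max-abs update falls below ``params.tol`` or
    ``params.max_iter`` is reached. All iterates are entrywise >= 0 (the
    iteration map and yhat are non-negative).
    """
    params = params or SSGCParams()
    if P is None:
        P = PairField.zeros(Y.drugs, Y.diseases)
    if not np.isin(Y.values, (0.0, 1.0)).all():
        raise ValueError("label field Y must be binary")
    return _iterate(Sc, Sd, Y, P, params, self_loops=False, track_loss=track_loss)


def closed_form_solve(
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    Y: PairField,
    P: PairField | None = None,
    params: SSGCParams | None = None,
    *,
    dense_cap: int = DENSE_CAP_DEFAULT,
    self_loops: bool = False,
) -> PairField:
    """Solve the stationarity system by dense linear algebra.

    The fixed point satisfies ``(I_q + mu Lam_L + xi Lam_U - S) f =
    mu y + xi p``. Builds the explicit q x q operator, so only usable for
    ``q = m * n <= dense_cap``; serves as the oracle for ``ssgc_solve``.
    """
    params = params or SSGCParams()
    if P is None:
        P = PairField.zeros(Y.drugs, Y.diseases)
    m, n = Y.shape
    q = m * n
    if q > dense_cap:
        raise ValueError(f"q = {q} exceeds the dense cap {dense_cap}")
    S = dense_pair_operator(
        Sc, Sd, params.degree_floor, self_loops=self_loops
    )
    y = Y.flat()
    p = P.flat()
    lam_l = y  # diagonal of Lam_L
    M = np.eye(q) + np.diag(params.mu * lam_l + params.xi * (1.0 - lam_l)) - S
    f = np.linalg.solve(M, params.mu * y + params.xi * p)
    return PairField.from_flat(Y.drugs, Y.diseases, f)


def hgbi_mode_solve(
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    Y: PairField,
    params: SSGCParams | None = None,
    *,
    track_loss: bool = True,
) -> PredictionResult:
    """Run the HGBI reduction: self-loop pair weights, no prior, mu = xi.

    With ``W_st = Sc(i,i') Sd(j,j')`` including s = t, ``p = 0`` and
    ``mu = xi``, the iteration collapses to
    ``f <- alpha S f + (1 - alpha) y`` — HGBI-style propagation on the
    normalized pair graph. Exposed as a named mode for ablation parity.
    """
    base = params or SSGCParams()
    hparams = SSGCParams(
        mu=base.mu,
        xi=base.mu,  # mu == xi by construction of the reduction
        tol=base.tol,
        max_iter=base.max_iter,
        degree_floor=base.degree_floor,
        allow_mu_eq_xi=True,
    )
    P = PairField.zeros(Y.drugs, Y.diseases)
    return _iterate(
        Sc, Sd, Y, P, hparams, self_loops=True, track_loss=track_loss
    )


# ---------------------------------------------------------------------------
# Dense oracle helpers (also used by the test suite)
# ---------------------------------------------------------------------------

def dense_pair_operator(
    Sc: SimilarityMatrix,
    Sd: SimilarityMatrix,
    degree_floor: float = 1e-12,
    *,
    self_loops: bool = False,
) -> np.ndarray:
    """Explicit q x q normalized pair-graph operator
    ``S = A^{-1/2} W A^{-1/2}`` with ``W = kron(Sc, Sd) - I`` (or with
    self-loops kept, ``W = kron(Sc, Sd)``). Small-problem oracle."""
    K = np.kron(Sc.values, Sd.values)
    W = K if self_loops else K - np.eye(K.shape[0])
    a = np.outer(Sc.values.sum(axis=1), Sd.values.sum(axis=1)).ravel()
    if not self_loops:
        a = a - 1.0
    a = np.maximum(a, degree_floor)
    d = 1.0 / np.sqrt(a)
    return d[:, None] * W * d[None, :]


def threshold_cut(scores: PairField, threshold: float) -> np.ndarray:
    """Binary treatment/non-treatment assignment at a score threshold.

    Rankings are the primary output of the method; this utility exposes the
    hard graph-cut reading (score >= threshold -> treatment group).
    """
    return (scores.values >= threshold).astype(int)
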