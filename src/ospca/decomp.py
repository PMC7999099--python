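"""The four decompositions: PCA, smoothed PCA, OS-PCA, repeated-measure OS-PCA.

Ordinary PCA maximizes the score variance ``var(t) = (1/n) w_x'X'X w_x``
under ``w_x'w_x = 1``.  Smoothed PCA keeps that objective but mixes a
roughness penalty into the constraint, ``(1-kappa) w_x'w_x +
kappa (Dt)'(Dt) = 1``, turning the problem into a generalized
eigenproblem ``(1/n) X'X w_x = lambda P w_x`` whose eigenvectors are
neither orthogonal nor statistically interpretable.

Orthogonal smoothed PCA (OS-PCA) restores both properties by introducing
an auxiliary score ``s = X w_y`` and maximizing the covariance
``cov(t, s) = (1/n) w_x'X'X w_y`` subject to ``w_x'w_x = 1`` and
``w_y'P w_y = 1``.  Eliminating ``w_y`` from the stationarity conditions

    (1/n) X'X w_y = 2 lambda_x w_x,    (1/n) X'X w_x = 2 lambda_y P w_y

gives the *ordinary* symmetric eigenproblem

    (1/n^2) X'X P^{-1} X'X w_x = lambda w_x,   lambda = 4 lambda_x lambda_y,

so the weight vectors w_x are orthonormal and the loadings are testable
correlations (see :mod:`ospca.inference`).  With repeated measurements
the same algebra runs on the averaged cross-product ``X'M'MX`` and the
averaged penalty ``Q``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .design import (
    AveragingOperator,
    DifferentialOperator,
    PenaltyMatrix,
    make_penalty_matrix,
)
from .preprocess import DataMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentModel",
    "fit_pca",
    "fit_smoothed_pca",
    "fit_ospca",
    "fit_ospca_repeated",
    "contribution_ratios",
]

_EIG_TOL = 1e-12


@dataclass(frozen=True)
class ComponentModel:
    """Fitted decomposition: weights, eigenvalues, scores, contributions.

    ``weights_y``, ``scores_s`` exist only for the covariance-maximizing
    methods (ospca, ospca_rep); ``scores_avg`` (one row per replicate
    set, ``M s``) only for ospca_rep.  ``lambda_x``/``lambda_y`` are the
    Lagrange multipliers of the covariance problem; per component
    ``eigenvalue = 4 lambda_x lambda_y`` and ``cov(t, s) = 2 lambda_x``.
    ``contribution_basis`` is "variance" (pca, spca) or "covariance"
    (ospca, ospca_rep) — ratios on different bases are not comparable.
    """

    method: str
    kappa: float | None
    weights_x: np.ndarray
    weights_y: np.ndarray | None
    eigenvalues: np.ndarray
    lambda_x: np.ndarray | None
    lambda_y: np.ndarray | None
    scores_t: np.ndarray
    scores_s: np.ndarray | None
    scores_avg: np.ndarray | None
    contribution: np.ndarray
    contribution_basis: str
    metabolite_names: tuple
    sample_ids: tuple
    replicate_set_ids: tuple | None
    n_samples: int
    averaged_data: np.ndarray | None = None
    penalty: PenaltyMatrix | None = None

    @property
    def k(self) -> int:
        return self.weights_x.shape[1]


def _default_k(n: int, p: int) -> int:
    return max(1, min(n - 1, p, 5))


def _fix_signs(W: np.ndarray, *companions: np.ndarray | None):
    """Flip each column so its largest-magnitude entry is positive.

    Companion arrays (paired weights, scores) are flipped jointly so
    sign-dependent relations such as cov(t, s) >= 0 survive the flip.
    """
    flips = np.ones(W.shape[1])
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            flips[j] = -1.0
    W = W * flips
    out = [W]
    for c in companions:
        out.append(None if c is None else c * flips)
    return out


def _truncate_k(k: int, eigvals_desc: np.ndarray, label: str) -> int:
    """Clip the requested component count to the numerical rank."""
    scale = max(eigvals_desc[0], 0.0) if eigvals_desc.size else 0.0
    rank = int(np.sum(eigvals_desc > _EIG_TOL * max(scale, 1.0)))
    if k > rank:
        logger.warning("%s: requested k=%d exceeds rank %d; truncating", label, k, rank)
        k = rank
    if k < 1:
        raise ValueError(f"{label}: data has no informative component")
    return k


def _check_scaled(X: DataMatrix, allowed: tuple, method: str):
    if X.scaling_state not in allowed:
        raise ValueError(
            f"{method} expects data in state {allowed}, got {X.scaling_state!r}; "
            "apply ospca.preprocess first"
        )


def fit_pca(X: DataMatrix, k: int | None = None) -> ComponentModel:
    """Ordinary PCA via the symmetric eigendecomposition of (1/n) X'X.

    Scores are ``t = X w_x``; the contribution ratio of component i is
    ``lambda_i / sum(lambda)`` over all nonnegative eigenvalues.
    """
    _check_scaled(X, ("autoscaled", "centered"), "fit_pca")
    n, p = X.values.shape
    k = _default_k(n, p) if k is None else int(k)
    C = (X.values.T @ X.values) / n
    evals, evecs = linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = _truncate_k(k, evals, "fit_pca")
    total = float(np.sum(evals[evals > _EIG_TOL]))
    W = evecs[:, :k]
    (W,) = _fix_signs(W)
    lam = evals[:k]
    return ComponentModel(
        method="pca",
        kappa=None,
        weights_x=W,
        weights_y=None,
        eigenvalues=lam,
        lambda_x=None,
        lambda_y=None,
        scores_t=X.values @ W,
        scores_s=None,
        scores_avg=None,
        contribution=lam / total,
        contribution_basis="variance",
        metabolite_names=X.metabolite_names,
        sample_ids=X.sample_ids,
        replicate_set_ids=None,
        n_samples=n,
    )


def fit_smoothed_pca(
    X: DataMatrix, D: DifferentialOperator, kappa: float, k: int | None = None
) -> ComponentModel:
    """Smoothed PCA: generalized eigenproblem (1/n) X'X w = lambda P w.

    Eigenvectors come back P-orthonormal (``w'Pw = 1``) but are not
    mutually orthogonal for kappa > 0, and carry no correlation
    interpretation: loading tests are deliberately unavailable for this
    model.  At kappa = 0 it coincides with ordinary PCA.
    """
    _check_scaled(X, ("autoscaled", "centered"), "fit_smoothed_pca")
    n, p = X.values.shape
    k = _default_k(n, p) if k is None else int(k)
    C = (X.values.T @ X.values) / n
    P = make_penalty_matrix(X.values, D, kappa)
    try:
        evals, evecs = linalg.eigh(C, P.matrix)
    except linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise ValueError(
            f"penalty matrix numerically singular at kappa={kappa}; use a smaller kappa"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = _truncate_k(k, evals, "fit_smoothed_pca")
    total = float(np.sum(evals[evals > _EIG_TOL]))
    W = evecs[:, :k]
    (W,) = _fix_signs(W)
    lam = evals[:k]
    return ComponentModel(
        method="spca",
        kappa=float(kappa),
        weights_x=W,
        weights_y=None,
        eigenvalues=lam,
        lambda_x=None,
        lambda_y=None,
        scores_t=X.values @ W,
        scores_s=None,
        scores_avg=None,
        contribution=lam / total,
        contribution_basis="variance",
        metabolite_names=X.metabolite_names,
        sample_ids=X.sample_ids,
        replicate_set_ids=None,
        n_samples=n,
        penalty=P,
    )


def _cov_eig_fit(G: np.ndarray, P: PenaltyMatrix, n: int, k: int, label: str):
    """Shared OS-PCA core: eigenproblem of K = (1/n^2) G P^{-1} G.

    Returns orthonormal W_x, P-normalized W_y with cov(t_i, s_i) >= 0,
    eigenvalues of K, the Lagrange multipliers, and covariance-based
    contribution fractions over all informative components.
    """
    cho = linalg.cho_factor(P.matrix)
    K = (G @ linalg.cho_solve(cho, G)) / (n * n)
    K = 0.5 * (K + K.T)
    evals, evecs = linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = _truncate_k(k, evals, label)
    # covariance cov(t_i, s_i) = sqrt(lambda_i); total over informative spectrum
    pos = evals[evals > _EIG_TOL * max(evals[0], 1.0)]
    total_cov = float(np.sum(np.sqrt(pos)))
    W_x = evecs[:, :k]
    W_y = np.empty_like(W_x)
    covs = np.empty(k)
    for j in range(k):
        v = linalg.cho_solve(cho, G @ W_x[:, j])
        norm = float(np.sqrt(v @ (P.matrix @ v)))
        w_y = v / norm
        cov = float(W_x[:, j] @ (G @ w_y)) / n
        if cov < 0:  # pair signs so the two scores covary positively
            w_y, cov = -w_y, -cov
        W_y[:, j] = w_y
        covs[j] = cov
    W_x, W_y = _fix_signs(W_x, W_y)
    lam_x = lam_y = covs / 2.0
    return W_x, W_y, evals[:k], lam_x, lam_y, covs / total_cov


def fit_ospca(
    X: DataMatrix, D: DifferentialOperator, kappa: float, k: int | None = None
) -> ComponentModel:
    """Orthogonal smoothed PCA on autoscaled data.

    Solves the symmetric eigenproblem ``(1/n^2) X'X P^{-1} X'X w_x =
    lambda w_x``; recovers each ``w_y`` proportional to ``P^{-1} X'X w_x``
    normalized to ``w_y'P w_y = 1`` with the sign making cov(t, s)
    nonnegative.  Contribution ratios are covariance-based:
    ``cov(t_i, s_i) / sum_j cov(t_j, s_j)``.
    """
    _check_scaled(X, ("autoscaled", "centered"), "fit_ospca")
    n, p = X.values.shape
    k = _default_k(n, p) if k is None else int(k)
    G = X.values.T @ X.values
    P = make_penalty_matrix(X.values, D, kappa)
    W_x, W_y, lam, lam_x, lam_y, contrib = _cov_eig_fit(G, P, n, k, "fit_ospca")
    return ComponentModel(
        method="ospca",
        kappa=float(kappa),
        weights_x=W_x,
        weights_y=W_y,
        eigenvalues=lam,
        lambda_x=lam_x,
        lambda_y=lam_y,
        scores_t=X.values @ W_x,
        scores_s=X.values @ W_y,
        scores_avg=None,
        contribution=contrib,
        contribution_basis="covariance",
        metabolite_names=X.metabolite_names,
        sample_ids=X.sample_ids,
        replicate_set_ids=None,
        n_samples=n,
        penalty=P,
    )


def fit_ospca_repeated(
    X: DataMatrix,
    M: AveragingOperator,
    D: DifferentialOperator,
    kappa: float,
    k: int | None = None,
) -> ComponentModel:
    """OS-PCA for repeated-measurement data.

    ``X`` must be scaled by :func:`ospca.preprocess.autoscale_by_average`
    and ``D`` built on the replicate-set-level (collapsed) design, so the
    smoothness penalty acts on the averaged score sequence ``M s``.  The
    algebra is that of :func:`fit_ospca` with the cross-product
    ``X'M'MX`` and penalty ``Q``.  Per-measurement scores ``t = X w_x``
    are kept alongside the per-set auxiliary scores ``M s = M X w_y`` —
    the latter is the score all repeats of a sample share.
    """
    _check_scaled(X, ("autoscaled_by_average", "autoscaled", "centered"), "fit_ospca_repeated")
    n, p = X.values.shape
    k = _default_k(n, p) if k is None else int(k)
    if M.matrix.shape[1] != n:
        raise ValueError(f"averaging operator expects {M.matrix.shape[1]} rows, data has {n}")
    avg = M.matrix @ X.values  # u x p
    if D.matrix.shape[1] != avg.shape[0]:
        raise ValueError(
            "difference matrix must be built on the collapsed (replicate-set) design: "
            f"D has {D.matrix.shape[1]} columns, averaged data has {avg.shape[0]} rows"
        )
    G = avg.T @ avg  # X'M'MX
    Q = make_penalty_matrix(X.values, D, kappa, M=M)
    W_x, W_y, lam, lam_x, lam_y, contrib = _cov_eig_fit(G, Q, n, k, "fit_ospca_repeated")
    return ComponentModel(
        method="ospca_rep",
        kappa=float(kappa),
        weights_x=W_x,
        weights_y=W_y,
        eigenvalues=lam,
        lambda_x=lam_x,
        lambda_y=lam_y,
        scores_t=X.values @ W_x,
        scores_s=X.values @ W_y,
        scores_avg=avg @ W_y,
        contribution=contrib,
        contribution_basis="covariance",
        metabolite_names=X.metabolite_names,
        sample_ids=X.sample_ids,
        replicate_set_ids=tuple(range(M.n_sets)),
        n_samples=n,
        averaged_data=avg,
        penalty=Q,
    )


def contribution_ratios(model: ComponentModel) -> tuple[np.ndarray, str]:
    """Per-component contribution fractions and the basis they are on.

    Variance-based for pca/spca, covariance-based for ospca/ospca_rep;
    fractions are over the full informative spectrum, so the retained-k
    fractions sum to at most 1.  The basis label travels with the numbers
    because ratios on different bases cannot be compared.
    """
    return model.contribution.copy(), model.contribution_basis
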