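"""Functional principal component analysis of smoothed trait curves.

Curves live in a B-spline basis, so all inner products reduce to the basis
Gram matrix W (W_jk = integral of phi_j phi_k over the domain), computed
exactly by piecewise Gauss-Legendre quadrature.  The leading eigenfunction
psi_1 maximizes sum_i <yhat_i, psi>^2 subject to ||psi|| = 1, and later
components continue the maximization under orthonormality.  Writing psi in
basis coordinates b and substituting u = L'b (L the Cholesky factor of W)
turns this into the symmetric eigenproblem of (1/n) L'C'CL, where C is the
n x K coefficient matrix; eigenfunctions are then exactly W-orthonormal.

By default the mean curve is subtracted first (the textbook functional-PCA
convention, and the one under which a 99% variance rule retains several
informative components on growth-curve data); ``center=False`` applies the
maximization criterion literally to the uncentered curves, in which case
the leading component is essentially the mean direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, eigh, solve_triangular


@dataclass(frozen=True)
class GramMatrix:
    """Exact inner products W_jk = <phi_j, phi_k> of the basis functions."""

    W: np.ndarray
    domain: tuple


def gram_matrix(basis):
    """Exact Gram matrix of a B-spline basis.

    Products of two order-``m`` splines are polynomials of degree 2(m-1) on
    each knot interval, so a fixed-order Gauss-Legendre rule per interval is
    exact (we use m nodes, enough for degree 2m-1 >= 2m-2).
    """
    lo, hi = basis.domain
    breaks = np.unique(basis.knots)
    nodes, weights = np.polynomial.legendre.leggauss(basis.order)
    W = np.zeros((basis.K, basis.K))
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        x = mid + half * nodes
        Phi = basis.design(x)  # (m, K)
        W += half * (Phi.T * weights) @ Phi
    return GramMatrix(W=0.5 * (W + W.T), domain=(lo, hi))


@dataclass
class FPCAResult:
    """Orthonormal eigenfunctions, eigenvalues, and the n x p score matrix.

    eigenfunctions : (p, K) basis coordinates of psi_1..psi_p.
    scores : (n, p) derived traits Z_ij = <yhat_i, psi_j>.
    psi_matrix : (p, T) eigenfunctions evaluated at the data time points.
    """

    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    varprop: np.ndarray
    psi_matrix: np.ndarray
    mean_coef: np.ndarray  # basis coordinates of the subtracted mean (zeros if uncentered)
    mean_curve: np.ndarray  # subtracted mean at the data time points (zeros if uncentered)
    centered: bool

    @property
    def p(self):
        return self.eigenvalues.size


def functional_pca(fit, gram, var_threshold=0.99, center=True, max_pc=None):
    """Functional PCA of a :class:`~curveqtl.smooth.SmoothFit`.

    The number of retained components p is the smallest count whose
    cumulative eigenvalue fraction reaches ``var_threshold`` (optionally
    capped by ``max_pc``, and by n-1 when centering).
    """
    if not (0 < var_threshold <= 1):
        raise ValueError("var_threshold must lie in (0, 1]")
    C = np.asarray(fit.coefficients, dtype=float)
    n, K = C.shape
    if n < 2:
        raise ValueError("functional PCA needs at least 2 lines")
    W = gram.W
    if np.min(np.linalg.eigvalsh(W)) < -1e-10:
        raise ValueError("Gram matrix is not positive semi-definite")
    mean_coef = np.zeros(K)
    if center:
        mean_coef = C.mean(axis=0)
        C = C - mean_coef

    L = cholesky(W, lower=True)
    A = (L.T @ C.T @ C @ L) / n
    vals, vecs = eigh(A)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]

    total = vals.sum()
    varprop_all = vals / total if total > 0 else np.zeros_like(vals)
    cum = np.cumsum(varprop_all)
    p = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    p = min(p, K)
    if max_pc is not None:
        p = min(p, int(max_pc))
    if center:
        p = min(p, n - 1)

    # basis coordinates: b = L^{-T} u, giving b' W b = u'u = I
    B = solve_triangular(L.T, vecs[:, :p]).T  # (p, K)
    # deterministic sign: largest-magnitude coordinate positive
    for j in range(p):
        k = np.argmax(np.abs(B[j]))
        if B[j, k] < 0:
            B[j] = -B[j]
    Z = C @ W @ B.T
    Phi_t = fit.basis.design(fit.times)
    Psi = B @ Phi_t.T
    return FPCAResult(
        eigenfunctions=B,
        eigenvalues=vals[:p],
        scores=Z,
        varprop=varprop_all[:p],
        psi_matrix=Psi,
        mean_coef=mean_coef,
        mean_curve=mean_coef @ Phi_t.T,
        centered=center,
    )


def reconstruct_curves(res):
    """Rank-p reconstruction sum_j Z_ij psi_j(t) of the smoothed curves.

    With p equal to the basis size this reproduces the smoothed curves
    exactly; the subtracted mean (if any) is added back.
    """
    return res.scores @ res.psi_matrix + res.mean_curve
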