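"""B-spline smoothing of function-valued phenotypes.

Each observed trait curve y_i(t_j) is replaced by a smooth approximation
x_i(t) = sum_k c_ik phi_k(t) in a shared cubic B-spline basis of K
functions.  Coefficients minimize the summed squared error over time
points (solved once per dataset through a shared QR factorization of the
T x K design matrix with entries phi_k(t_j)).  The basis size K is chosen
by ten-fold cross-validation over time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import lstsq


@dataclass(frozen=True)
class BSplineBasis:
    """A B-spline basis of K functions on [t1, tT].

    order : spline order (4 = cubic).  K = order + number of interior knots.
    Interior knots are equally spaced inside the domain; boundary knots are
    repeated ``order`` times so the basis is a partition of unity.
    """

    order: int
    knots: np.ndarray  # full knot vector, boundary knots repeated
    domain: tuple

    @property
    def K(self):
        return self.knots.size - self.order

    @property
    def degree(self):
        return self.order - 1

    def design(self, times):
        """Design matrix Phi with Phi[j, k] = phi_k(t_j); shape (len(times), K)."""
        t = np.asarray(times, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(f"evaluation outside the basis domain [{lo}, {hi}]")
        t = np.clip(t, lo, hi)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()


def build_basis(times, K, order=4):
    """Build a K-function spline basis on the span of ``times``.

    Interior knots (K - order of them) are equally spaced strictly inside
    (t1, tT); boundary knots are repeated to the order.
    """
    times = np.asarray(times, dtype=float)
    if K < order:
        raise ValueError(f"K={K} must be >= order={order}")
    if np.unique(times).size < K:
        raise ValueError(f"need at least K={K} distinct time points, got {np.unique(times).size}")
    lo, hi = float(times[0]), float(times[-1])
    n_interior = K - order
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([np.full(order, lo), interior, np.full(order, hi)])
    return BSplineBasis(order=order, knots=knots, domain=(lo, hi))


@dataclass
class SmoothFit:
    """Result of smoothing an n x T phenotype matrix in a shared basis."""

    basis: BSplineBasis
    times: np.ndarray
    coefficients: np.ndarray  # (n, K)
    fitted: np.ndarray  # (n, T)
    residuals: np.ndarray  # (n, T)

    @property
    def sse(self):
        """Total summed squared error over lines and time points."""
        return float(np.sum(self.residuals**2))


def impute_missing(phenotypes, times):
    """Per-line linear interpolation in time of missing phenotype cells.

    Boundary gaps are carried from the nearest observation.  Returns a copy;
    warns when any cell is imputed.
    """
    Y = np.asarray(phenotypes, dtype=float).copy()
    t = np.asarray(times, dtype=float)
    bad = ~np.isfinite(Y)
    if not bad.any():
        return Y
    warnings.warn(f"imputing {int(bad.sum())} missing phenotype cells by linear interpolation in time")
    for i in np.nonzero(bad.any(axis=1))[0]:
        ok = np.isfinite(Y[i])
        if not ok.any():
            raise ValueError(f"line {i} has no observed phenotype values")
        Y[i, ~ok] = np.interp(t[~ok], t[ok], Y[i, ok])
    return Y


def fit_smooth(phenotypes, times, basis):
    """Least-squares fit of every line's curve in a shared basis.

    Coefficient row i minimizes sum_j [y_i(t_j) - sum_k c_ik phi_k(t_j)]^2.
    The design matrix is common to all lines, so one factorization serves
    every line.
    """
    Y = np.asarray(phenotypes, dtype=float)
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("phenotypes contain missing values; impute first (impute_missing)")
    Phi = basis.design(times)
    if np.linalg.matrix_rank(Phi) < basis.K:
        raise ValueError(f"rank-deficient design for K={basis.K} with {times.size} time points")
    C, *_ = lstsq(Phi, Y.T)
    fitted = (Phi @ C).T
    return SmoothFit(basis=basis, times=times, coefficients=C.T, fitted=fitted, residuals=Y - fitted)


def select_K_cv(phenotypes, times, K_grid=None, n_folds=10, seed=0, order=4):
    """Choose the basis size K by n-fold cross-validation over time points.

    Time points are partitioned into random folds; each fold is predicted
    from a basis fit to the remaining points, and squared errors are summed
    over all lines and folds.  Returns (K_star, {K: cv_sse}); infeasible K
    (a training set too small for the basis) map to inf.  Ties break to the
    smaller K.
    """
    Y = np.asarray(phenotypes, dtype=float)
    times = np.asarray(times, dtype=float)
    T = times.size
    if K_grid is None:
        K_grid = range(order, min(40, T - 1) + 1)
    K_grid = sorted(int(K) for K in K_grid)
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(T) % n_folds

    cv = {}
    for K in K_grid:
        sse = 0.0
        feasible = True
        for f in range(n_folds):
            test = fold_of == f
            if not test.any():
                continue
            train = ~test
            t_train = times[train]
            if np.unique(t_train).size < K:
                feasible = False
                break
            try:
                b = build_basis(t_train, K, order=order)
                fit = fit_smooth(Y[:, train], t_train, b)
            except ValueError:
                feasible = False
                break
            # held-out times can fall outside the training span; clamp to it
            t_test = np.clip(times[test], *b.domain)
            pred = fit.coefficients @ b.design(t_test).T
            sse += float(np.sum((Y[:, test] - pred) ** 2))
        cv[K] = sse if feasible else np.inf
    feas = [K for K in K_grid if np.isfinite(cv[K])]
    if not feas:
        raise ValueError("no K in the grid was feasible under cross-validation")
    K_star = min(feas, key=lambda K: (cv[K], K))
    return K_star, cv
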