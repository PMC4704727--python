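"""Single-QTL genome scans by Haley-Knott regression.

At each grid position the traits are regressed on expected genotype
dosages (an additive dosage P(BB) - P(AA), plus a dominance column P(AB)
for an intercross).  Per-trait LOD curves are combined across the p
functional-PC traits by averaging (SL) or maximizing (ML), or replaced by
the multivariate HKLOD statistic

    HKLOD(lambda) = (n/2) log10(|RSS0| / |RSS(lambda)|)

with RSS the p x p residual sum-of-squares-and-cross-products matrix.
SLOD/MLOD are the same mean/max combinations applied to the raw time-point
curves instead of PC scores.

Everything is computed from centered cross-products with stacked
position-wise solves, so a whole-genome scan is a handful of matrix
products; ``fixed_X`` lets multiple-QTL code reuse the same path by
residualizing out already-placed QTL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: floor on RSS relative to the null RSS, capping LOD at perfect fits
RSS_FLOOR = 1e-12


def default_model(cross_type):
    """additive for RIL; additive + dominance for an intercross."""
    return "additive" if cross_type == "ril_self" else "add+dom"


def _predictor_stack(probs, model):
    """Dosage predictors per grid position; shape (G, n, m)."""
    P = probs.probs
    if probs.cross_type == "ril_self":
        if model != "additive":
            raise ValueError("ril_self supports only the additive model")
        return (P[:, :, 1] - P[:, :, 0]).T[:, :, None]
    add = (P[:, :, 2] - P[:, :, 0]).T[:, :, None]
    if model == "additive":
        return add
    if model == "add+dom":
        dom = P[:, :, 1].T[:, :, None]
        return np.concatenate([add, dom], axis=2)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class RegressionDesign:
    """Haley-Knott design at one position: intercept + dosage columns."""

    X: np.ndarray  # (n, q)
    chrom: str
    pos_cM: float


def hk_design(probs, chrom, pos_cM, model=None):
    """Design matrix at an exact grid position (no silent snapping)."""
    if model is None:
        model = default_model(probs.cross_type)
    g = probs.locate(chrom, pos_cM)
    dos = _predictor_stack(probs, model)[g]  # (n, m)
    X = np.column_stack([np.ones(dos.shape[0]), dos])
    name = probs.chrom_names[chrom] if isinstance(chrom, int) else chrom
    return RegressionDesign(X=X, chrom=name, pos_cM=float(pos_cM))


def _residualize(A, Q):
    """Residuals of columns of A on the column space of Q (via thin QR)."""
    Qo, _ = np.linalg.qr(Q)
    return A - Qo @ (Qo.T @ A)


def joint_scan(probs, Y, model=None, fixed_X=None, want_hklod=True):
    """Genome scan of the joint model {fixed QTL} + {one QTL at each position}.

    Returns ``(per_trait_lod, hklod)``: per-trait joint LOD curves (G, p)
    against the intercept-only null, and (if requested) the joint HKLOD
    curve.  With ``fixed_X=None`` this is the ordinary single-QTL scan.

    ``fixed_X`` are the dosage columns of already-placed QTL; they are
    residualized out of both traits and candidate dosages, so the scan cost
    is independent of the number of fixed QTL.
    """
    if model is None:
        model = default_model(probs.cross_type)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and probs.probs.shape[0] != 1:
        Y = Y.T
    n, p = Y.shape
    Xs = _predictor_stack(probs, model)  # (G, n, m)
    G, _, m = Xs.shape

    # null (intercept-only) sums of squares, per trait
    Yc = Y - Y.mean(axis=0)
    rss0 = np.einsum("np,np->p", Yc, Yc)
    const = rss0 <= RSS_FLOOR * max(rss0.max(), 1.0)
    if const.any():
        warnings.warn(f"{int(const.sum())} constant trait(s); their LOD curves are set to 0")

    if fixed_X is None or (hasattr(fixed_X, "size") and fixed_X.size == 0):
        Q0 = np.ones((n, 1))
    else:
        Q0 = np.column_stack([np.ones(n), fixed_X])
    q0 = Q0.shape[1]
    if want_hklod and p > n - (q0 + m):
        raise ValueError(
            f"{p} traits exceed the residual degrees of freedom (n={n}, design {q0 + m} columns); "
            "lower the functional-PCA variance threshold or cap the component count"
        )
    Yr = _residualize(Y, Q0)
    Xr = np.empty_like(Xs)
    Qo, _ = np.linalg.qr(Q0)
    flat = Xs.transpose(1, 0, 2).reshape(n, G * m)
    Xr = (flat - Qo @ (Qo.T @ flat)).reshape(n, G, m).transpose(1, 0, 2)

    rss_fixed = np.einsum("np,np->p", Yr, Yr)
    Sxy = np.einsum("gnm,np->gmp", Xr, Yr)
    Sxx = np.einsum("gnm,gnk->gmk", Xr, Xr)
    # pseudo-inverse handles uninformative positions (flat posteriors -> rank 0)
    Sxx_pinv = np.linalg.pinv(Sxx, hermitian=True, rcond=1e-10)
    beta = np.einsum("gmk,gkp->gmp", Sxx_pinv, Sxy)
    reduction = np.einsum("gmp,gmp->gp", Sxy, beta)

    rss = rss_fixed[None, :] - reduction
    floor = RSS_FLOOR * np.where(const, 1.0, rss0)
    rss = np.maximum(rss, floor[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(rss0[None, :] / rss)
    lod[:, const] = 0.0
    lod = np.maximum(lod, 0.0)

    hklod = None
    if want_hklod:
        rss0_mat = Yc.T @ Yc
        rssf_mat = Yr.T @ Yr
        contrib = np.einsum("gmp,gmq->gpq", Sxy, beta)
        rss_mat = rssf_mat[None] - contrib
        ld0 = _stable_logdet(rss0_mat)
        ldg = np.array([_stable_logdet(rss_mat[g]) for g in range(G)])
        hklod = np.maximum(0.5 * n * (ld0 - ldg) / np.log(10.0), 0.0)
    return lod, hklod


def _stable_logdet(M):
    """log|M| via slogdet, with a trace-scaled ridge on degenerate matrices."""
    sign, ld = np.linalg.slogdet(M)
    if sign > 0 and np.isfinite(ld):
        return ld
    ridge = 1e-10 * max(np.trace(M), 1e-300)
    sign, ld = np.linalg.slogdet(M + ridge * np.eye(M.shape[0]))
    if sign <= 0:
        warnings.warn("residual cross-product matrix numerically singular; log-determinant floored")
        return -690.0 * M.shape[0]  # ~ log(1e-300)
    return ld


def trait_lod_scan(probs, Z, model=None):
    """Per-trait single-QTL Haley-Knott LOD curves; shape (G, p)."""
    Z = np.asarray(Z, dtype=float)
    if np.any(~np.isfinite(Z)):
        raise ValueError("trait matrix contains missing values")
    lod, _ = joint_scan(probs, Z, model=model, want_hklod=False)
    return lod

def combine_sl_ml(per_trait_lod):
    """(mean, max) of the per-trait LOD curves across the trait axis."""
    L = np.atleast_2d(per_trait_lod)
    return L.mean(axis=1), L.max(axis=1)


def hklod_scan(probs, Z, model=None):
    """Multivariate determinant-RSS LOD curve over the grid."""
    _, hk = joint_scan(probs, np.asarray(Z, float), model=model, want_hklod=True)
    return hk


def raw_slod_mlod_scan(probs, smoothed_phenotypes, model=None):
    """SLOD/MLOD comparators: mean/max of per-time-point LOD curves."""
    lod = trait_lod_scan(probs, smoothed_phenotypes, model=model)
    return combine_sl_ml(lod)


STATISTICS = ("sl", "ml", "hklod", "slod", "mlod")


@dataclass
class ScanResult:
    """Statistic curves over the pseudomarker grid."""

    chrom_names: list
    grid_chrom: np.ndarray
    grid_pos: np.ndarray
    is_pseudomarker: np.ndarray
    per_trait_lod: np.ndarray | None
    sl: np.ndarray | None = None
    ml: np.ndarray | None = None
    hklod: np.ndarray | None = None
    slod: np.ndarray | None = None
    mlod: np.ndarray | None = None

    def statistic(self, name):
        val = getattr(self, name)
        if val is None:
            raise ValueError(f"statistic {name!r} was not computed in this scan")
        return val

    def argmax(self, name):
        """(chrom_name, pos_cM, value) of the genome-wide maximum (leftmost tie)."""
        s = self.statistic(name)
        g = int(np.argmax(s))
        return self.chrom_names[self.grid_chrom[g]], float(self.grid_pos[g]), float(s[g])

    def to_frame(self):
        import pandas as pd

        d = {
            "chrom": [self.chrom_names[c] for c in self.grid_chrom],
            "pos_cM": self.grid_pos,
            "is_pseudomarker": self.is_pseudomarker,
        }
        for name in STATISTICS:
            if getattr(self, name) is not None:
                d[name] = getattr(self, name)
        df = pd.DataFrame(d)
        if self.per_trait_lod is not None:
            for j in range(self.per_trait_lod.shape[1]):
                df[f"lod_pc{j + 1}"] = self.per_trait_lod[:, j]
        return df


def scan_genome(probs, Z=None, smoothed=None, methods=("sl", "ml", "hklod"), model=None):
    """Run the requested scan statistics and bundle them in a ScanResult."""
    methods = tuple(methods)
    per_trait = sl = ml = hk = slod = mlod = None
    if any(m in methods for m in ("sl", "ml", "hklod")):
        if Z is None:
            raise ValueError("score matrix Z required for sl/ml/hklod")
        want_hk = "hklod" in methods
        per_trait, hk = joint_scan(probs, np.asarray(Z, float), model=model, want_hklod=want_hk)
        if "sl" in methods or "ml" in methods:
            sl, ml = combine_sl_ml(per_trait)
    if any(m in methods for m in ("slod", "mlod")):
        if smoothed is None:
            raise ValueError("smoothed phenotype matrix required for slod/mlod")
        slod, mlod = raw_slod_mlod_scan(probs, smoothed, model=model)
    return ScanResult(
        chrom_names=probs.chrom_names,
        grid_chrom=probs.grid_chrom,
        grid_pos=probs.grid_pos,
        is_pseudomarker=probs.is_pseudomarker,
        per_trait_lod=per_trait,
        sl=sl if "sl" in methods else None,
        ml=ml if "ml" in methods else None,
        hklod=hk if "hklod" in methods else None,
        slod=slod if "slod" in methods else None,
        mlod=mlod if "mlod" in methods else None,
    )
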