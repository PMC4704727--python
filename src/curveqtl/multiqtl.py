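"""Penalized-LOD stepwise search for additive multiple-QTL models.

A model gamma is a set of QTL positions; its joint fit regresses the
derived traits on an intercept plus one dosage block per QTL, and its
criterion is the penalized LOD

    pLOD(gamma) = LOD(gamma) - T |gamma|

with T a permutation-derived penalty.  LOD here is any of the SL / ML /
HKLOD statistics on functional-PC scores (or SLOD / MLOD on the raw
time-point curves).  The search runs forward selection to a fixed maximum
size, refining all positions by coordinate ascent after each addition,
then backward elimination to the null model; the returned model maximizes
pLOD over everything visited, with ties broken toward the smaller model
and then the leftmost positions.

Per-QTL profile LOD curves compare the model with that QTL moved along
its chromosome (all others fixed) against the model with it dropped; for
SL/ML the per-trait profiles are formed first and then averaged or
maximized.  Effect estimates translate back to the time domain as
beta_hat @ Psi, where Psi holds the eigenfunctions evaluated at the
original time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan import RSS_FLOOR, _predictor_stack, _stable_logdet, default_model, joint_scan

_COMBINE = {"sl": "mean", "slod": "mean", "ml": "max", "mlod": "max", "hklod": "det"}


@dataclass
class FittedQTLModel:
    """Joint fit of a fixed set of QTL positions."""

    statistic: str
    qtl: list  # [(chrom_name, pos_cM), ...]
    joint_lod: float
    penalty_T: float
    per_trait_lod: np.ndarray  # (p,) joint per-trait LODs (empty for hklod)
    design_Q: np.ndarray
    effects_beta: np.ndarray  # (1 + m*|qtl|, p)
    search_log: list = field(default_factory=list)

    @property
    def n_qtl(self):
        return len(self.qtl)

    @property
    def plod(self):
        return self.joint_lod - self.penalty_T * self.n_qtl


def _dosage_columns(probs, positions, model):
    """Stacked dosage columns (n, m*|positions|) for the given grid positions."""
    if not positions:
        return np.empty((probs.probs.shape[0], 0))
    Xs = _predictor_stack(probs, model)
    cols = [Xs[probs.locate(c, p)] for c, p in positions]
    return np.hstack(cols)


def _combine(per_trait, hk, statistic):
    if statistic == "hklod":
        return hk
    if _COMBINE[statistic] == "mean":
        return per_trait.mean(axis=-1)
    return per_trait.max(axis=-1)


def fit_model(probs, Z, positions, statistic="sl", penalty_T=0.0, model=None):
    """Fit the additive multiple-QTL model at the given positions.

    Returns a :class:`FittedQTLModel` with the joint statistic against the
    intercept-only null and the coefficient matrix beta_hat = (Q'Q)^- Q'Z.
    """
    if model is None:
        model = default_model(probs.cross_type)
    if statistic not in _COMBINE:
        raise ValueError(f"unknown statistic {statistic!r}")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1:
        Z = Z.T
    n, p = Z.shape
    positions = [(c, float(pos)) for c, pos in positions]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate QTL positions give a collinear design")
    X = _dosage_columns(probs, positions, model)
    Q = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Q, Z, rcond=None)
    resid = Z - Q @ beta
    Zc = Z - Z.mean(axis=0)
    rss0 = np.einsum("np,np->p", Zc, Zc)
    rss = np.einsum("np,np->p", resid, resid)
    rss = np.maximum(rss, RSS_FLOOR * np.maximum(rss0, 1.0))
    with np.errstate(divide="ignore"):
        per_trait = np.where(rss0 > 0, 0.5 * n * np.log10(np.maximum(rss0, RSS_FLOOR) / rss), 0.0)
    per_trait = np.maximum(per_trait, 0.0)
    if statistic == "hklod":
        ld0 = _stable_logdet(Zc.T @ Zc)
        ld = _stable_logdet(resid.T @ resid)
        joint = max(0.5 * n * (ld0 - ld) / np.log(10.0), 0.0)
    else:
        joint = float(_combine(per_trait, None, statistic)) if positions else 0.0
        if not positions:
            per_trait = np.zeros(p)
    if not positions:
        joint = 0.0
    return FittedQTLModel(
        statistic=statistic,
        qtl=positions,
        joint_lod=float(joint),
        penalty_T=float(penalty_T),
        per_trait_lod=per_trait,
        design_Q=Q,
        effects_beta=beta,
    )


def _candidate_mask(probs, positions, min_sep, exclude_chrom=None):
    """Grid mask of legal new positions given min-separation constraints."""
    ok = np.ones(probs.n_positions, dtype=bool)
    for c, pos in positions:
        ci = probs.chrom_names.index(c) if isinstance(c, str) else c
        ok &= ~((probs.grid_chrom == ci) & (np.abs(probs.grid_pos - pos) < min_sep))
    if exclude_chrom is not None:
        ok &= probs.grid_chrom == exclude_chrom
    return ok


def _joint_curves(probs, Z, fixed_positions, statistic, model):
    """Joint-statistic curve for one added QTL at every grid position."""
    fixed = _dosage_columns(probs, fixed_positions, model)
    want_hk = statistic == "hklod"
    per_trait, hk = joint_scan(probs, Z, model=model, fixed_X=fixed if fixed.size else None, want_hklod=want_hk)
    return per_trait, hk


def _refine_positions(probs, Z, positions, statistic, model, min_sep, max_sweeps=20):
    """Coordinate ascent: move each QTL on its own chromosome to the argmax of
    its profile objective (the gain over the model with it dropped), holding
    the others fixed, until no position moves."""
    positions = list(positions)
    if not positions:
        return positions
    for _ in range(max_sweeps):
        moved = False
        for k in range(len(positions)):
            others = positions[:k] + positions[k + 1 :]
            ck, _ = positions[k]
            ci = probs.chrom_names.index(ck)
            per_trait, hk = _joint_curves(probs, Z, others, statistic, model)
            # profile objective: gain over the model without QTL k; for sl/hklod
            # the baseline is constant in position so this equals the joint statistic
            if statistic in ("ml", "mlod"):
                red = fit_model(probs, Z, others, statistic, model=model).per_trait_lod
                curve = (per_trait - red[None, :]).max(axis=1)
            else:
                curve = _combine(per_trait, hk, statistic)
            mask = _candidate_mask(probs, others, min_sep, exclude_chrom=ci)
            if not mask.any():
                continue
            cand = np.where(mask, curve, -np.inf)
            g = int(np.argmax(cand))
            new = (probs.chrom_names[probs.grid_chrom[g]], float(probs.grid_pos[g]))
            if cand[g] > curve[probs.locate(*positions[k])] + 1e-9 and new != positions[k]:
                positions[k] = new
                moved = True
        if not moved:
            break
    return positions


def _model_key(joint_lod, penalty_T, positions, probs):
    """Sort key: higher pLOD, then smaller model, then leftmost positions."""
    plod = joint_lod - penalty_T * len(positions)
    loc = tuple(sorted((probs.chrom_names.index(c), p) for c, p in positions))
    return (-plod, len(positions), loc)


def stepwise_search(probs, Z, statistic="sl", penalty_T=1.0, max_qtl=10, min_sep=10.0, model=None, refine=True):
    """Forward selection to ``max_qtl`` QTL then backward elimination,
    returning the visited model with the highest penalized LOD.

    After each forward addition the positions of all QTL are re-optimized by
    coordinate ascent; the best model is refined once more before return.
    """
    if max_qtl < 1:
        raise ValueError("max_qtl must be >= 1")
    if penalty_T <= 0:
        raise ValueError("penalty_T must be > 0")
    if model is None:
        model = default_model(probs.cross_type)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1:
        Z = Z.T

    log = [{"step": "null", "qtl": [], "joint_lod": 0.0, "plod": 0.0}]
    visited = [([], 0.0)]
    positions = []
    # forward path
    while len(positions) < max_qtl:
        per_trait, hk = _joint_curves(probs, Z, positions, statistic, model)
        curve = _combine(per_trait, hk, statistic)
        mask = _candidate_mask(probs, positions, min_sep)
        if not mask.any():
            break
        cand = np.where(mask, curve, -np.inf)
        g = int(np.argmax(cand))
        positions = positions + [(probs.chrom_names[probs.grid_chrom[g]], float(probs.grid_pos[g]))]
        if refine:
            positions = _refine_positions(probs, Z, positions, statistic, model, min_sep)
        fitted = fit_model(probs, Z, positions, statistic, penalty_T, model=model)
        visited.append((list(positions), fitted.joint_lod))
        log.append({"step": "forward", "qtl": list(positions), "joint_lod": fitted.joint_lod, "plod": fitted.plod})
    # backward path
    while positions:
        best_red, best_val = None, -np.inf
        for k in range(len(positions)):
            others = positions[:k] + positions[k + 1 :]
            val = fit_model(probs, Z, others, statistic, model=model).joint_lod
            if val > best_val + 1e-12:
                best_red, best_val = others, val
        positions = best_red
        visited.append((list(positions), best_val))
        log.append(
            {
                "step": "backward",
                "qtl": list(positions),
                "joint_lod": best_val,
                "plod": best_val - penalty_T * len(positions),
            }
        )

    best_positions, _ = min(visited, key=lambda v: _model_key(v[1], penalty_T, v[0], probs))
    if refine and best_positions:
        best_positions = _refine_positions(probs, Z, best_positions, statistic, model, min_sep)
    final = fit_model(probs, Z, best_positions, statistic, penalty_T, model=model)
    final.qtl = sorted(final.qtl, key=lambda q: (probs.chrom_names.index(q[0]), q[1]))
    final.search_log = log
    return final


@dataclass
class ProfileResult:
    """Per-QTL profile curves over that QTL's chromosome grid."""

    qtl: list
    chrom: list  # chromosome name per QTL
    pos_cM: list  # grid positions per QTL (arrays)
    curves: list  # profile values per QTL (arrays)


def profile_lod(model_fit, probs, Z, model=None):
    """Profile LOD: statistic(model with QTL k at lambda) - statistic(model
    without k), for every grid position lambda on k's chromosome."""
    if model is None:
        model = default_model(probs.cross_type)
    statistic = model_fit.statistic
    if model_fit.n_qtl < 1:
        raise ValueError("profile LOD needs at least one QTL in the model")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1:
        Z = Z.T
    chroms, poss, curves = [], [], []
    for k in range(model_fit.n_qtl):
        others = model_fit.qtl[:k] + model_fit.qtl[k + 1 :]
        reduced = fit_model(probs, Z, others, statistic, model=model)
        per_trait, hk = _joint_curves(probs, Z, others, statistic, model)
        if statistic == "hklod":
            curve = hk - reduced.joint_lod
        elif _COMBINE[statistic] == "mean":
            curve = per_trait.mean(axis=1) - reduced.joint_lod
        else:
            curve = (per_trait - reduced.per_trait_lod[None, :]).max(axis=1)
        ci = probs.chrom_names.index(model_fit.qtl[k][0])
        sl = probs.chrom_slice(ci)
        chroms.append(model_fit.qtl[k][0])
        poss.append(probs.grid_pos[sl].copy())
        curves.append(curve[sl])
    return ProfileResult(qtl=list(model_fit.qtl), chrom=chroms, pos_cM=poss, curves=curves)


@dataclass
class EffectCurves:
    """Model effects translated to the time domain via beta_hat @ Psi."""

    times: np.ndarray
    baseline: np.ndarray  # (T,)
    qtl: list
    effects: np.ndarray  # (n_qtl, T): high-allele minus low-allele contrast
    dominance: np.ndarray | None = None  # (n_qtl, T) for intercross models


def effects_to_time_domain(model_fit, fpca_res, cross_type="ril_self", times=None):
    """Translate fitted coefficients on the PC traits back to curves over time.

    QTL rows are reported as the high-allele-minus-low-allele contrast:
    dosages are coded -1/+1, so the contrast is twice the additive
    coefficient.  The baseline adds back the mean curve when the PCA was
    centered.
    """
    beta = model_fit.effects_beta
    Psi = fpca_res.psi_matrix
    if beta.shape[1] != Psi.shape[0]:
        raise ValueError(
            f"coefficient columns ({beta.shape[1]}) do not match eigenfunction rows ({Psi.shape[0]})"
        )
    curves = beta @ Psi  # rows: intercept then per-QTL blocks
    m = 1 if cross_type == "ril_self" else 2
    baseline = curves[0] + fpca_res.mean_curve
    add = 2.0 * curves[1::m] if model_fit.n_qtl else np.empty((0, Psi.shape[1]))
    dom = curves[2::m] if m == 2 and model_fit.n_qtl else None
    return EffectCurves(
        times=np.asarray(times, float) if times is not None else None,
        baseline=baseline,
        qtl=list(model_fit.qtl),
        effects=add,
        dominance=dom,
    )
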