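"""Simulation designs for benchmarking the function-valued QTL methods.

Two designs are provided.

Single-QTL intercross
    One 100 cM chromosome with six equally spaced markers and a QTL at
    32 cM.  Mean curves follow a logistic growth function
    g(t) = a / (1 + b exp(-r t)) with genotype-specific (a, b, r):
    AA (29, 7, 0.70), AB (28.5, 6.5, 0.73), BB (27.5, 5, 0.75).  Residual
    curves are multivariate normal with covariance c*Sigma, Sigma either
    autoregressive (sigma^2 = 3, rho = 0.6), equicorrelated (sigma^2 = 3,
    rho = 0.5), or a user-supplied matrix; c scales the error variance and
    thereby the mean heritability across the ten time points.

Multi-QTL RIL
    A five-chromosome selfed-RIL genome.  Each line's curve is a cubic
    polynomial over t in [0, 1] whose four coefficients are a baseline
    plus QTL-dosage multiples of per-QTL cubic effect coefficients plus a
    multivariate-normal individual deviation, observed at 241 equally
    spaced time points with i.i.d. measurement noise.  The effect
    coefficients are inputs: no canonical values exist, so tests and the
    built-in benchmark use the package's documented example spec.

A small driver (:func:`run_power_study`) runs the full pipeline —
smoothing with cross-validated K, functional PCA, scans, permutation
thresholds — over replicate datasets and reports per-method power and RMS
position error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fpca import functional_pca, gram_matrix
from .genetics import CrossData, GeneticMap, calc_genoprob, simulate_cross
from .permutation import permute_thresholds
from .scan import scan_genome
from .smooth import build_basis, fit_smooth, select_K_cv

#: genotype-specific logistic growth parameters (a, b, r)
DEFAULT_LOGISTIC_PARAMS = {
    "AA": (29.0, 7.0, 0.70),
    "AB": (28.5, 6.5, 0.73),
    "BB": (27.5, 5.0, 0.75),
}


def logistic_mean(t, a, b, r):
    """Logistic growth curve g(t) = a / (1 + b e^{-rt})."""
    if r <= 0:
        raise ValueError("growth rate r must be > 0")
    if b <= -1:
        raise ValueError("b must be > -1 so the curve is defined at t=0")
    t = np.asarray(t, dtype=float)
    return a / (1.0 + b * np.exp(-r * t))


@dataclass(frozen=True)
class CovarianceSpec:
    """Residual covariance c*Sigma for the single-QTL design."""

    structure: str = "autoregressive"  # autoregressive | equicorrelated | custom
    sigma2: float = 3.0
    rho: float = 0.6
    c: float = 1.0
    T_pts: int = 10
    custom_matrix: np.ndarray | None = None


def build_covariance(spec):
    """Realize the T x T covariance matrix of a :class:`CovarianceSpec`."""
    T = spec.T_pts
    if spec.structure == "autoregressive":
        j = np.arange(T)
        S = spec.sigma2 * spec.rho ** np.abs(j[:, None] - j[None, :])
    elif spec.structure == "equicorrelated":
        S = np.full((T, T), spec.sigma2 * spec.rho)
        np.fill_diagonal(S, spec.sigma2)
    elif spec.structure == "custom":
        if spec.custom_matrix is None:
            raise ValueError("custom structure requires custom_matrix")
        S = np.asarray(spec.custom_matrix, dtype=float)
        if S.shape != (T, T):
            raise ValueError(f"custom_matrix must be {T}x{T}")
        if not np.allclose(S, S.T) or np.min(np.linalg.eigvalsh(S)) < -1e-8:
            raise ValueError("custom covariance matrix must be symmetric PSD")
    else:
        raise ValueError(f"unknown covariance structure {spec.structure!r}")
    return spec.c * S


F2_GENO_FREQS = (0.25, 0.5, 0.25)


def mean_heritability(params, cov_matrix, genotype_freqs=F2_GENO_FREQS, times=None):
    """Mean across time of h^2(t) = var_g(t) / (var_g(t) + residual var(t)).

    Genetic variance at each time point is the weighted variance of the
    genotype mean curves under ``genotype_freqs``.
    """
    freqs = np.asarray(genotype_freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("genotype frequencies must sum to 1")
    cov_matrix = np.asarray(cov_matrix, dtype=float)
    T = cov_matrix.shape[0]
    if times is None:
        times = np.arange(1, T + 1, dtype=float)
    curves = np.array([logistic_mean(times, *params[g]) for g in ("AA", "AB", "BB")])
    gbar = freqs @ curves
    var_g = freqs @ (curves - gbar) ** 2
    h2 = var_g / (var_g + np.diag(cov_matrix))
    return float(h2.mean())


def simulate_single_qtl_dataset(
    n,
    params=DEFAULT_LOGISTIC_PARAMS,
    cov_spec=CovarianceSpec(),
    qtl_pos=32.0,
    chrom_len=100.0,
    n_markers=6,
    T_pts=10,
    seed=0,
):
    """Simulate the single-QTL intercross design; returns (cross, qtl_geno).

    ``qtl_geno`` are the latent QTL genotype codes used to pick each line's
    mean curve (handy for oracle checks); the QTL itself is not among the
    observed markers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    marker_pos = np.linspace(0.0, chrom_len, n_markers)
    aug = np.sort(np.unique(np.append(marker_pos, qtl_pos)))
    qtl_idx = int(np.nonzero(np.abs(aug - qtl_pos) < 1e-9)[0][0])
    names = tuple(f"M{j + 1}" if p in marker_pos else "QTL" for j, p in enumerate(aug))
    from .genetics import Chromosome

    aug_map = GeneticMap((Chromosome("1", names, aug),))
    full = simulate_cross(aug_map, n, "f2", rng=rng)
    qtl_geno = full.genotypes[:, qtl_idx].copy()
    keep = [j for j in range(aug.size) if names[j] != "QTL"]
    obs_map = GeneticMap((Chromosome("1", tuple(names[j] for j in keep), aug[keep]),))
    genotypes = full.genotypes[:, keep]

    times = np.arange(1, T_pts + 1, dtype=float)
    spec = CovarianceSpec(
        structure=cov_spec.structure,
        sigma2=cov_spec.sigma2,
        rho=cov_spec.rho,
        c=cov_spec.c,
        T_pts=T_pts,
        custom_matrix=cov_spec.custom_matrix,
    )
    cov = build_covariance(spec)
    means = np.array([logistic_mean(times, *params[g]) for g in ("AA", "AB", "BB")])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(T_pts))
    resid = rng.standard_normal((n, T_pts)) @ chol.T
    Y = means[qtl_geno] + resid
    cross = CrossData("f2", obs_map, genotypes, phenotypes=Y, times=times)
    return cross, qtl_geno


def add_measurement_noise(cross, sd, seed=0):
    """Add i.i.d. Gaussian measurement noise to every phenotype cell."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return cross
    rng = np.random.default_rng(seed)
    noisy = cross.phenotypes + sd * rng.standard_normal(cross.phenotypes.shape)
    return cross.with_phenotypes(noisy, cross.times)


@dataclass
class MultiQTLSimSpec:
    """Configuration of the cubic multi-QTL RIL design."""

    qtl: list  # [(chrom_name, pos_cM), ...]
    effect_coeffs: np.ndarray  # (n_qtl, 4) cubic coefficients (a, b, c, d) on t in [0,1]
    baseline_coeffs: np.ndarray  # (4,)
    coeff_covariance: np.ndarray  # (4, 4) individual-level deviation covariance
    noise_sd: float = 1.0
    n: int = 162
    T_pts: int = 241
    genmap: GeneticMap = None
    marker_spacing: float = 10.0

    def __post_init__(self):
        if self.qtl is None or self.effect_coeffs is None or self.baseline_coeffs is None:
            raise ValueError(
                "qtl positions, effect_coeffs and baseline_coeffs are required inputs "
                "(see MultiQTLSimSpec / example_threeqtl_spec)"
            )
        self.effect_coeffs = np.atleast_2d(np.asarray(self.effect_coeffs, dtype=float))
        self.baseline_coeffs = np.asarray(self.baseline_coeffs, dtype=float)
        if self.effect_coeffs.shape != (len(self.qtl), 4) or self.baseline_coeffs.shape != (4,):
            raise ValueError("effect_coeffs must be (n_qtl, 4) and baseline_coeffs length 4")
        if self.coeff_covariance is None:
            self.coeff_covariance = np.zeros((4, 4))
        self.coeff_covariance = np.asarray(self.coeff_covariance, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.genmap is None:
            self.genmap = GeneticMap.uniform(5, 100.0, self.marker_spacing)

    @property
    def times(self):
        return np.linspace(0.0, 1.0, self.T_pts)


def example_threeqtl_spec(n=162, noise_sd=1.0, T_pts=241):
    """A documented example of the three-QTL cubic design.

    QTL sit at chr1@61, chr3@76 and chr4@40 on a five-chromosome RIL map.
    The cubic coefficients are the package's own example values, chosen so
    the three effect curves differ in shape and timing (late-rising,
    mid-bump, early-broad) with heritabilities in the detectable range.
    """
    return MultiQTLSimSpec(
        qtl=[("C1", 61.0), ("C3", 76.0), ("C4", 40.0)],
        effect_coeffs=np.array(
            [
                [0.0, 0.5, 1.0, 3.0],  # chr1: effect grows toward late times
                [0.2, 1.5, -1.5, 0.3],  # chr3: modest mid-course bump
                [1.0, 4.0, -4.5, 1.2],  # chr4: early onset, broad in time
            ]
        ),
        baseline_coeffs=np.array([20.0, 90.0, -60.0, 10.0]),
        coeff_covariance=np.diag([4.0, 16.0, 16.0, 4.0]),
        noise_sd=noise_sd,
        n=n,
        T_pts=T_pts,
    )


def simulate_multiqtl_dataset(spec, seed=0):
    """Simulate the cubic multi-QTL RIL design; returns (cross, dosages).

    Per line, coefficient vector = baseline + sum_q dosage_q * effect_q +
    MVN(0, coeff_covariance), with RIL dosage -1/+1; the phenotype is the
    cubic evaluated at the T time points plus N(0, noise_sd^2) noise.
    """
    rng = np.random.default_rng(seed)
    # simulate on a map augmented with the QTL as extra loci, then split the
    # genotype matrix into observed markers and latent QTL dosages
    from .genetics import Chromosome

    aug_chroms, qtl_cols, keep_cols, off = [], {}, [], 0
    for chrom in spec.genmap.chromosomes:
        here = [(pos, q) for q, (cn, pos) in enumerate(spec.qtl) if cn == chrom.name]
        pos = list(chrom.positions)
        names = list(chrom.markers)
        for p, q in here:
            if not any(abs(p - x) < 1e-9 for x in pos):
                j = int(np.searchsorted(pos, p))
                pos.insert(j, p)
                names.insert(j, f"__QTL{q}")
        aug_chroms.append(Chromosome(chrom.name, tuple(names), np.array(pos)))
        for j, nm in enumerate(names):
            if nm.startswith("__QTL"):
                qtl_cols[int(nm[5:])] = off + j
            else:
                keep_cols.append(off + j)
                if here and any(abs(pos[j] - p) < 1e-9 for p, _ in here):
                    for p, q in here:
                        if abs(pos[j] - p) < 1e-9:
                            qtl_cols[q] = off + j
        off += len(names)
    full = simulate_cross(GeneticMap(tuple(aug_chroms)), spec.n, "ril_self", rng=rng)
    dosages = np.column_stack(
        [2.0 * full.genotypes[:, qtl_cols[q]] - 1.0 for q in range(len(spec.qtl))]
    )
    cross = CrossData("ril_self", spec.genmap, full.genotypes[:, keep_cols])

    coeffs = (
        spec.baseline_coeffs[None, :]
        + dosages @ spec.effect_coeffs
        + rng.multivariate_normal(np.zeros(4), spec.coeff_covariance, size=spec.n, method="svd")
    )
    t = spec.times
    design = np.vstack([np.ones_like(t), t, t**2, t**3]).T  # (T, 4)
    Y = coeffs @ design.T + spec.noise_sd * rng.standard_normal((spec.n, spec.T_pts))
    return cross.with_phenotypes(Y, t), dosages


@dataclass
class PipelineSettings:
    """Analysis settings used when the power study runs the full pipeline."""

    step: float = 2.0
    error_prob: float = 1e-4
    k_grid: tuple = None
    n_folds: int = 10
    var_threshold: float = 0.99
    center: bool = True
    max_pc: int = None


def analyze_dataset(cross, settings=PipelineSettings(), methods=("sl", "ml", "hklod", "slod", "mlod"), seed=0):
    """Smooth (CV for K), run functional PCA, and scan with each method.

    Returns (scan_result, context) where context carries the smooth fit,
    PCA result, and genotype probabilities for reuse.
    """
    Y, times = cross.phenotypes, cross.times
    k_grid = settings.k_grid or range(4, min(13, times.size) + 1)
    K, cv = select_K_cv(Y, times, k_grid, n_folds=min(settings.n_folds, times.size), seed=seed)
    basis = build_basis(times, K)
    fit = fit_smooth(Y, times, basis)
    W = gram_matrix(basis)
    res = functional_pca(fit, W, var_threshold=settings.var_threshold, center=settings.center, max_pc=settings.max_pc)
    probs = calc_genoprob(cross, step=settings.step, error_prob=settings.error_prob)
    sr = scan_genome(probs, Z=res.scores, smoothed=fit.fitted, methods=methods)
    return sr, {"K": K, "cv": cv, "smooth": fit, "fpca": res, "probs": probs}


def run_power_study(
    design_fn,
    methods=("sl", "ml", "hklod", "slod", "mlod"),
    n_reps=100,
    n_perm=200,
    alpha=0.05,
    true_pos=32.0,
    true_chrom="1",
    settings=PipelineSettings(),
    seed=0,
    thresholds=None,
):
    """Power and RMS position error per method over replicate datasets.

    ``design_fn(seed)`` must return a CrossData.  Per-method 5% thresholds
    are estimated once by permutation on the first replicate (passing
    ``thresholds`` skips this) and reused across replicates; a detection is
    a genome-wide maximum above threshold, and RMS position error is taken
    over detected replicates on the true chromosome.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps + 1)]

    if thresholds is None:
        first = design_fn(rep_seeds[-1])
        sr0, ctx = analyze_dataset(first, settings, methods, seed=rep_seeds[-1])
        perms = permute_thresholds(
            ctx["probs"], scores=ctx["fpca"].scores, smoothed=ctx["smooth"].fitted,
            statistics=methods, n_perm=n_perm, alpha=alpha, seed=rep_seeds[-1],
        )
        thresholds = {m: perms[m].threshold(alpha) for m in methods}

    detected = {m: 0 for m in methods}
    sqerr = {m: [] for m in methods}
    for rep in range(n_reps):
        cross = design_fn(rep_seeds[rep])
        sr, _ = analyze_dataset(cross, settings, methods, seed=rep_seeds[rep])
        for m in methods:
            chrom, pos, val = sr.argmax(m)
            if val > thresholds[m]:
                detected[m] += 1
                if chrom == true_chrom:
                    sqerr[m].append((pos - true_pos) ** 2)
    rows = []
    for m in methods:
        power = detected[m] / n_reps
        rms = float(np.sqrt(np.mean(sqerr[m]))) if sqerr[m] else np.nan
        rows.append({"method": m, "power": power, "rms_error_cM": rms, "threshold": thresholds[m], "n_reps": n_reps})
    return pd.DataFrame(rows).set_index("method")
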