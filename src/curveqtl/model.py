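"""Model / results facade over the full function-valued QTL pipeline.

`FunctionalQTLModel` is built from a cross (genotypes, genetic map, and a
phenotype-curve matrix); `fit()` executes smoothing with cross-validated
basis size, functional PCA, single-QTL genome scans, and optionally
permutation thresholds and penalized-LOD stepwise model selection,
returning a `FunctionalQTLResults` object with the estimates, curves and
a text `summary()`.  `save_artifacts()` writes every intermediate next to
a manifest of the effective configuration and seeds, so a run is
reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__


def _jsonable(obj):
    """Fallback encoder for numpy scalars, arrays, ranges, and paths."""
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, range):
        return list(obj)
    return str(obj)
from .fpca import functional_pca, gram_matrix
from .genetics import calc_genoprob
from .io import read_cross_csvr
from .multiqtl import effects_to_time_domain, fit_model, profile_lod, stepwise_search
from .permutation import permute_thresholds
from .scan import default_model, scan_genome
from .smooth import build_basis, fit_smooth, impute_missing, select_K_cv


@dataclass
class FunctionalQTLConfig:
    step: float = 1.0
    error_prob: float = 1e-4
    k_grid: tuple | None = None
    n_folds: int = 10
    var_threshold: float = 0.99
    center: bool = True
    max_pc: int | None = None
    methods: tuple = ("sl", "ml", "hklod")
    n_perm: int = 0
    alpha: float = 0.05
    penalty: float | None = None
    stepwise: str | None = None
    max_qtl: int = 10
    min_sep: float = 10.0
    seed: int = 0


class FunctionalQTLModel:
    """QTL mapping of a function-valued trait on an experimental cross."""

    def __init__(self, cross, **config):
        self.cross = cross
        self.config = FunctionalQTLConfig(**config)

    @classmethod
    def from_csvr(cls, path, cross_type="ril_self", **config):
        return cls(read_cross_csvr(path, cross_type=cross_type), **config)

    def fit(self, **overrides):
        """Run the pipeline under the model's configuration.

        Keyword overrides update the stored configuration for this fit.
        Stepwise model selection runs when ``stepwise`` names a statistic;
        its penalty is ``penalty`` if given, else that statistic's
        permutation threshold (which requires ``n_perm > 0``).
        """
        cfg = FunctionalQTLConfig(**{**asdict(self.config), **overrides})
        cross = self.cross
        timings = {}

        t0 = time.perf_counter()
        Y = impute_missing(cross.phenotypes, cross.times)
        k_grid = cfg.k_grid or range(4, min(40, cross.times.size - 1) + 1)
        K, cv = select_K_cv(Y, cross.times, k_grid, n_folds=min(cfg.n_folds, cross.times.size), seed=cfg.seed)
        basis = build_basis(cross.times, K)
        smooth = fit_smooth(Y, cross.times, basis)
        timings["smooth"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        W = gram_matrix(basis)
        fpca = functional_pca(smooth, W, var_threshold=cfg.var_threshold, center=cfg.center, max_pc=cfg.max_pc)
        timings["fpca"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        probs = calc_genoprob(cross, step=cfg.step, error_prob=cfg.error_prob)
        scan = scan_genome(probs, Z=fpca.scores, smoothed=smooth.fitted, methods=cfg.methods)
        timings["scan"] = time.perf_counter() - t0

        thresholds = {}
        if cfg.n_perm > 0:
            t0 = time.perf_counter()
            perms = permute_thresholds(
                probs, scores=fpca.scores, smoothed=smooth.fitted,
                statistics=cfg.methods, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed,
            )
            thresholds = {m: perms[m].threshold(cfg.alpha) for m in cfg.methods}
            timings["permute"] = time.perf_counter() - t0

        selected = profiles = effects = None
        if cfg.stepwise is not None:
            t0 = time.perf_counter()
            stat = cfg.stepwise
            penalty = cfg.penalty if cfg.penalty is not None else thresholds.get(stat)
            if penalty is None:
                raise ValueError("stepwise search needs an explicit penalty or n_perm > 0")
            traits = smooth.fitted if stat in ("slod", "mlod") else fpca.scores
            selected = stepwise_search(
                probs, traits, statistic=stat, penalty_T=penalty, max_qtl=cfg.max_qtl, min_sep=cfg.min_sep
            )
            if selected.n_qtl:
                profiles = profile_lod(selected, probs, traits)
                if stat not in ("slod", "mlod"):
                    effects = effects_to_time_domain(selected, fpca, cross.cross_type, times=cross.times)
            timings["stepwise"] = time.perf_counter() - t0

        return FunctionalQTLResults(
            cross=cross,
            config=cfg,
            K=K,
            cv_table=cv,
            smooth=smooth,
            fpca=fpca,
            probs=probs,
            scan=scan,
            thresholds=thresholds,
            selected=selected,
            profiles=profiles,
            effects=effects,
            timings=timings,
        )


@dataclass
class FunctionalQTLResults:
    """Fitted curves, scores, scan statistics, and the selected QTL model."""

    cross: object
    config: FunctionalQTLConfig
    K: int
    cv_table: dict
    smooth: object
    fpca: object
    probs: object
    scan: object
    thresholds: dict
    selected: object | None
    profiles: object | None
    effects: object | None
    timings: dict = field(default_factory=dict)

    def summary(self):
        c = self.cross
        lines = [
            "Function-valued QTL mapping results",
            "=" * 40,
            f"cross type        : {c.cross_type}",
            f"lines             : {c.n_lines}",
            f"markers           : {c.genmap.n_markers} on {len(c.genmap.chromosomes)} chromosomes",
            f"time points       : {c.times.size}",
            f"basis size K (CV) : {self.K}",
            f"PCs retained p    : {self.fpca.p} "
            f"(cumulative variance {self.fpca.varprop.sum():.4f})",
        ]
        for m in self.config.methods:
            chrom, pos, val = self.scan.argmax(m)
            thr = self.thresholds.get(m)
            mark = "" if thr is None else ("  *" if val > thr else "")
            thr_s = "" if thr is None else f" (5% threshold {thr:.2f})"
            lines.append(f"max {m.upper():6s}        : {val:.2f} at {chrom}@{pos:g} cM{thr_s}{mark}")
        if self.selected is not None:
            lines.append(
                f"selected model ({self.selected.statistic.upper()}): {self.selected.n_qtl} QTL, "
                f"joint LOD {self.selected.joint_lod:.2f}, pLOD {self.selected.plod:.2f}"
            )
            for chrom, pos in self.selected.qtl:
                lines.append(f"    QTL {chrom}@{pos:g} cM")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save_artifacts(self, outdir):
        """Write all intermediates plus a manifest; returns the manifest dict."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        c = self.cross

        smoothed = pd.DataFrame(self.smooth.fitted, index=c.line_ids, columns=[f"{t:g}" for t in c.times])
        smoothed.to_csv(out / "smoothed.csv")
        scores = pd.DataFrame(
            self.fpca.scores, index=c.line_ids, columns=[f"PC{j + 1}" for j in range(self.fpca.p)]
        )
        scores.to_csv(out / "scores.csv")
        pd.DataFrame(
            {"K": list(self.cv_table), "cv_sse": [self.cv_table[k] for k in self.cv_table]}
        ).to_csv(out / "cv_table.tsv", sep="\t", index=False)
        self.scan.to_frame().to_csv(out / "scan.tsv", sep="\t", index=False)
        if self.thresholds:
            (out / "thresholds.json").write_text(json.dumps(self.thresholds, indent=2, sort_keys=True, default=_jsonable))
        if self.selected is not None:
            model_doc = {
                "statistic": self.selected.statistic,
                "qtl": [{"chrom": ch, "pos_cM": p} for ch, p in self.selected.qtl],
                "joint_lod": self.selected.joint_lod,
                "plod": self.selected.plod,
                "penalty_T": self.selected.penalty_T,
                "search_log": self.selected.search_log,
            }
            (out / "model.json").write_text(json.dumps(model_doc, indent=2, default=_jsonable))
            if self.profiles is not None:
                rows = []
                for k in range(len(self.profiles.qtl)):
                    for pos, v in zip(self.profiles.pos_cM[k], self.profiles.curves[k]):
                        rows.append({"qtl": k + 1, "chrom": self.profiles.chrom[k], "pos_cM": pos, "profile": v})
                pd.DataFrame(rows).to_csv(out / "profiles.tsv", sep="\t", index=False)
            if self.effects is not None:
                eff = pd.DataFrame({"time": c.times, "baseline": self.effects.baseline})
                for k, (ch, p) in enumerate(self.effects.qtl):
                    eff[f"{ch}@{p:g}"] = self.effects.effects[k]
                eff.to_csv(out / "effects.csv", index=False)

        manifest = {
            "package": "curveqtl",
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, (tuple, range)) else v) for k, v in asdict(self.config).items()},
            "n_lines": c.n_lines,
            "n_markers": c.genmap.n_markers,
            "n_times": int(c.times.size),
            "K": self.K,
            "p": self.fpca.p,
            "thresholds": self.thresholds,
            "stage_seconds": {k: round(v, 3) for k, v in self.timings.items()},
            "outputs": {},
        }
        for f in sorted(out.glob("*")):
            if f.name == "manifest.json":
                continue
            manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        stable = {k: v for k, v in manifest.items() if k != "stage_seconds"}
        manifest["content_hash"] = hashlib.sha256(
            json.dumps(stable, sort_keys=True, default=_jsonable).encode()
        ).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_jsonable))
        return manifest
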