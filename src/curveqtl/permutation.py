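"""Genome-wide significance thresholds by permutation.

Rows of the derived-trait matrix (all traits jointly, so their correlation
structure is preserved) are permuted against the genotypes; each
permutation is rescanned genome-wide and the maximum statistic recorded.
The threshold at level alpha is the empirical (1 - alpha) quantile of
those maxima — the order statistic of 1-based rank ceil((1-alpha) R) —
and doubles as the penalty T of the penalized-LOD criterion.

Permutations are seeded independently from the root seed by a counter
(numpy SeedSequence spawn keys), so results do not depend on execution
order or batching.  For the per-trait statistics (sl/ml/slod/mlod) all
permutations are scanned in one batched call by stacking the permuted
trait matrices as extra trait columns; statistics that share a scan (SL
and ML; SLOD and MLOD) are extracted from the same pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan import STATISTICS, joint_scan

_PC_STATS = ("sl", "ml", "hklod")
_RAW_STATS = ("slod", "mlod")


@dataclass
class PermutationResult:
    statistic: str
    null_maxima: np.ndarray  # (R,)
    alpha: float
    seed: int

    @property
    def n_perm(self):
        return self.null_maxima.size

    def threshold(self, alpha=None):
        """Empirical (1-alpha) quantile: order statistic of rank ceil((1-a)R)."""
        if alpha is None:
            alpha = self.alpha
        if not (0 < alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        R = self.n_perm
        rank = max(int(np.ceil((1.0 - alpha) * R)), 1)
        return float(np.sort(self.null_maxima)[rank - 1])


def _perm_indices(n, n_perm, seed):
    out = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        out[i] = rng.permutation(n)
    return out


def _as_matrix(Z):
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return Z.T if Z.shape[0] == 1 else Z


def _batched_mean_max_maxima(probs, Z, idx, model, batch):
    """Genome-wide maxima of the mean- and max-combined per-trait LOD for
    every permutation, via stacked-trait batched scans."""
    n, p = Z.shape
    n_perm = idx.shape[0]
    mean_max = np.empty(n_perm)
    max_max = np.empty(n_perm)
    for start in range(0, n_perm, batch):
        stop = min(start + batch, n_perm)
        nb = stop - start
        Zbig = Z[idx[start:stop]].transpose(1, 0, 2).reshape(n, nb * p)
        lod, _ = joint_scan(probs, Zbig, model=model, want_hklod=False)
        lod = lod.reshape(lod.shape[0], nb, p)
        mean_max[start:stop] = lod.mean(axis=2).max(axis=0)
        max_max[start:stop] = lod.max(axis=2).max(axis=0)
    return mean_max, max_max


def permute_thresholds(
    probs,
    scores=None,
    smoothed=None,
    statistics=("sl",),
    n_perm=1000,
    alpha=0.05,
    seed=0,
    model=None,
    batch=256,
):
    """Null distributions of the genome-wide maximum for several statistics.

    ``scores`` feeds sl/ml/hklod; ``smoothed`` feeds slod/mlod.  Statistics
    sharing a trait matrix and a combine rule reuse one batched permutation
    scan.  Returns {statistic: PermutationResult}.
    """
    statistics = tuple(statistics)
    for s in statistics:
        if s not in STATISTICS:
            raise ValueError(f"statistic {s!r} is not scannable")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    out = {}

    def _run_group(traits, wanted, mean_name, max_name, det_name):
        traits = _as_matrix(traits)
        idx = _perm_indices(traits.shape[0], n_perm, seed)
        if mean_name in wanted or max_name in wanted:
            mean_max, max_max = _batched_mean_max_maxima(probs, traits, idx, model, batch)
            if mean_name in wanted:
                out[mean_name] = PermutationResult(mean_name, mean_max, alpha, seed)
            if max_name in wanted:
                out[max_name] = PermutationResult(max_name, max_max, alpha, seed)
        if det_name in wanted:
            maxima = np.empty(n_perm)
            for i in range(n_perm):
                _, hk = joint_scan(probs, traits[idx[i]], model=model, want_hklod=True)
                maxima[i] = hk.max()
            out[det_name] = PermutationResult(det_name, maxima, alpha, seed)

    pc_wanted = [s for s in statistics if s in _PC_STATS]
    if pc_wanted:
        if scores is None:
            raise ValueError("sl/ml/hklod permutations need the score matrix")
        _run_group(scores, pc_wanted, "sl", "ml", "hklod")
    raw_wanted = [s for s in statistics if s in _RAW_STATS]
    if raw_wanted:
        if smoothed is None:
            raise ValueError("slod/mlod permutations need the smoothed phenotype matrix")
        _run_group(smoothed, raw_wanted, "slod", "mlod", None)
    return out


def permute_scan(probs, Z, statistic="sl", n_perm=1000, alpha=0.05, seed=0, model=None, batch=256):
    """Permutation distribution of the genome-wide maximum of one statistic.

    ``Z`` is the trait matrix the statistic scans (PC scores for
    sl/ml/hklod, the smoothed phenotype matrix for slod/mlod).
    """
    kwargs = dict(statistics=(statistic,), n_perm=n_perm, alpha=alpha, seed=seed, model=model, batch=batch)
    if statistic in _RAW_STATS:
        return permute_thresholds(probs, smoothed=Z, **kwargs)[statistic]
    return permute_thresholds(probs, scores=Z, **kwargs)[statistic]
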