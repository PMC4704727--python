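"""Genetic maps, cross simulation, and conditional QTL-genotype probabilities.

Experimental crosses are modeled as Markov chains along each chromosome,
with transition probabilities derived from the Haldane map function
(no crossover interference).  Two cross types are supported:

``ril_self``
    Recombinant inbred lines by selfing.  Lines are fully homozygous, so
    there are two genotype classes (AA=0, BB=1) and the map is expanded by
    R = 2r/(1+2r).
``f2``
    An intercross with three genotype classes (AA=0, AB=1, BB=2), realized
    as two independent meiotic haplotypes.

Posterior genotype probabilities on a pseudomarker grid (the inputs to
Haley-Knott regression) are computed by a forward-backward pass over the
chain, with a symmetric genotyping-error emission model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

CROSS_TYPES = ("ril_self", "f2")

#: genotype class counts per cross type
N_GENO = {"ril_self": 2, "f2": 3}


def haldane_recfrac(d):
    """Map distance in cM -> recombination fraction under the Haldane map.

    r = (1 - exp(-2d/100)) / 2, monotone in d, saturating at 1/2.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative (got negative cM)")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def ril_self_recfrac(r):
    """Meiotic recombination fraction -> effective two-line RIL fraction.

    For RIL by selfing, R = 2r / (1 + 2r).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass(frozen=True)
class Chromosome:
    name: str
    markers: tuple
    positions: np.ndarray  # cM, ascending

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.size == 0:
            raise ValueError(f"chromosome {self.name!r} has no markers")
        if len(self.markers) != pos.size:
            raise ValueError(f"chromosome {self.name!r}: marker/position length mismatch")
        if not np.all(np.isfinite(pos)) or np.any(pos < 0):
            raise ValueError(f"chromosome {self.name!r}: positions must be finite and >= 0")
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"chromosome {self.name!r}: positions must be non-decreasing")


@dataclass(frozen=True)
class GeneticMap:
    """An ordered collection of chromosomes with marker names and cM positions."""

    chromosomes: tuple

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def n_markers(self):
        return sum(len(c.markers) for c in self.chromosomes)

    @property
    def marker_names(self):
        return [m for c in self.chromosomes for m in c.markers]

    @classmethod
    def uniform(cls, n_chrom, length_cM, spacing_cM, prefix="C"):
        """Equally spaced markers every ``spacing_cM`` on ``n_chrom`` chromosomes."""
        chroms = []
        for i in range(n_chrom):
            name = f"{prefix}{i + 1}"
            pos = np.arange(0.0, length_cM + 1e-9, spacing_cM)
            markers = tuple(f"{name}M{j + 1}" for j in range(pos.size))
            chroms.append(Chromosome(name, markers, pos))
        return cls(tuple(chroms))


@dataclass
class CrossData:
    """Genotypes, a genetic map, and a function-valued phenotype matrix.

    genotypes : (n, M) int array; ril_self codes {0=AA, 1=BB}, f2 codes
        {0=AA, 1=AB, 2=BB}; MISSING (-1) allowed.
    phenotypes : (n, T) float array or None; one trait value per time point.
    times : (T,) ascending reals.
    """

    cross_type: str
    genmap: GeneticMap
    genotypes: np.ndarray
    phenotypes: np.ndarray | None = None
    times: np.ndarray | None = None
    line_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.cross_type not in CROSS_TYPES:
            raise ValueError(f"unknown cross_type {self.cross_type!r}; expected one of {CROSS_TYPES}")
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != self.genmap.n_markers:
            raise ValueError("genotype matrix must be n x (number of mapped markers)")
        legal = set(range(N_GENO[self.cross_type])) | {MISSING}
        observed = set(np.unique(self.genotypes).tolist())
        if not observed <= legal:
            raise ValueError(f"illegal genotype codes {sorted(observed - legal)} for cross_type {self.cross_type!r}")
        if self.phenotypes is not None:
            self.phenotypes = np.asarray(self.phenotypes, dtype=float)
            if self.phenotypes.shape[0] != self.genotypes.shape[0]:
                raise ValueError("phenotype row count must equal genotype row count")
            self.times = np.asarray(self.times, dtype=float)
            if self.times.size != self.phenotypes.shape[1]:
                raise ValueError("times length must equal phenotype column count")
        if not self.line_ids:
            self.line_ids = [f"L{i + 1}" for i in range(self.genotypes.shape[0])]

    @property
    def n_lines(self):
        return self.genotypes.shape[0]

    @property
    def n_geno(self):
        return N_GENO[self.cross_type]

    def with_phenotypes(self, phenotypes, times):
        return replace(self, phenotypes=np.asarray(phenotypes, float), times=np.asarray(times, float))


@dataclass
class GenoProb:
    """Posterior genotype probabilities on a marker + pseudomarker grid.

    grid : DataFrame-like records (chrom, pos_cM, is_pseudomarker), flattened
        across chromosomes in map order.
    probs : (n, G, S) array summing to 1 over the last axis.
    """

    cross_type: str
    chrom_names: list
    grid_chrom: np.ndarray  # (G,) int index into chrom_names
    grid_pos: np.ndarray  # (G,) cM
    is_pseudomarker: np.ndarray  # (G,) bool
    probs: np.ndarray  # (n, G, S)

    @property
    def n_positions(self):
        return self.grid_pos.size

    def chrom_slice(self, c):
        """Grid index slice for chromosome index or name ``c``."""
        if isinstance(c, str):
            c = self.chrom_names.index(c)
        idx = np.nonzero(self.grid_chrom == c)[0]
        return slice(idx[0], idx[-1] + 1)

    def locate(self, chrom, pos_cM, atol=1e-6):
        """Flat grid index of an exact (chrom, position); no silent snapping."""
        if isinstance(chrom, str):
            chrom = self.chrom_names.index(chrom)
        hit = np.nonzero((self.grid_chrom == chrom) & (np.abs(self.grid_pos - pos_cM) < atol))[0]
        if hit.size == 0:
            raise KeyError(
                f"position {pos_cM} cM on chromosome {self.chrom_names[chrom]!r} is not on the grid"
            )
        return int(hit[0])


def _transition_matrix(r, cross_type):
    """One-step transition matrix between adjacent loci at meiotic fraction r."""
    if cross_type == "ril_self":
        R = float(ril_self_recfrac(r))
        return np.array([[1 - R, R], [R, 1 - R]])
    # f2: two independent meioses
    r = float(r)
    return np.array(
        [
            [(1 - r) ** 2, 2 * r * (1 - r), r**2],
            [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
            [r**2, 2 * r * (1 - r), (1 - r) ** 2],
        ]
    )


def _init_probs(cross_type):
    if cross_type == "ril_self":
        return np.array([0.5, 0.5])
    return np.array([0.25, 0.5, 0.25])


def simulate_cross(genmap, n, cross_type, seed=None, rng=None):
    """Simulate genotypes for ``n`` lines of ``cross_type`` on ``genmap``.

    Chromosomes are independent; along each chromosome genotypes follow the
    no-interference Markov chain implied by the Haldane map (for f2, two
    independent haplotype chains are summed).  Phenotypes are left empty.
    """
    if cross_type not in CROSS_TYPES:
        raise ValueError(f"unknown cross_type {cross_type!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cols = []
    for chrom in genmap.chromosomes:
        d = np.diff(chrom.positions)
        r = haldane_recfrac(d)
        if cross_type == "ril_self":
            R = ril_self_recfrac(r)
            g = np.empty((n, chrom.positions.size), dtype=np.int8)
            g[:, 0] = rng.random(n) < 0.5
            for j in range(1, g.shape[1]):
                swap = rng.random(n) < R[j - 1]
                g[:, j] = np.where(swap, 1 - g[:, j - 1], g[:, j - 1])
            cols.append(g)
        else:
            haps = []
            for _ in range(2):
                h = np.empty((n, chrom.positions.size), dtype=np.int8)
                h[:, 0] = rng.random(n) < 0.5
                for j in range(1, h.shape[1]):
                    swap = rng.random(n) < r[j - 1]
                    h[:, j] = np.where(swap, 1 - h[:, j - 1], h[:, j - 1])
                haps.append(h)
            cols.append((haps[0] + haps[1]).astype(np.int8))
    return CrossData(cross_type, genmap, np.hstack(cols))


def _build_grid(positions, step):
    """Marker positions plus pseudomarkers every ``step`` cM; sorted, markers kept."""
    lo, hi = positions[0], positions[-1]
    extra = np.arange(lo, hi + 1e-9, step)
    # drop pseudo-positions that coincide with markers
    keep = np.ones(extra.size, dtype=bool)
    for j, p in enumerate(extra):
        if np.any(np.abs(positions - p) < 1e-6):
            keep[j] = False
    pseudo = extra[keep]
    grid = np.concatenate([positions, pseudo])
    is_pseudo = np.concatenate([np.zeros(positions.size, bool), np.ones(pseudo.size, bool)])
    order = np.argsort(grid, kind="stable")
    return grid[order], is_pseudo[order]


def calc_genoprob(cross, step=1.0, error_prob=1e-4):
    """Posterior genotype probabilities at markers and pseudomarkers.

    A forward-backward pass over the chain on each chromosome, with a
    symmetric genotyping-error emission (probability ``error_prob`` of
    observing each wrong class) at typed markers and flat emissions at
    missing genotypes and pseudomarkers.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if not (0 <= error_prob < 0.5):
        raise ValueError("error_prob must lie in [0, 0.5)")
    S = cross.n_geno
    n = cross.n_lines
    init = _init_probs(cross.cross_type)

    all_chrom_idx, all_pos, all_pseudo, all_probs = [], [], [], []
    m_off = 0
    for ci, chrom in enumerate(cross.genmap.chromosomes):
        M = chrom.positions.size
        obs = cross.genotypes[:, m_off : m_off + M]
        m_off += M
        grid, is_pseudo = _build_grid(chrom.positions, step)
        G = grid.size

        # emission probabilities (n, G, S)
        emit = np.ones((n, G, S))
        marker_slot = np.nonzero(~is_pseudo)[0]
        e_mat = np.full((S, S), error_prob / (S - 1))
        np.fill_diagonal(e_mat, 1.0 - error_prob)
        for k, gidx in enumerate(marker_slot):
            o = obs[:, k]
            typed = o != MISSING
            emit[typed, gidx, :] = e_mat[o[typed]]

        trans = [_transition_matrix(haldane_recfrac(grid[j + 1] - grid[j]), cross.cross_type) for j in range(G - 1)]

        # scaled forward-backward, vectorized over lines
        alpha = np.empty((n, G, S))
        a = init[None, :] * emit[:, 0, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0, :] = a
        for j in range(1, G):
            a = (a @ trans[j - 1]) * emit[:, j, :]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, j, :] = a
        beta = np.ones((n, S))
        post = np.empty((n, G, S))
        post[:, G - 1, :] = alpha[:, G - 1, :]
        for j in range(G - 2, -1, -1):
            beta = (beta * emit[:, j + 1, :]) @ trans[j].T
            beta /= beta.sum(axis=1, keepdims=True)
            p = alpha[:, j, :] * beta
            post[:, j, :] = p / p.sum(axis=1, keepdims=True)

        all_chrom_idx.append(np.full(G, ci))
        all_pos.append(grid)
        all_pseudo.append(is_pseudo)
        all_probs.append(post)

    return GenoProb(
        cross_type=cross.cross_type,
        chrom_names=[c.name for c in cross.genmap.chromosomes],
        grid_chrom=np.concatenate(all_chrom_idx),
        grid_pos=np.concatenate(all_pos),
        is_pseudomarker=np.concatenate(all_pseudo),
        probs=np.concatenate(all_probs, axis=1),
    )
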