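import numpy as np
import pytest

import curveqtl as cq


@pytest.fixture(scope="session")
def ril_cross_with_qtl():
    """RIL cross on two chromosomes with a strong QTL at C1@60 driving the
    slope of otherwise-linear trait curves."""
    gm = cq.GeneticMap.uniform(2, 100, 20)
    cross = cq.simulate_cross(gm, 150, "ril_self", seed=1)
    rng = np.random.default_rng(0)
    t = np.linspace(0, 1, 25)
    d = 2.0 * cross.genotypes[:, 3] - 1.0  # C1@60
    Y = np.outer(5 + d, t) + 2.0 + 0.3 * rng.standard_normal((150, 25))
    return cross.with_phenotypes(Y, t)


@pytest.fixture(scope="session")
def ril_probs(ril_cross_with_qtl):
    return cq.calc_genoprob(ril_cross_with_qtl, step=5.0, error_prob=0.0)


@pytest.fixture(scope="session")
def ril_smooth(ril_cross_with_qtl):
    cross = ril_cross_with_qtl
    basis = cq.build_basis(cross.times, 6)
    return cq.fit_smooth(cross.phenotypes, cross.times, basis)


@pytest.fixture(scope="session")
def ril_fpca(ril_smooth):
    W = cq.gram_matrix(ril_smooth.basis)
    return cq.functional_pca(ril_smooth, W, var_threshold=0.999)


@pytest.fixture(scope="session")
def ril_scores(ril_fpca):
    return ril_fpca.scores


@pytest.fixture(scope="session")
def f2_cross_with_qtl():
    """The logistic single-QTL intercross design at its printed settings."""
    cross, qtl_geno = cq.simulate_single_qtl_dataset(200, seed=11)
    return cross, qtl_geno


def dense_lod_oracle(X, y):
    """(n/2) log10(RSS0/RSS) by an explicit QR solve; independent of scan.py."""
    n = y.shape[0]
    rss0 = float(np.sum((y - y.mean()) ** 2))
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    rss = float(np.sum((y - X @ beta) ** 2))
    return 0.5 * n * np.log10(rss0 / max(rss, 1e-12 * rss0))
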