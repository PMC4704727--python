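"""Haley-Knott scan statistics: per-trait LOD, SL/ML, HKLOD, SLOD/MLOD."""

import numpy as np
import pytest

import curveqtl as cq
from curveqtl.scan import joint_scan

from conftest import dense_lod_oracle


@pytest.fixture(scope="module")
def traits(ril_probs):
    rng = np.random.default_rng(17)
    n = ril_probs.probs.shape[0]
    d = ril_probs.probs[:, ril_probs.locate(0, 60.0), 1] * 2 - 1
    Z = rng.standard_normal((n, 3))
    Z[:, 0] += 0.8 * d
    return Z


class TestHKDesign:
    def test_ril_typed_marker_gives_plus_minus_one(self, ril_cross_with_qtl, ril_probs):
        design = cq.hk_design(ril_probs, 0, 60.0)
        expected = 2.0 * ril_cross_with_qtl.genotypes[:, 3] - 1.0
        assert np.allclose(design.X[:, 1], expected)
        assert np.all(design.X[:, 0] == 1.0)

    def test_uninformative_position_gives_zero_dosage(self):
        gm = cq.GeneticMap.uniform(1, 40, 20)
        geno = np.full((10, 3), cq.MISSING, dtype=np.int8)
        cross = cq.CrossData("ril_self", gm, geno)
        probs = cq.calc_genoprob(cross, step=10.0)
        design = cq.hk_design(probs, 0, 20.0)
        assert np.allclose(design.X[:, 1], 0.0)
        assert np.linalg.matrix_rank(design.X) == 1

    def test_f2_typed_marker_matches_one_hot_contrasts(self, f2_cross_with_qtl):
        cross, _ = f2_cross_with_qtl
        probs = cq.calc_genoprob(cross, step=1000.0, error_prob=0.0)
        design = cq.hk_design(probs, 0, 20.0, model="add+dom")
        g = cross.genotypes[:, 1]
        onehot = np.eye(3)[g]
        assert np.allclose(design.X[:, 1], onehot[:, 2] - onehot[:, 0])
        assert np.allclose(design.X[:, 2], onehot[:, 1])

    def test_off_grid_position_rejected(self, ril_probs):
        with pytest.raises(KeyError):
            cq.hk_design(ril_probs, 0, 33.33)


class TestTraitLod:
    def test_matches_dense_least_squares_oracle(self, ril_probs, traits):
        lod = cq.trait_lod_scan(ril_probs, traits)
        for g in range(0, ril_probs.n_positions, 3):
            X = np.column_stack([np.ones(traits.shape[0]), ril_probs.probs[:, g, 1] - ril_probs.probs[:, g, 0]])
            for j in range(traits.shape[1]):
                assert abs(lod[g, j] - dense_lod_oracle(X, traits[:, j])) < 1e-8

    def test_perfect_fit_is_capped_at_marker(self, ril_probs):
        d = ril_probs.probs[:, ril_probs.locate(0, 60.0), 1] * 2 - 1
        lod = cq.trait_lod_scan(ril_probs, d[:, None])
        g_star = np.argmax(lod[:, 0])
        assert ril_probs.grid_pos[g_star] == 60.0 and ril_probs.grid_chrom[g_star] == 0
        n = d.size
        assert lod[g_star, 0] >= 0.5 * n * np.log10(1e11)

    def test_constant_trait_warns_and_zeroes(self, ril_probs):
        Z = np.ones((ril_probs.probs.shape[0], 1))
        with pytest.warns(UserWarning, match="constant"):
            lod = cq.trait_lod_scan(ril_probs, Z)
        assert np.all(lod == 0.0)

    def test_missing_traits_rejected(self, ril_probs):
        Z = np.ones((ril_probs.probs.shape[0], 2))
        Z[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cq.trait_lod_scan(ril_probs, Z)

    def test_affine_invariance(self, ril_probs, traits):
        base = cq.trait_lod_scan(ril_probs, traits)
        scaled = cq.trait_lod_scan(ril_probs, traits * 3.7 - 11.0)
        assert np.max(np.abs(base - scaled)) < 1e-8

    def test_hk_equals_exact_marker_regression_when_fully_typed(
        self, ril_cross_with_qtl, ril_probs, traits
    ):
        """At a typed marker the HK design spans the genotype-class space."""
        g_idx = ril_probs.locate(1, 40.0)
        lod = cq.trait_lod_scan(ril_probs, traits)[g_idx]
        classes = np.eye(2)[ril_cross_with_qtl.genotypes[:, 8]]  # C2@40
        for j in range(traits.shape[1]):
            assert abs(lod[j] - dense_lod_oracle(classes, traits[:, j])) < 1e-10


class TestCombine:
    def test_single_trait_sl_equals_ml(self, ril_probs, traits):
        lod = cq.trait_lod_scan(ril_probs, traits[:, :1])
        sl, ml = cq.combine_sl_ml(lod)
        assert np.array_equal(sl, ml)
        assert np.array_equal(sl, lod[:, 0])

    def test_arithmetic(self):
        sl, ml = cq.combine_sl_ml(np.array([[2.0, 4.0]]))
        assert sl[0] == 3.0 and ml[0] == 4.0

    def test_sl_below_ml(self, ril_probs, traits):
        sl, ml = cq.combine_sl_ml(cq.trait_lod_scan(ril_probs, traits))
        assert np.all(sl <= ml + 1e-12)


class TestHKLOD:
    def test_single_trait_equals_per_trait_lod(self, ril_probs, traits):
        lod = cq.trait_lod_scan(ril_probs, traits[:, :1])
        hk = cq.hklod_scan(ril_probs, traits[:, :1])
        assert np.max(np.abs(hk - lod[:, 0])) < 1e-8

    def test_orthogonal_traits_give_zero(self, ril_probs):
        """Traits residualized against every dosage column have HKLOD 0."""
        rng = np.random.default_rng(3)
        n = ril_probs.probs.shape[0]
        D = ril_probs.probs[:, :, 1] - ril_probs.probs[:, :, 0]
        Q = np.column_stack([np.ones(n), D])
        Z = rng.standard_normal((n, 2))
        Qo, _ = np.linalg.qr(Q)
        Z -= Qo @ (Qo.T @ Z)
        hk = cq.hklod_scan(ril_probs, Z)
        assert np.max(np.abs(hk)) < 1e-8

    def test_matches_brute_force_determinants(self):
        rng = np.random.default_rng(8)
        gm = cq.GeneticMap((cq.Chromosome("1", ("m1",), np.array([0.0])),))
        geno = rng.integers(0, 2, size=(12, 1)).astype(np.int8)
        cross = cq.CrossData("ril_self", gm, geno)
        probs = cq.calc_genoprob(cross, step=10.0, error_prob=0.0)
        Z = rng.standard_normal((12, 2))
        hk = cq.hklod_scan(probs, Z)
        X = np.column_stack([np.ones(12), 2.0 * geno[:, 0] - 1.0])
        B = np.linalg.lstsq(X, Z, rcond=None)[0]
        R1 = Z - X @ B
        Zc = Z - Z.mean(0)
        expected = (12 / 2) * np.log10(np.linalg.det(Zc.T @ Zc) / np.linalg.det(R1.T @ R1))
        assert abs(hk[0] - expected) < 1e-10

    def test_rotation_invariance(self, ril_probs, traits):
        rng = np.random.default_rng(21)
        Q, _ = np.linalg.qr(rng.standard_normal((traits.shape[1],) * 2))
        a = cq.hklod_scan(ril_probs, traits)
        b = cq.hklod_scan(ril_probs, traits @ Q)
        assert np.max(np.abs(a - b)) < 1e-8

    def test_too_many_traits_rejected(self, ril_probs):
        n = ril_probs.probs.shape[0]
        Z = np.random.default_rng(0).standard_normal((n, n - 1))
        with pytest.raises(ValueError, match="variance threshold"):
            cq.hklod_scan(ril_probs, Z)


class TestRawSlodMlod:
    def test_single_time_point_degenerate(self, ril_probs, traits):
        slod, mlod = cq.raw_slod_mlod_scan(ril_probs, traits[:, :1])
        assert np.array_equal(slod, mlod)

    def test_identical_time_points_collapse(self, ril_probs, traits):
        Y = np.repeat(traits[:, :1], 5, axis=1)
        slod, mlod = cq.raw_slod_mlod_scan(ril_probs, Y)
        assert np.max(np.abs(slod - mlod)) < 1e-12

    def test_slod_below_mlod(self, ril_probs, traits):
        slod, mlod = cq.raw_slod_mlod_scan(ril_probs, traits)
        assert np.all(slod <= mlod + 1e-12)


class TestScanResult:
    def test_scan_genome_bundles_consistent_statistics(self, ril_probs, traits):
        sr = cq.scan_genome(ril_probs, Z=traits, smoothed=traits, methods=("sl", "ml", "hklod", "slod", "mlod"))
        sl, ml = cq.combine_sl_ml(sr.per_trait_lod)
        assert np.max(np.abs(sr.sl - sl)) < 1e-10
        assert np.max(np.abs(sr.ml - ml)) < 1e-10
        assert all(getattr(sr, m) is not None for m in ("hklod", "slod", "mlod"))
        df = sr.to_frame()
        assert {"chrom", "pos_cM", "sl", "ml", "hklod"} <= set(df.columns)

    def test_argmax_recovers_simulated_qtl(self, ril_probs, traits):
        chrom, pos, _ = cq.scan_genome(ril_probs, Z=traits, methods=("sl",)).argmax("sl")
        assert chrom == "C1" and abs(pos - 60.0) <= 10.0


class TestLocalization:
    def test_high_heritability_peaks_near_truth(self):
        """With a strong single QTL (mean heritability near 0.3, n=400) every
        statistic's genome-wide argmax lands within 5 cM of the true QTL in
        at least 95% of replicates."""
        from curveqtl.simulate import CovarianceSpec, simulate_single_qtl_dataset

        cov = CovarianceSpec("autoregressive", 3.0, 0.6, c=0.2)
        hits = {m: 0 for m in ("sl", "ml", "hklod")}
        n_reps = 100
        for rep in range(n_reps):
            cross, _ = simulate_single_qtl_dataset(400, cov_spec=cov, seed=10_000 + rep)
            basis = cq.build_basis(cross.times, 5)
            fit = cq.fit_smooth(cross.phenotypes, cross.times, basis)
            res = cq.functional_pca(fit, cq.gram_matrix(basis))
            probs = cq.calc_genoprob(cross, step=1.0)
            sr = cq.scan_genome(probs, Z=res.scores, methods=("sl", "ml", "hklod"))
            for m in hits:
                _, pos, _ = sr.argmax(m)
                hits[m] += abs(pos - 32.0) <= 5.0
        for m, h in hits.items():
            assert h >= 95, f"{m}: {h}/{n_reps} within 5 cM"
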