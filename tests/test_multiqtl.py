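"""Multiple-QTL model fits, stepwise search, profiles, and effect curves."""

import numpy as np
import pytest

import curveqtl as cq


@pytest.fixture(scope="module")
def two_qtl_setup():
    """RIL cross with two unlinked additive QTL of known effect."""
    gm = cq.GeneticMap.uniform(2, 100, 20)
    cross = cq.simulate_cross(gm, 400, "ril_self", seed=31)
    rng = np.random.default_rng(31)
    d1 = 2.0 * cross.genotypes[:, 2] - 1.0  # C1@40
    d2 = 2.0 * cross.genotypes[:, 9] - 1.0  # C2@60
    Z = rng.standard_normal((400, 2))
    Z[:, 0] += 1.0 * d1 + 0.6 * d2
    Z[:, 1] += 0.5 * d1 - 0.8 * d2
    probs = cq.calc_genoprob(cross, step=2.0, error_prob=0.0)
    return probs, Z, (d1, d2)


class TestFitModel:
    def test_empty_model_has_zero_lod(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        for stat in ("sl", "ml", "hklod"):
            assert cq.fit_model(probs, Z, [], stat).joint_lod == 0.0

    @pytest.mark.parametrize("stat", ["sl", "ml", "hklod"])
    def test_single_position_equals_scan(self, two_qtl_setup, stat):
        probs, Z, _ = two_qtl_setup
        sr = cq.scan_genome(probs, Z=Z, methods=(stat,))
        g = probs.locate("C1", 40.0)
        fit = cq.fit_model(probs, Z, [("C1", 40.0)], stat)
        assert abs(fit.joint_lod - sr.statistic(stat)[g]) < 1e-10

    def test_duplicate_positions_rejected(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        with pytest.raises(ValueError, match="collinear"):
            cq.fit_model(probs, Z, [("C1", 40.0), ("C1", 40.0)], "sl")

    def test_order_invariance(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        a = cq.fit_model(probs, Z, [("C1", 40.0), ("C2", 60.0)], "hklod")
        b = cq.fit_model(probs, Z, [("C2", 60.0), ("C1", 40.0)], "hklod")
        assert abs(a.joint_lod - b.joint_lod) < 1e-10

    def test_two_qtl_joint_exceeds_singles_and_recovers_effects(self, two_qtl_setup):
        probs, Z, (d1, d2) = two_qtl_setup
        joint = cq.fit_model(probs, Z, [("C1", 40.0), ("C2", 60.0)], "sl")
        s1 = cq.fit_model(probs, Z, [("C1", 40.0)], "sl").joint_lod
        s2 = cq.fit_model(probs, Z, [("C2", 60.0)], "sl").joint_lod
        assert joint.joint_lod > max(s1, s2)
        # coefficient rows: intercept, d1, d2; compare with the simulated effects
        Q = joint.design_Q
        resid = Z - Q @ joint.effects_beta
        sigma2 = (resid**2).sum(axis=0) / (Q.shape[0] - Q.shape[1])
        se = np.sqrt(np.outer(np.diag(np.linalg.inv(Q.T @ Q)), sigma2))
        truth = np.array([[0.0, 0.0], [1.0, 0.5], [0.6, -0.8]])
        assert np.all(np.abs(joint.effects_beta - truth) <= 3 * se + 1e-9)


class TestStepwise:
    def test_huge_penalty_returns_null(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        fit = cq.stepwise_search(probs, Z, "sl", penalty_T=1e6, max_qtl=3)
        assert fit.n_qtl == 0 and fit.plod == 0.0

    def test_tiny_penalty_single_qtl_matches_scan_argmax(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        sr = cq.scan_genome(probs, Z=Z, methods=("sl",))
        chrom, pos, _ = sr.argmax("sl")
        fit = cq.stepwise_search(probs, Z, "sl", penalty_T=1e-9, max_qtl=1, refine=False)
        assert fit.qtl == [(chrom, pos)]

    def test_recovers_both_qtl(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        fit = cq.stepwise_search(probs, Z, "sl", penalty_T=2.5, max_qtl=5)
        assert fit.n_qtl == 2
        found = {q[0]: q[1] for q in fit.qtl}
        assert abs(found["C1"] - 40.0) <= 10.0
        assert abs(found["C2"] - 60.0) <= 10.0

    def test_returned_plod_dominates_search_log(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        fit = cq.stepwise_search(probs, Z, "ml", penalty_T=2.5, max_qtl=4)
        assert fit.plod >= max(e["plod"] for e in fit.search_log) - 1e-9
        assert fit.plod >= 0.0

    def test_min_separation_enforced(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        fit = cq.stepwise_search(probs, Z, "sl", penalty_T=0.5, max_qtl=8, min_sep=10.0)
        by_chrom = {}
        for c, p in fit.qtl:
            by_chrom.setdefault(c, []).append(p)
        for pos in by_chrom.values():
            pos = sorted(pos)
            assert all(b - a >= 10.0 for a, b in zip(pos, pos[1:]))

    def test_invalid_arguments_rejected(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        with pytest.raises(ValueError, match="max_qtl"):
            cq.stepwise_search(probs, Z, "sl", penalty_T=1.0, max_qtl=0)
        with pytest.raises(ValueError, match="penalty"):
            cq.stepwise_search(probs, Z, "sl", penalty_T=0.0)


class TestProfiles:
    @pytest.mark.parametrize("stat", ["sl", "ml", "hklod"])
    def test_single_qtl_profile_equals_scan_curve(self, two_qtl_setup, stat):
        probs, Z, _ = two_qtl_setup
        fit = cq.fit_model(probs, Z, [("C1", 40.0)], stat)
        prof = cq.profile_lod(fit, probs, Z)
        sr = cq.scan_genome(probs, Z=Z, methods=(stat,))
        sel = probs.chrom_slice("C1")
        assert np.max(np.abs(prof.curves[0] - sr.statistic(stat)[sel])) < 1e-10

    def test_profile_at_fitted_position_is_lod_drop(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        positions = [("C1", 40.0), ("C2", 60.0)]
        fit = cq.fit_model(probs, Z, positions, "sl")
        prof = cq.profile_lod(fit, probs, Z)
        for k, (chrom, pos) in enumerate(positions):
            reduced = cq.fit_model(probs, Z, positions[:k] + positions[k + 1 :], "sl")
            at = np.nonzero(np.abs(prof.pos_cM[k] - pos) < 1e-9)[0][0]
            assert abs(prof.curves[k][at] - (fit.joint_lod - reduced.joint_lod)) < 1e-10

    def test_profiles_peak_at_refined_positions(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        fit = cq.stepwise_search(probs, Z, "sl", penalty_T=2.5, max_qtl=3)
        prof = cq.profile_lod(fit, probs, Z)
        for k, (chrom, pos) in enumerate(fit.qtl):
            peak = prof.pos_cM[k][np.argmax(prof.curves[k])]
            assert peak == pos

    def test_linked_qtl_profiles_separate(self):
        """Two QTL 40 cM apart: each profile peaks within 10 cM of its own
        QTL in the overwhelming majority of replicates (n=400)."""
        gm = cq.GeneticMap.uniform(1, 100, 10)
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            cross = cq.simulate_cross(gm, 400, "ril_self", seed=5000 + rep)
            rng = np.random.default_rng(5000 + rep)
            d1 = 2.0 * cross.genotypes[:, 3] - 1.0  # 30 cM
            d2 = 2.0 * cross.genotypes[:, 7] - 1.0  # 70 cM
            Z = rng.standard_normal((400, 2))
            Z[:, 0] += 0.8 * d1 + 0.8 * d2
            Z[:, 1] += 0.4 * d1 - 0.4 * d2
            probs = cq.calc_genoprob(cross, step=2.0, error_prob=0.0)
            fit = cq.fit_model(probs, Z, [("C1", 30.0), ("C1", 70.0)], "sl")
            prof = cq.profile_lod(fit, probs, Z)
            p1 = prof.pos_cM[0][np.argmax(prof.curves[0])]
            p2 = prof.pos_cM[1][np.argmax(prof.curves[1])]
            hits += (abs(p1 - 30.0) <= 10.0) and (abs(p2 - 70.0) <= 10.0)
        assert hits >= 85, f"{hits}/{n_reps}"

    def test_profile_requires_qtl(self, two_qtl_setup):
        probs, Z, _ = two_qtl_setup
        fit = cq.fit_model(probs, Z, [], "sl")
        with pytest.raises(ValueError, match="at least one"):
            cq.profile_lod(fit, probs, Z)


class TestEffects:
    def test_zero_coefficients_give_flat_curves(self, ril_fpca, ril_probs):
        import dataclasses

        fit = cq.fit_model(ril_probs, ril_fpca.scores, [("C1", 60.0)], "sl")
        zeroed = dataclasses.replace(fit, effects_beta=np.zeros_like(fit.effects_beta))
        eff = cq.effects_to_time_domain(zeroed, ril_fpca, "ril_self")
        assert np.allclose(eff.effects, 0.0)

    def test_dimension_mismatch_rejected(self, ril_fpca, ril_probs):
        import dataclasses

        fit = cq.fit_model(ril_probs, ril_fpca.scores, [("C1", 60.0)], "sl")
        bad = dataclasses.replace(fit, effects_beta=fit.effects_beta[:, :-1])
        with pytest.raises(ValueError, match="do not match"):
            cq.effects_to_time_domain(bad, ril_fpca, "ril_self")

    def test_recovers_linear_effect_curve(self, ril_cross_with_qtl, ril_probs, ril_smooth, ril_fpca):
        """The simulated high-low contrast is 2t; the recovered curve should
        track it closely over the interior of the time domain."""
        cross = ril_cross_with_qtl
        fit = cq.fit_model(ril_probs, ril_fpca.scores, [("C1", 60.0)], "sl")
        eff = cq.effects_to_time_domain(fit, ril_fpca, "ril_self", times=cross.times)
        truth = 2.0 * cross.times
        assert np.max(np.abs(eff.effects[0] - truth)) < 0.2

    def test_baseline_tracks_mean_smoothed_curve(self, ril_probs, ril_smooth, ril_fpca):
        fit = cq.fit_model(ril_probs, ril_fpca.scores, [("C1", 60.0)], "sl")
        eff = cq.effects_to_time_domain(fit, ril_fpca, "ril_self")
        mean_curve = ril_smooth.fitted.mean(axis=0)
        resid_sd = ril_smooth.residuals.std()
        assert np.max(np.abs(eff.baseline - mean_curve)) < 2 * resid_sd
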