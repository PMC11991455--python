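"""Power means, the means field, and robust (trimmed) estimation."""

import numpy as np
import pytest

from meansfield.means import (
    DEFAULT_H_VALUES,
    FieldConfig,
    RobustConfig,
    arithmetic_mean,
    compute_means_field,
    geometric_mean,
    harmonic_mean,
    power_mean,
    robust_mean,
    robust_means_field,
    standardized_distances,
)
from meansfield.spd import TrialCovarianceSet, airm_distance, geodesic_point

from conftest import random_spd, random_spd_set


def spd_set(*mats, weights=None, labels=None):
    return TrialCovarianceSet(np.stack([np.asarray(m, float) for m in mats]),
                              labels=labels, weights=weights)


class TestClosedFormMeans:
    def test_arithmetic_examples(self):
        assert np.allclose(arithmetic_mean(spd_set(np.diag([2.0, 3.0]))), np.diag([2.0, 3.0]))
        assert np.allclose(
            arithmetic_mean(spd_set(np.eye(2), np.diag([3.0, 5.0]))), np.diag([2.0, 3.0])
        )
        assert np.allclose(
            arithmetic_mean(spd_set(np.eye(2), 3 * np.eye(2), weights=[0.25, 0.75])),
            2.5 * np.eye(2),
        )

    def test_harmonic_examples(self):
        C = random_spd(np.random.default_rng(0), 3)
        assert np.allclose(harmonic_mean(spd_set(C)), C, atol=1e-10)
        # scalar harmonic mean 2/(1 + 1/3) = 1.5 on the first axis
        assert np.allclose(
            harmonic_mean(spd_set(np.diag([1.0, 1.0]), np.diag([3.0, 1.0]))),
            np.diag([1.5, 1.0]),
        )

    def test_harmonic_below_arithmetic_loewner(self, rng):
        s = random_spd_set(rng, 6, 4)
        diff = arithmetic_mean(s) - harmonic_mean(s)
        assert np.linalg.eigvalsh(diff)[0] >= -1e-8


class TestGeometricMean:
    def test_identical_matrices(self, rng):
        C = random_spd(rng, 4)
        assert np.allclose(geometric_mean(spd_set(C, C, C)), C, atol=1e-6)

    def test_two_matrix_closed_form_is_geodesic_midpoint(self, rng):
        A, B = random_spd(rng, 4), random_spd(rng, 4)
        G = geometric_mean(spd_set(A, B))
        assert airm_distance(G, geodesic_point(A, B, 0.5)) < 1e-6

    def test_commuting_elementwise(self):
        G = geometric_mean(spd_set(np.diag([1.0, 2.0]), np.diag([4.0, 8.0])))
        assert np.allclose(G, np.diag([2.0, 4.0]), atol=1e-6)

    def test_karcher_equation_residual(self, rng):
        from meansfield.spd import sym_invsqrtm, sym_logm

        s = random_spd_set(rng, 8, 5, weights=True)
        G = geometric_mean(s)
        Gih = sym_invsqrtm(G)
        w = s.normalized_weights()
        grad = sum(wk * sym_logm(Gih @ C @ Gih) for wk, C in zip(w, s.matrices))
        assert np.linalg.norm(grad) / np.sqrt(5) < 10 * FieldConfig().tolerance

    def test_initialization_independence(self, rng):
        s = random_spd_set(rng, 6, 4)
        G1 = geometric_mean(s)
        G2 = geometric_mean(s, init=np.eye(4))
        assert airm_distance(G1, G2) < 1e-5

    def test_congruence_equivariance(self, rng):
        s = random_spd_set(rng, 5, 4)
        F = rng.normal(size=(4, 4)) + np.eye(4)
        G = geometric_mean(s)
        mapped = TrialCovarianceSet(
            np.stack([F @ C @ F.T for C in s.matrices]), weights=s.weights
        )
        assert airm_distance(geometric_mean(mapped), F @ G @ F.T) < 1e-6


class TestPowerMean:
    def test_endpoints_match_closed_forms(self, rng):
        s = random_spd_set(rng, 6, 4, weights=True)
        assert np.allclose(power_mean(s, 1.0), arithmetic_mean(s), rtol=1e-6)
        assert np.allclose(power_mean(s, -1.0), harmonic_mean(s), rtol=1e-6)

    def test_scalar_reduction_example(self):
        s = spd_set([[1.0]], [[16.0]])
        # scalar power mean ((1 + 16^0.5)/2)^{1/0.5} = 6.25
        P = power_mean(s, 0.5, FieldConfig(tolerance=1e-12))
        assert P[0, 0] == pytest.approx(6.25, abs=1e-9)

    @pytest.mark.parametrize("h", [h for h in DEFAULT_H_VALUES if h != 0])
    def test_scalar_reduction_all_default_h(self, h):
        g = np.random.default_rng(5)
        c = g.uniform(0.5, 4.0, size=5)
        w = g.uniform(0.5, 2.0, size=5)
        s = TrialCovarianceSet(c.reshape(-1, 1, 1), weights=w)
        expected = (np.sum((w / w.sum()) * c**h)) ** (1.0 / h)
        P = power_mean(s, h, FieldConfig(tolerance=1e-13))
        assert P[0, 0] == pytest.approx(expected, abs=1e-10, rel=1e-10)

    def test_duality(self, rng):
        s = random_spd_set(rng, 5, 3)
        inv = TrialCovarianceSet(
            np.stack([np.linalg.inv(C) for C in s.matrices]), weights=s.weights
        )
        lhs = power_mean(s, -0.5)
        rhs = np.linalg.inv(power_mean(inv, 0.5))
        assert airm_distance(lhs, rhs) < 1e-7

    def test_fixed_point_residual(self, rng):
        s = random_spd_set(rng, 7, 4, weights=True)
        cfg = FieldConfig()
        for h in (0.25, 0.75):
            P = power_mean(s, h, cfg)
            w = s.normalized_weights()
            rhs = sum(wk * geodesic_point(P, C, h) for wk, C in zip(w, s.matrices))
            rel = np.linalg.norm(P - rhs) / np.linalg.norm(P)
            assert rel < 10 * cfg.tolerance

    def test_limit_continuity_toward_geometric(self, rng):
        s = random_spd_set(rng, 6, 4)
        G = geometric_mean(s)
        scale = airm_distance(harmonic_mean(s), arithmetic_mean(s))
        for h in (0.01, -0.01):
            assert airm_distance(power_mean(s, h), G) < 0.01 * scale

    def test_loewner_ordering_endpoints(self, rng):
        s = random_spd_set(rng, 6, 4)
        H, G, A = harmonic_mean(s), geometric_mean(s), arithmetic_mean(s)
        assert np.linalg.eigvalsh(G - H)[0] >= -1e-8
        assert np.linalg.eigvalsh(A - G)[0] >= -1e-8

    def test_h_out_of_range(self, rng):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            power_mean(random_spd_set(rng, 3, 3), 1.5)

    def test_permutation_invariance(self, rng):
        s = random_spd_set(rng, 6, 3)
        perm = rng.permutation(6)
        shuffled = TrialCovarianceSet(s.matrices[perm], weights=s.weights[perm])
        for h in (0.5, -0.25, 0.0):
            assert np.allclose(power_mean(s, h), power_mean(shuffled, h), atol=1e-9)


class TestMeansField:
    def test_identical_matrices_single_class(self, rng):
        C = random_spd(rng, 3)
        s = TrialCovarianceSet(np.stack([C] * 4), labels=[0] * 4)
        fld = compute_means_field(s)
        assert len(fld.means) == 11
        for h in fld.h_values:
            assert airm_distance(fld.means[(0, h)], C) < 1e-5

    def test_two_class_default_has_eleven_means_per_class(self, rng):
        s = random_spd_set(rng, 8, 3)
        s.labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fld = compute_means_field(s)
        assert fld.h_values == tuple(sorted(DEFAULT_H_VALUES))
        for cls in (0, 1):
            assert sum(1 for k in fld.means if k[0] == cls) == 11

    def test_warm_start_matches_cold_start(self, rng):
        s = random_spd_set(rng, 8, 4)
        s.labels = np.zeros(8, dtype=int)
        fld = compute_means_field(s)
        cfg = FieldConfig()
        for h in DEFAULT_H_VALUES:
            cold = power_mean(TrialCovarianceSet(s.matrices), h, cfg, init=np.eye(4))
            assert airm_distance(fld.means[(0, h)], cold) < 1e-5

    def test_diagnostics_recorded(self, rng):
        s = random_spd_set(rng, 6, 3)
        s.labels = np.array([0, 0, 0, 1, 1, 1])
        fld = compute_means_field(s)
        assert set(fld.diagnostics) == set(fld.means)
        its, res = fld.diagnostics[(0, 0.5)]
        assert its >= 1 and res < FieldConfig().tolerance

    def test_empty_class_rejected(self, rng):
        s = random_spd_set(rng, 4, 3)
        with pytest.raises(ValueError):
            compute_means_field(s)  # no labels at all


class TestStandardizedDistances:
    def test_equidistant_gives_zeros(self):
        # all trials at the same distance from the center -> degenerate sd
        mats = [np.diag([2.0, 1.0]), np.diag([0.5, 1.0]), np.diag([1.0, 2.0])]
        z = standardized_distances(spd_set(*mats), np.eye(2))
        assert np.allclose(z, 0.0)

    def test_direct_arithmetic(self):
        # distances (1,1,1,5) from I: z4 = (5-2)/sd, sd over n-1=3 -> sd=2
        mats = [np.exp(d) * np.eye(1) for d in (1.0, 1.0, 1.0, 5.0)]
        z = standardized_distances(spd_set(*mats), np.eye(1))
        assert z[3] == pytest.approx(1.5, rel=1e-10)
        assert z.sum() == pytest.approx(0.0, abs=1e-10)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            standardized_distances(spd_set(np.eye(2)), np.eye(2))


class TestRobustMean:
    def test_clean_cloud_identical_to_plain(self, rng):
        from meansfield.synthetic import sample_spd_cloud

        s = sample_spd_cloud(np.eye(3), 0.1, 20, seed=3)
        mean, keep = robust_mean(s, 0.0)
        assert len(keep) >= 18  # a tight cloud loses at most a stray tail trial
        plain = geometric_mean(s.subset(keep))
        assert airm_distance(mean, plain) < 1e-6

    def test_planted_outlier_removed(self):
        from meansfield.synthetic import sample_spd_cloud

        s = sample_spd_cloud(np.eye(3), 0.1, 20, seed=11)
        mats = np.concatenate([s.matrices, [1e4 * np.eye(3)]])
        full = TrialCovarianceSet(mats)
        robust, keep = robust_mean(full, 0.0)
        assert 20 not in keep
        plain = geometric_mean(full)
        assert airm_distance(robust, np.eye(3)) < airm_distance(plain, np.eye(3))

    def test_single_refinement_removes_one_batch(self):
        from meansfield.synthetic import sample_spd_cloud

        s = sample_spd_cloud(np.eye(3), 0.1, 15, seed=2)
        mats = np.concatenate([s.matrices, [1e3 * np.eye(3)], [1e6 * np.eye(3)]])
        full = TrialCovarianceSet(mats)
        rcfg = RobustConfig(max_refinements=1)
        _, keep = robust_mean(full, 0.0, rcfg=rcfg)
        _, keep_full = robust_mean(full, 0.0, rcfg=RobustConfig(max_refinements=4))
        assert len(keep) >= len(keep_full)

    def test_min_retained_guard(self):
        mats = [np.eye(2), 100.0 * np.eye(2), 0.01 * np.eye(2)]
        _, keep = robust_mean(spd_set(*mats), 0.0, rcfg=RobustConfig(min_retained=3))
        assert len(keep) == 3  # removal would breach the floor -> skipped


class TestRobustMeansField:
    def test_outlier_free_equals_plain_field(self, rng):
        s = random_spd_set(rng, 8, 3)
        s = TrialCovarianceSet(s.matrices, labels=np.array([0] * 4 + [1] * 4))
        plain = compute_means_field(s)
        robust = robust_means_field(s)
        if all(len(robust.retained[c]) == 4 for c in (0, 1)):
            for key in plain.means:
                assert np.allclose(plain.means[key], robust.means[key], atol=1e-12)

    def test_equivalence_with_manual_cleaning(self):
        from meansfield.synthetic import sample_spd_cloud

        rng = np.random.default_rng(9)
        blocks, labels = [], []
        for cls in (0, 1):
            clean = sample_spd_cloud(np.eye(3), 0.1, 15, seed=cls)
            blocks += [clean.matrices, [1e4 * np.eye(3)]]
            labels += [cls] * 16
        s = TrialCovarianceSet(np.concatenate(blocks), labels=np.array(labels))
        robust = robust_means_field(s)
        # per-class screening must never mix classes
        for cls in (0, 1):
            assert set(robust.retained[cls]) <= set(range(16))
        cleaned_idx = [i for cls in (0, 1) for i in np.flatnonzero(s.labels == cls)[robust.retained[cls]]]
        manual = compute_means_field(s.subset(cleaned_idx))
        for key in robust.means:
            assert airm_distance(robust.means[key], manual.means[key]) < 1e-9
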