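import copy

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.stats import ortho_group

from reachkdi.config import CoreConfig
from reachkdi.core import (
    build_reference,
    embed_trial,
    gpa_consensus,
    procrustes_rotation,
    score_trial,
)
from reachkdi.errors import (
    DegenerateGeometryError,
    DimensionalityError,
    ReferenceUnavailableError,
    SchemaError,
)
from reachkdi.preprocessing import NormalizedTrial
from reachkdi.synthetic import PerturbationSpec
from conftest import make_normalized


def _nt(matrix, names=None, trial_id="t", animal_id="a"):
    p = matrix.shape[1]
    return NormalizedTrial(
        matrix=matrix,
        variable_names=names or [f"v{j}" for j in range(p)],
        trial_id=trial_id, animal_id=animal_id,
        condition="baseline", endpoint="success",
        original_n_frames=matrix.shape[0],
    )


class TestEmbedTrial:
    def test_correlated_columns_dominate_first_component(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 100)
        X = np.column_stack([t, 2 * t, rng.normal(0, 0.01, 100)])
        emb = embed_trial(_nt(X), n_components=3, scaling="center_only")
        assert emb.explained_variance[0] > 0.9
        # first component is carried by the two correlated columns
        assert np.sum(emb.loadings[:2, 0] ** 2) > 0.99
        # oracle: independent SVD of the centered matrix
        Z = X - X.mean(0)
        s = np.linalg.svd(Z, compute_uv=False)
        np.testing.assert_allclose(
            emb.explained_variance, s[:3] ** 2 / np.sum(s**2), atol=1e-10
        )

    def test_rank_one_explained_variance(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 3 * t, -2 * t])
        emb = embed_trial(_nt(X), n_components=3, scaling="center_only")
        np.testing.assert_allclose(emb.explained_variance, [1.0, 0.0, 0.0], atol=1e-12)

    def test_scores_are_projection_of_standardized_matrix(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 6))
        emb = embed_trial(_nt(X), n_components=3)
        Z = (X - emb.column_centers) / emb.column_scales
        np.testing.assert_allclose(emb.scores, Z @ emb.loadings, atol=1e-8)
        # projecting back stays within the retained subspace
        np.testing.assert_allclose(
            emb.scores @ emb.loadings.T @ emb.loadings, emb.scores, atol=1e-8
        )

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(2)
        emb = embed_trial(_nt(rng.normal(size=(100, 5))), n_components=3)
        np.testing.assert_allclose(emb.loadings.T @ emb.loadings, np.eye(3), atol=1e-8)
        for j in range(3):
            i = np.argmax(np.abs(emb.loadings[:, j]))
            assert emb.loadings[i, j] > 0

    def test_too_few_variables_is_dimensionality_error(self):
        with pytest.raises(DimensionalityError):
            embed_trial(_nt(np.random.default_rng(0).normal(size=(100, 2))), n_components=3)


class TestProcrustesRotation:
    def test_recovers_random_orthogonal_transform(self):
        rng = np.random.default_rng(0)
        for k in range(10):
            source = rng.normal(size=(6, 3))
            Q = ortho_group.rvs(3, random_state=100 + k)
            R = procrustes_rotation(source, source @ Q)
            assert np.linalg.norm(R - Q) < 1e-10

    def test_identity_when_target_equals_source(self):
        source = np.random.default_rng(1).normal(size=(5, 3))
        np.testing.assert_allclose(
            procrustes_rotation(source, source), np.eye(3), atol=1e-10
        )

    def test_reflection_recovered_exactly(self):
        source = np.linalg.qr(np.random.default_rng(2).normal(size=(6, 3)))[0]
        target = source * np.array([-1.0, 1.0, 1.0])
        R = procrustes_rotation(source, target)
        np.testing.assert_allclose(R, np.diag([-1.0, 1.0, 1.0]), atol=1e-10)

    def test_matches_library_oracle_objective(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            A, B = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
            R = procrustes_rotation(A, B)
            R_oracle, _ = orthogonal_procrustes(A, B)
            obj = np.linalg.norm(A @ R - B)
            obj_oracle = np.linalg.norm(A @ R_oracle - B)
            assert obj <= obj_oracle + 1e-8

    def test_zero_matrix_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            procrustes_rotation(np.zeros((4, 2)), np.ones((4, 2)))


class TestGpaConsensus:
    def test_single_matrix_is_its_own_consensus(self):
        m = np.random.default_rng(0).normal(size=(6, 3))
        consensus, rotations, iterations, residual = gpa_consensus([m])
        np.testing.assert_allclose(consensus, m, atol=1e-12)
        assert iterations == 1
        assert residual < 1e-12

    def test_orthogonally_related_pair_aligns(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3))
        Q = ortho_group.rvs(3, random_state=7)
        consensus, rotations, _, _ = gpa_consensus([base, base @ Q])
        for m, r in zip([base, base @ Q], rotations):
            assert np.linalg.norm(m @ r - consensus) < 1e-8

    def test_identical_matrices_zero_residual(self):
        m = np.random.default_rng(2).normal(size=(6, 3))
        consensus, _, _, residual = gpa_consensus([m.copy() for _ in range(5)])
        np.testing.assert_allclose(consensus, m, atol=1e-10)
        assert residual < 1e-10

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 3))
        mats = [base + rng.normal(0, 0.2, base.shape) for _ in range(6)]
        history: list[float] = []
        gpa_consensus(mats, objective_history=history)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_empty_set_and_shape_mismatch(self):
        from reachkdi.errors import ParameterError
        with pytest.raises(ParameterError):
            gpa_consensus([])
        with pytest.raises(SchemaError):
            gpa_consensus([np.zeros((4, 2)), np.zeros((5, 2))])


class TestBuildReference:
    def test_single_trial_reference_is_own_scores(self, template):
        nt = make_normalized(template, PerturbationSpec("none"), seed=42,
                             endpoint="success")
        ref = build_reference([nt])
        emb = embed_trial(nt)
        np.testing.assert_allclose(ref.reference_scores, emb.scores, atol=1e-10)
        assert ref.n_baseline_trials == 1

    def test_template_trials_have_similar_small_kdi(self, template):
        trials = [
            make_normalized(template, PerturbationSpec("none"), seed=500 + i,
                            endpoint="success")
            for i in range(3)
        ]
        ref = build_reference(trials)
        kdis = [score_trial(t, ref).kdi for t in trials]
        assert np.std(kdis) / np.mean(kdis) < 0.5

    def test_mismatched_variables_is_schema_error(self):
        rng = np.random.default_rng(0)
        a = _nt(rng.normal(size=(50, 4)))
        b = _nt(rng.normal(size=(50, 4)), names=["a", "b", "c", "d"])
        with pytest.raises(SchemaError):
            build_reference([a, b])

    def test_no_baseline_trials_is_reference_unavailable(self):
        with pytest.raises(ReferenceUnavailableError):
            build_reference([])

    def test_mixed_animals_rejected(self):
        rng = np.random.default_rng(1)
        a = _nt(rng.normal(size=(50, 4)), animal_id="a1")
        b = _nt(rng.normal(size=(50, 4)), animal_id="a2")
        with pytest.raises(SchemaError):
            build_reference([a, b])


class TestScoreTrial:
    def test_self_reference_is_zero(self, template):
        nt = make_normalized(template, PerturbationSpec("none"), seed=7,
                             endpoint="success")
        ref = build_reference([nt])
        result = score_trial(nt, ref)
        assert result.kdi < 1e-10

    def test_hand_computed_small_case(self):
        # p = 3, J = 2, 5 samples: every step recomputed independently
        # with plain loops and eigendecomposition instead of SVD
        X_ref = np.array([
            [1.0, 2.0, 0.0],
            [2.0, 4.0, 1.0],
            [3.0, 5.0, 0.0],
            [4.0, 8.0, 1.0],
            [5.0, 9.0, 0.0],
        ])
        X_test = np.array([
            [1.0, 2.5, 1.0],
            [2.0, 3.5, 0.0],
            [3.0, 6.0, 1.0],
            [4.0, 7.5, 0.0],
            [5.0, 9.5, 1.0],
        ])
        cfg = CoreConfig(n_components=2, scaling="center_only")
        ref = build_reference([_nt(X_ref, trial_id="ref")], cfg)
        result = score_trial(_nt(X_test, trial_id="test"), ref, cfg)

        def pca_loadings(X, J):
            Z = X - X.mean(axis=0)
            evals, evecs = np.linalg.eigh(Z.T @ Z)
            order = np.argsort(evals)[::-1]
            L = evecs[:, order[:J]]
            for j in range(J):
                i = np.argmax(np.abs(L[:, j]))
                if L[i, j] < 0:
                    L[:, j] = -L[:, j]
            return Z, L

        Z_ref, L_ref = pca_loadings(X_ref, 2)
        Z_tst, L_tst = pca_loadings(X_test, 2)
        ref_scores = Z_ref @ L_ref
        U, _, Vt = np.linalg.svd(L_tst.T @ L_ref)
        S = Z_tst @ (L_tst @ (U @ Vt))
        expected_d = np.array([
            np.sqrt(sum((S[n, j] - ref_scores[n, j]) ** 2 for j in range(2)))
            for n in range(5)
        ])
        np.testing.assert_allclose(result.kd_trajectory, expected_d, atol=1e-10)
        np.testing.assert_allclose(result.kdi, expected_d.sum(), atol=1e-10)

    def test_perturbed_trial_scores_higher_than_clean(self, template, baseline_trials):
        ref = build_reference(baseline_trials[:5])
        clean = make_normalized(template, PerturbationSpec("none"), seed=900)
        perturbed = make_normalized(
            template,
            PerturbationSpec("grasp_alteration", amplitude=12.0, segment=(0.68, 1.0)),
            seed=900,
        )
        assert score_trial(perturbed, ref).kdi > score_trial(clean, ref).kdi

    def test_variable_mismatch_is_schema_error(self, baseline_trials):
        ref = build_reference(baseline_trials[:3])
        rng = np.random.default_rng(0)
        alien = _nt(rng.normal(size=(100, 8)), animal_id="a1")
        with pytest.raises(SchemaError):
            score_trial(alien, ref)

    def test_j_mismatch_is_dimensionality_error(self, baseline_trials):
        ref = build_reference(baseline_trials[:3], CoreConfig(n_components=3))
        with pytest.raises(DimensionalityError):
            score_trial(baseline_trials[0], ref, CoreConfig(n_components=2))

    def test_rotation_is_orthogonal(self, template, baseline_trials):
        ref = build_reference(baseline_trials[:5])
        result = score_trial(baseline_trials[5], ref)
        R = result.rotation_used
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-8)


class TestStabilityProperties:
    def test_baseline_order_permutation_stable(self, baseline_trials):
        cfg = CoreConfig()
        ref = build_reference(baseline_trials, cfg)
        perm = [3, 0, 7, 5, 1, 9, 2, 8, 4, 6]
        ref_p = build_reference([baseline_trials[i] for i in perm], cfg)
        assert np.max(np.abs(ref.reference_scores - ref_p.reference_scores)) < 1e-6
        for t in baseline_trials[:3]:
            a = score_trial(t, ref, cfg).kdi
            b = score_trial(t, ref_p, cfg).kdi
            assert abs(a - b) / a < 1e-6

    def test_orthogonal_invariance_center_only(self, baseline_trials):
        cfg = CoreConfig(scaling="center_only")
        ref = build_reference(baseline_trials[:5], cfg)
        kdis = [score_trial(t, ref, cfg).kdi for t in baseline_trials]
        Q = ortho_group.rvs(baseline_trials[0].p, random_state=11)

        def rotate(nt):
            out = copy.deepcopy(nt)
            out.matrix = nt.matrix @ Q
            return out

        rotated = [rotate(t) for t in baseline_trials]
        ref_q = build_reference(rotated[:5], cfg)
        kdis_q = [score_trial(t, ref_q, cfg).kdi for t in rotated]
        for a, b in zip(kdis, kdis_q):
            assert abs(a - b) / a < 1e-8
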