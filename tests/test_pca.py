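"""Essential-dynamics PCA, RMSIP and projections."""

import numpy as np
import pytest

from mdcna import pca as pca_mod
from mdcna import synthetic as syn
from mdcna.pca import align_to_mean, compute_pca, mode_vectors, project, rmsip

from conftest import displacement_ensemble, full_selection


def _unit(v):
    return v / np.linalg.norm(v)


def make_planted_mode_ensemble(rng, n_atoms, directions, score_stds, n_frames):
    """Frames displaced along fixed orthonormal 3N directions with *exact*
    per-mode score variance (scores are centred and whitened analytically)."""
    dirs = np.array([_unit(d) for d in directions])
    scores = rng.standard_normal((n_frames, len(dirs)))
    scores -= scores.mean(axis=0)
    # Exact orthonormalisation of the score columns -> exact variances.
    q, _ = np.linalg.qr(scores)
    scores = q * np.sqrt(n_frames) * np.asarray(score_stds)
    base = rng.normal(scale=5.0, size=(n_atoms, 3))
    disp = (scores @ dirs).reshape(n_frames, n_atoms, 3)
    return displacement_ensemble(base, disp), dirs, scores


class TestComputePca:
    def test_rank_one_ensemble(self):
        rng = np.random.default_rng(0)
        n = 8
        direction = rng.normal(size=3 * n)
        ens, dirs, scores = make_planted_mode_ensemble(
            rng, n, [direction], [0.7], n_frames=50
        )
        res = compute_pca(ens, full_selection(ens))
        assert np.isclose(res.variance_fraction[0], 100.0, atol=1e-8)
        assert np.isclose(res.eigenvalues[0], 0.49, atol=1e-10)

    def test_two_orthogonal_modes_variance_ratio(self):
        rng = np.random.default_rng(1)
        n = 10
        d1 = rng.normal(size=3 * n)
        d2 = rng.normal(size=3 * n)
        d2 -= d1 @ d2 / (d1 @ d1) * d1
        ens, _, _ = make_planted_mode_ensemble(rng, n, [d1, d2], [2.0, 1.0], 200)
        res = compute_pca(ens, full_selection(ens))
        assert np.isclose(res.variance_fraction[0], 80.0, atol=1e-8)
        assert np.isclose(res.variance_fraction[1], 20.0, atol=1e-8)

    def test_matches_dense_eigensolver_oracle(self, two_block_run):
        _, ensemble, _ = two_block_run
        small = ensemble.window(0, 300)
        sel = full_selection(small)
        res = compute_pca(small, sel)
        x = small.coords[:, sel.atom_indices, :].reshape(small.n_frames, -1)
        cov = np.cov(x.T, bias=True)
        evals = np.linalg.eigvalsh(cov)[::-1]
        k = res.n_modes
        assert np.allclose(res.eigenvalues, evals[:k], rtol=1e-8, atol=1e-12)

    def test_trace_conservation_and_orthonormality(self, two_block_run):
        _, ensemble, _ = two_block_run
        small = ensemble.window(0, 150)
        sel = full_selection(small)
        res = compute_pca(small, sel)
        x = small.coords[:, sel.atom_indices, :].reshape(small.n_frames, -1)
        total = ((x - x.mean(axis=0)) ** 2).mean(axis=0).sum()
        assert np.isclose(res.eigenvalues.sum(), total, rtol=1e-8)
        gram = res.eigenvectors @ res.eigenvectors.T
        assert np.abs(gram - np.eye(res.n_modes)).max() < 1e-8
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.isclose(res.variance_fraction.sum(), 100.0, rtol=1e-10)

    def test_degenerate_inputs_rejected(self, two_block_run):
        _, ensemble, _ = two_block_run
        sel = full_selection(ensemble)
        with pytest.raises(ValueError, match="2 frames"):
            compute_pca(ensemble.window(0, 1), sel)


@pytest.fixture(scope="module")
def basis():
    rng = np.random.default_rng(2)
    q, _ = np.linalg.qr(rng.standard_normal((40, 40)))
    return q.T  # rows orthonormal


class TestRmsip:
    def test_identical_subspaces(self, basis):
        assert np.isclose(rmsip(basis[:10], basis[:10]), 1.0, atol=1e-12)

    def test_orthogonal_subspaces(self, basis):
        assert np.isclose(rmsip(basis[:10], basis[10:20]), 0.0, atol=1e-12)

    def test_invariant_to_remixing_reordering_and_sign(self, basis):
        rng = np.random.default_rng(3)
        sub = basis[:10]
        perm = rng.permutation(10)
        flipped = sub[perm] * rng.choice([-1.0, 1.0], size=(10, 1))
        assert np.isclose(rmsip(sub, flipped), 1.0, atol=1e-10)
        mix, _ = np.linalg.qr(rng.standard_normal((10, 10)))
        remixed = mix @ sub
        assert np.isclose(rmsip(sub, remixed), 1.0, atol=1e-10)

    def test_dimension_and_depth_errors(self, basis):
        with pytest.raises(ValueError, match="common coordinate"):
            rmsip(basis[:10], basis[:10, :20])
        with pytest.raises(ValueError, match="at least"):
            rmsip(basis[:5], basis[:10])

    def test_replicate_draws_share_dominant_subspace(self):
        """Two independent draws from one planted covariance overlap strongly
        when the leading 10+ eigenvalues are well separated."""
        design = syn.multi_block_design()
        vecs = []
        for seed in (11, 12):
            ens, _ = syn.sample_block_ensemble(design, seed=seed)
            res = compute_pca(ens, full_selection(ens))
            vecs.append(res.eigenvectors[:10])
        assert rmsip(vecs[0], vecs[1]) >= 0.9


class TestProjection:
    def test_score_variance_equals_eigenvalues_and_zero_mean(self, two_block_run):
        _, ensemble, _ = two_block_run
        small = ensemble.window(0, 200)
        sel = full_selection(small)
        res = compute_pca(small, sel)
        proj = project(small, res, 3, sel)
        var = proj.scores.var(axis=0)  # population variance, matching 1/F
        assert np.allclose(var, res.eigenvalues[:3], rtol=1e-8)
        assert np.all(
            np.abs(proj.scores.mean(axis=0)) <= 1e-6 * proj.scores.std(axis=0)
        )

    def test_mean_frame_projects_to_zero(self, two_block_run):
        _, ensemble, _ = two_block_run
        small = ensemble.window(0, 50)
        sel = full_selection(small)
        res = compute_pca(small, sel)
        from mdcna.ensemble_io import CoordinateEnsemble

        mean_frame = res.mean_coords.reshape(1, -1, 3)
        mean_ens = CoordinateEnsemble(
            mean_frame, small.atom_table.iloc[sel.atom_indices].reset_index(drop=True)
        )
        proj = project(mean_ens, res, 3)
        assert np.abs(proj.scores).max() < 1e-10

    def test_k_exceeding_modes_rejected(self, two_block_run):
        _, ensemble, _ = two_block_run
        small = ensemble.window(0, 20)
        sel = full_selection(small)
        res = compute_pca(small, sel)
        with pytest.raises(ValueError, match="exceeds"):
            project(small, res, res.n_modes + 1, sel)

    def test_distinct_covariances_separate_in_joint_subspace(self):
        """Frames from two different planted covariances occupy separable
        regions of the joint PC1-3 space (positive silhouette)."""
        from sklearn.metrics import silhouette_score
        from mdcna.ensemble_io import CoordinateEnsemble

        d1 = syn.multi_block_design(n_frames=300)
        d2 = syn.multi_block_design(rho_in=0.4, rho_out=0.0, sigma=(0.3, 0.3, 0.3),
                                    n_frames=300)
        e1, _ = syn.sample_block_ensemble(d1, seed=5)
        e2, _ = syn.sample_block_ensemble(d2, seed=6)
        joint = CoordinateEnsemble(
            np.concatenate([e1.coords, e2.coords]), e1.atom_table
        )
        sel = full_selection(joint)
        res = compute_pca(joint, sel)
        proj = project(joint, res, 3, sel)
        labels = np.repeat([0, 1], 300)
        assert silhouette_score(proj.scores, labels) > 0


class TestModeVectors:
    def test_rank_one_arrows_parallel_to_planted_direction(self):
        rng = np.random.default_rng(4)
        n = 6
        direction = rng.normal(size=3 * n)
        ens, dirs, _ = make_planted_mode_ensemble(rng, n, [direction], [1.0], 40)
        res = compute_pca(ens, full_selection(ens))
        arrows = mode_vectors(res, 1, scale=1.0).reshape(-1)
        cos = abs(arrows @ dirs[0]) / np.linalg.norm(arrows)
        assert cos > 1 - 1e-8

    def test_scale_doubles_lengths(self, two_block_run):
        _, ensemble, _ = two_block_run
        small = ensemble.window(0, 30)
        res = compute_pca(small, full_selection(small))
        a1 = mode_vectors(res, 1, scale=1.0)
        a2 = mode_vectors(res, 1, scale=2.0)
        assert np.allclose(a2, 2 * a1)
        with pytest.raises(ValueError, match="positive"):
            mode_vectors(res, 1, scale=0.0)

    def test_export_mode_pdb_two_models(self, two_block_run, tmp_path):
        from mdcna.ensemble_io import read_ensemble
        from mdcna.pca import export_mode_pdb

        _, ensemble, _ = two_block_run
        small = ensemble.window(0, 30)
        sel = full_selection(small)
        res = compute_pca(small, sel)
        path = tmp_path / "pc1.pdb"
        export_mode_pdb(res, 1, small.atom_table.iloc[sel.atom_indices], path,
                        scale=3.0)
        stack = read_ensemble(path, path, format="multimodel-pdb")
        assert stack.n_frames == 2
        arrow_lengths = np.linalg.norm(stack.coords[1] - stack.coords[0], axis=1)
        assert np.isclose(arrow_lengths.max(), 3.0, atol=0.01)  # PDB precision

    def test_hinge_lobes_move_in_opposition(self, hinge_run):
        design, ensemble, _ = hinge_run
        sel = full_selection(ensemble)
        aligned = align_to_mean(ensemble, sel)
        res = compute_pca(aligned, sel)
        arrows = mode_vectors(res, 1, scale=1.0)
        part = design.partition_truth
        mean_a = arrows[part == 0].mean(axis=0)
        mean_b = arrows[part == 1].mean(axis=0)
        cos = mean_a @ mean_b / (np.linalg.norm(mean_a) * np.linalg.norm(mean_b))
        assert cos < 0


class TestHingeEssentialDynamics:
    def test_pc1_dominates_and_tracks_angle(self, hinge_run):
        design, ensemble, truth = hinge_run
        sel = full_selection(ensemble)
        aligned = align_to_mean(ensemble, sel)
        res = compute_pca(aligned, sel)
        assert res.variance_fraction[0] >= 60.0
        proj = project(aligned, res, 1, sel)
        r = np.corrcoef(proj.scores[:, 0], truth["angle_deg"])[0, 1]
        assert abs(r) >= 0.95
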