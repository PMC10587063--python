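"""Kabsch superposition, pruned RMSD, and model-level RMSD tables."""

import numpy as np
import pytest

from lamnode.superposition import (
    GeometryError,
    kabsch,
    kabsch_superpose,
    pairwise_rmsd_table,
    pruned_rmsd,
    superpose_models,
)
from lamnode.synthetic import (
    SyntheticNodeSpec,
    build_toy_node,
    perturb,
    random_rotation,
)
from oracles import grid_search_rmsd


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestKabsch:
    def test_identity_gives_zero(self, rng):
        A = rng.normal(size=(30, 3)) * 10
        res = kabsch_superpose(A, A.copy())
        assert res.rmsd_all == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_recovered(self, rng):
        A = rng.normal(size=(30, 3)) * 10
        R = random_rotation(rng)
        t = rng.normal(size=3) * 20
        res = kabsch_superpose(A, A @ R.T + t)
        assert res.rmsd_all == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, R, atol=1e-8)
        assert np.allclose(res.translation, t, atol=1e-7)

    def test_rotation_always_proper(self, rng):
        """det(R) = +1 even for near-reflective correspondences."""
        A = rng.normal(size=(10, 3))
        B = A.copy()
        B[:, 2] = -B[:, 2]  # mirrored partner
        res = kabsch_superpose(A, B)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_rotation_grid_oracle(self, seed):
        """4-atom toys: optimum matches exhaustive rotation search to 1e-3 Å."""
        r = np.random.default_rng(seed)
        A = r.normal(size=(4, 3)) * 3
        B = r.normal(size=(4, 3)) * 3
        ours = kabsch_superpose(A, B).rmsd_all
        oracle = grid_search_rmsd(A, B)
        assert ours <= oracle + 1e-9  # never worse than any searched rotation
        assert abs(ours - oracle) < 1e-3

    def test_agrees_with_biotite(self, rng):
        """Independent implementation cross-check on a random pair."""
        biotite_struc = pytest.importorskip("biotite.structure")
        A = rng.normal(size=(25, 3)) * 8
        B = A @ random_rotation(rng).T + rng.normal(size=3) + rng.normal(
            0, 0.3, size=(25, 3)
        )
        ours = kabsch_superpose(A, B).rmsd_all
        arr_a = biotite_struc.AtomArray(25)
        arr_b = biotite_struc.AtomArray(25)
        arr_a.coord = A.astype(np.float32)
        arr_b.coord = B.astype(np.float32)
        fitted, _ = biotite_struc.superimpose(arr_b, arr_a)
        theirs = float(biotite_struc.rmsd(arr_b, fitted))
        assert ours == pytest.approx(theirs, abs=1e-4)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(GeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch(line, line + 1.0)

    def test_fit_and_score_selections_differ(self, rng):
        """Fitting on a clean subset isolates the displaced remainder."""
        A = rng.normal(size=(20, 3)) * 10
        B = A.copy()
        B[10:] += 5.0
        res = kabsch_superpose(A, B, fit_selection=np.arange(10),
                               score_selection=np.arange(10, 20))
        assert res.rmsd_all == pytest.approx(np.sqrt(75.0), rel=1e-6)


class TestPrunedRmsd:
    def test_identical_structures_all_retained(self, rng):
        A = rng.normal(size=(40, 3)) * 10
        res = pruned_rmsd(A, A.copy(), cutoff=2.0)
        assert res.pruned_pairs == 40
        assert res.rmsd_pruned == pytest.approx(0.0, abs=1e-9)

    def test_planted_outliers_pruned(self, rng):
        """8 coincident pairs + 2 displaced 10 Å, cutoff 2 Å: 8 retained, 0 RMSD."""
        A = rng.normal(size=(10, 3)) * 20
        B = A.copy()
        B[3] += [10.0, 0, 0]
        B[7] += [0, 10.0, 0]
        res = pruned_rmsd(A, B, cutoff=2.0)
        assert res.pruned_pairs == 8
        assert res.rmsd_pruned == pytest.approx(0.0, abs=1e-9)
        assert res.rmsd_pruned <= res.rmsd_all

    def test_fixed_point_properties(self, rng):
        """At convergence every retained pair deviates <= cutoff under the
        final transform, the pruned RMSD never exceeds the all-pair RMSD,
        and extra iterations change nothing."""
        A = rng.normal(size=(100, 3)) * 15
        B = A + rng.normal(0, 0.3, size=(100, 3))
        B[::10] += rng.normal(0, 6.0, size=(10, 3))
        res = pruned_rmsd(A, B, cutoff=1.0, max_iter=20)
        assert res.rmsd_pruned <= res.rmsd_all
        assert res.rmsd_pruned <= 1.0
        dev = np.linalg.norm(res.transform(A) - B, axis=1)
        assert (dev <= 1.0).sum() == res.pruned_pairs
        again = pruned_rmsd(A, B, cutoff=1.0, max_iter=40)
        assert again.pruned_pairs == res.pruned_pairs
        assert again.rmsd_pruned == pytest.approx(res.rmsd_pruned, abs=1e-12)

    def test_emptying_prune_reports_iteration(self, rng):
        A = rng.normal(size=(10, 3))
        B = A + 50.0 * rng.normal(size=(10, 3))
        with pytest.raises(GeometryError, match="iteration"):
            pruned_rmsd(A, B, cutoff=0.01)

    def test_noise_recovery_matches_expectation(self, rng):
        """σ=0.5 Å per coordinate on 1000 atoms: RMSD ≈ σ√3 after refit."""
        A = rng.normal(size=(1000, 3)) * 15
        B = A + rng.normal(0, 0.5, size=(1000, 3))
        res = kabsch_superpose(A, B)
        expected = 0.5 * np.sqrt(3)
        assert res.rmsd_all == pytest.approx(expected, rel=0.05)


class TestModelLevel:
    def test_rigid_transformed_fixture_superposes_to_zero(self):
        rng = np.random.default_rng(7)
        spec = SyntheticNodeSpec(seed=7, audit=False)
        base, _ = build_toy_node(spec)
        moved, _ = build_toy_node(
            SyntheticNodeSpec(
                seed=7, audit=False,
                rigid_transform=(random_rotation(rng), rng.normal(size=3) * 10),
            )
        )
        res = superpose_models(moved, base, atom_mode="all_heavy")
        assert res.rmsd_all == pytest.approx(0.0, abs=1e-6)

    def test_perturbed_model_backbone_vs_allheavy(self, toy_model):
        noisy = perturb(toy_model, 0.4, seed=3)
        res = superpose_models(noisy, toy_model, atom_mode="all_heavy")
        assert 0.4 < res.rmsd_all < 1.2
        assert res.rmsd_backbone is not None

    def test_pairwise_table_symmetric_zero_diagonal(self, toy_model):
        noisy = perturb(toy_model, 0.5, seed=1)
        noisy.model_id = "noisy"
        mat, labels = pairwise_rmsd_table([toy_model, toy_model.copy(), noisy])
        assert mat.shape == (3, 3)
        assert np.allclose(np.diag(mat), 0.0)
        assert np.allclose(mat, mat.T)
        assert mat[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert mat[0, 2] > 0.5

    def test_known_displacement_matrix_entries(self):
        """Conformers built by a known uniform displacement give exactly 0 RMSD
        after superposition; a known stretched copy gives the hand value."""
        spec = SyntheticNodeSpec(seed=5, audit=False)
        base, _ = build_toy_node(spec)
        shifted = base.copy()
        shifted.model_id = "shifted"
        for chain in shifted.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + np.array([3.0, -2.0, 1.0])
        mat, _ = pairwise_rmsd_table([base, shifted], atom_mode="all_heavy")
        assert mat[0, 1] == pytest.approx(0.0, abs=1e-6)
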