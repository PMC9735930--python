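"""Superposition, RMSD series and atom-pair distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from liekit.exceptions import ValidationError
from liekit.geometry import (
    AtomTable,
    CoordinateSet,
    Trajectory,
    atom_pair_distances,
    kabsch_superpose,
    rmsd,
    rmsd_series,
)
from liekit.synthetic import gen_toy_trajectory, random_rigid_motions


def coordset(xyz, elements=None, groups=None):
    n = len(xyz)
    atoms = AtomTable(
        ids=np.arange(1, n + 1),
        names=np.array(["CA"] * n),
        residue_ids=np.array([f"GLY{i + 1}" for i in range(n)]),
        elements=np.array(elements if elements is not None else ["C"] * n),
        groups=np.array(groups if groups is not None else ["protein"] * n),
    )
    return CoordinateSet(atoms=atoms, xyz=np.asarray(xyz, dtype=float))


def grid_search_rmsd(mobile, reference, coarse=24, refinements=3):
    """Brute-force minimum RMSD over rotations (independent oracle).

    Hierarchical Euler-angle grid with optimal translation at each
    candidate (centroids aligned)."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def value(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return rmsd(x @ rot.T, y)

    best_angles, best = None, np.inf
    widths = (np.pi, np.pi / 2, np.pi)
    centers = (0.0, 0.0, 0.0)
    for level in range(refinements + 1):
        n = coarse if level == 0 else 9
        axes = [np.linspace(c - w, c + w, n) for c, w in zip(centers, widths)]
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    v = value((a, b, c))
                    if v < best:
                        best, best_angles = v, (a, b, c)
        centers = best_angles
        widths = tuple(2 * w / (n - 1) for w in widths)
    return best


class TestKabsch:
    def test_self_superposition_is_identity(self):
        ref = coordset(np.random.default_rng(0).normal(size=(6, 3)))
        fit = kabsch_superpose(ref, ref)
        assert fit.fitted_rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(fit.translation, 0.0, atol=1e-10)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(7, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = base @ rot.T + np.array([1.0, 2.0, 3.0])
        fit = kabsch_superpose(coordset(base), coordset(moved))
        assert fit.fitted_rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.apply(base), moved, atol=1e-10)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(5, 3)) * 2.0
        reference = rng.normal(size=(5, 3)) * 2.0
        fit = kabsch_superpose(coordset(mobile), coordset(reference))
        oracle = grid_search_rmsd(mobile, reference)
        assert fit.fitted_rmsd == pytest.approx(oracle, abs=1e-3)
        assert fit.fitted_rmsd <= oracle + 1e-9  # SVD optimum is never worse

    def test_rotation_is_always_proper(self):
        # near-reflection case: mirrored coordinates
        rng = np.random.default_rng(4)
        base = rng.normal(size=(6, 3))
        mirrored = base * np.array([1.0, 1.0, -1.0])
        fit = kabsch_superpose(coordset(base), coordset(mirrored))
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    def test_invariant_to_rigid_pretransformation(self):
        rng = np.random.default_rng(5)
        mobile = rng.normal(size=(8, 3))
        reference = rng.normal(size=(8, 3))
        baseline = kabsch_superpose(coordset(mobile), coordset(reference)).fitted_rmsd
        (rot, trans), = random_rigid_motions(1, seed=6)
        pre = mobile @ rot.T + trans
        again = kabsch_superpose(coordset(pre), coordset(reference)).fitted_rmsd
        assert again == pytest.approx(baseline, abs=1e-9)

    def test_matches_reference_svd_superimposer(self):
        from Bio.SVDSuperimposer import SVDSuperimposer

        rng = np.random.default_rng(14)
        mobile = rng.normal(size=(9, 3)) * 3.0
        reference = rng.normal(size=(9, 3)) * 3.0
        fit = kabsch_superpose(coordset(mobile), coordset(reference))
        sup = SVDSuperimposer()
        sup.set(reference, mobile)
        sup.run()
        assert fit.fitted_rmsd == pytest.approx(float(sup.get_rms()), abs=1e-9)
        rot, tran = sup.get_rotran()  # Biopython applies x @ rot + tran
        np.testing.assert_allclose(fit.rotation, rot.T, atol=1e-9)
        np.testing.assert_allclose(fit.translation, tran, atol=1e-9)

    def test_degenerate_selections_rejected(self):
        with pytest.raises(ValidationError, match=">=3"):
            kabsch_superpose(coordset(np.zeros((2, 3))), coordset(np.zeros((2, 3))))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValidationError, match="collinear"):
            kabsch_superpose(coordset(line), coordset(line))


class TestRMSDSeries:
    def test_identical_frames_give_zero(self):
        toy = gen_toy_trajectory(20, 4, displacement_sd=0.0, seed=0)
        summary = rmsd_series(toy.trajectory, fit_selection="all", measure_selection="all")
        assert summary.mean == pytest.approx(0.0, abs=1e-12)
        assert summary.sd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motions_removed_by_superposition(self):
        motions = random_rigid_motions(5, seed=7)
        toy = gen_toy_trajectory(20, 5, displacement_sd=0.0, rigid_motions=motions, seed=7)
        summary = rmsd_series(toy.trajectory, fit_selection="all", measure_selection="all")
        assert summary.mean == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_displacement_mean_matches_closed_form(self):
        """Isotropic per-atom Gaussian displacement sigma gives an RMSD of
        about sigma*sqrt(3) for many atoms."""
        sigma = 0.4
        toy = gen_toy_trajectory(500, 8, displacement_sd=sigma, seed=9)
        summary = rmsd_series(
            toy.trajectory, reference=toy.base, fit_selection="all", measure_selection="all"
        )
        assert summary.mean == pytest.approx(sigma * np.sqrt(3.0), rel=0.05)

    def test_frame_reordering_leaves_summary_unchanged(self):
        toy = gen_toy_trajectory(30, 6, displacement_sd=0.3, seed=10)
        traj = toy.trajectory
        shuffled = Trajectory(atoms=traj.atoms, coords=traj.coords[::-1].copy())
        a = rmsd_series(traj, reference=toy.base, fit_selection="all", measure_selection="all")
        b = rmsd_series(shuffled, reference=toy.base, fit_selection="all", measure_selection="all")
        assert a.mean == pytest.approx(b.mean)
        assert a.sd == pytest.approx(b.sd)

    def test_superposed_rmsd_never_exceeds_raw(self):
        motions = random_rigid_motions(6, seed=11)
        toy = gen_toy_trajectory(25, 6, displacement_sd=0.2, rigid_motions=motions, seed=11)
        fitted = rmsd_series(
            toy.trajectory, reference=toy.base, fit_selection="all", measure_selection="all"
        )
        raw = rmsd_series(
            toy.trajectory, reference=toy.base, fit_selection="all",
            measure_selection="all", superpose=False,
        )
        assert (fitted.per_frame <= raw.per_frame + 1e-9).all()

    def test_hydrogens_excluded_by_default(self):
        xyz = np.vstack([np.eye(3) * 2, [[100.0, 0.0, 0.0]]])
        elements = ["C", "C", "C", "H"]
        atoms = coordset(xyz, elements=elements).atoms
        traj = Trajectory(atoms=atoms, coords=np.stack([xyz, xyz]))
        heavy = rmsd_series(traj, fit_selection="all", measure_selection="all")
        assert heavy.mean == pytest.approx(0.0, abs=1e-12)

    def test_empty_selection_rejected(self):
        toy = gen_toy_trajectory(10, 2, seed=1)
        with pytest.raises(ValidationError, match="zero atoms"):
            rmsd_series(toy.trajectory, fit_selection="all", measure_selection="ligand")


class TestAtomPairDistances:
    def test_cases(self):
        coords = coordset([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [0.0, 0.0, 0.0]])
        values = atom_pair_distances(coords, [(1, 2), (1, 3)])
        assert values[0] == pytest.approx(5.0)  # 3-4-5 triangle
        assert values[1] == pytest.approx(0.0)  # coincident atoms

    def test_translation_invariance(self):
        rng = np.random.default_rng(13)
        xyz = rng.normal(size=(6, 3))
        pairs = [(1, 4), (2, 6), (3, 5)]
        before = atom_pair_distances(coordset(xyz), pairs)
        after = atom_pair_distances(coordset(xyz + np.array([5.0, -2.0, 9.0])), pairs)
        assert np.allclose(before, after)

    def test_unknown_id_named_in_error(self):
        coords = coordset(np.zeros((3, 3)))
        with pytest.raises(ValidationError, match="99"):
            atom_pair_distances(coords, [(1, 99)])
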