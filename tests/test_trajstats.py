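"""Contact, SASA/burial, distance, hydrogen-bond and RMSD statistics."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from fepscan import (
    ContactSpec,
    ResidueContactProfile,
    Trajectory,
    contact_area_ratio,
    contact_probability,
    hydrogen_bond_occupancy,
    kabsch_rmsd,
    key_residue_filter,
    pair_distance_series,
    rmsd_series,
    sasa,
    tail_mean,
)
from fepscan.trajectory import make_atom_table
from fepscan.trajstats import residue_sasa


def atoms(n, chain="A", resid=None, element="C", names=None):
    return make_atom_table(
        names=names or [f"C{i}" for i in range(n)],
        resids=resid or [1] * n,
        resnames=["UNK"] * n,
        chains=[chain] * n if isinstance(chain, str) else chain,
        elements=[element] * n if isinstance(element, str) else element,
    )


ALL_FRAMES = ContactSpec(cutoff=4.5, tail_fraction=1.0)


class TestContactProbability:
    def test_constructed_seven_of_ten(self, two_chain_traj):
        got = contact_probability(two_chain_traj, "P:1", "R", ALL_FRAMES)
        assert got == pytest.approx(0.7)

    def test_far_partner_never_contacts(self, two_chain_traj):
        got = contact_probability(two_chain_traj, "P:2", "R", ALL_FRAMES)
        assert got == 0.0

    def test_pooling_is_frame_weighted_mean(self, two_chain_traj):
        """Pooled probability over replicas equals brute-force frame
        enumeration over the concatenated tails."""
        # second replica: the same trajectory truncated to 5 frames
        half = Trajectory(two_chain_traj.coords[:5].copy(),
                          two_chain_traj.atoms)
        pooled = contact_probability(
            [two_chain_traj, half], "P:1", "R", ALL_FRAMES
        )
        # brute force, counting frames explicitly
        hits = total = 0
        for traj in (two_chain_traj, half):
            ia = traj.select("P:1", heavy_only=True)
            ib = traj.select("R", heavy_only=True)
            for f in range(traj.n_frames):
                d = cdist(traj.coords[f][ia], traj.coords[f][ib]).min()
                hits += d < 4.5
                total += 1
        assert pooled == pytest.approx(hits / total)
        # and equals the frame-count-weighted mean of per-replica values
        p1 = contact_probability(two_chain_traj, "P:1", "R", ALL_FRAMES)
        p2 = contact_probability(half, "P:1", "R", ALL_FRAMES)
        assert pooled == pytest.approx((10 * p1 + 5 * p2) / 15)

    def test_monotone_in_cutoff(self, two_chain_traj):
        probs = [
            contact_probability(
                two_chain_traj, "P:1", "R",
                ContactSpec(cutoff=c, tail_fraction=1.0),
            )
            for c in (2.0, 4.5, 10.0, 40.0)
        ]
        assert probs == sorted(probs)
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_tail_window_selects_final_frames(self, two_chain_traj):
        # last 30% = frames 8-10, all out of contact
        got = contact_probability(
            two_chain_traj, "P:1", "R",
            ContactSpec(cutoff=4.5, tail_fraction=0.3),
        )
        assert got == 0.0

    def test_empty_selection_rejected(self, two_chain_traj):
        with pytest.raises(ValueError):
            contact_probability(two_chain_traj, "Z", "R", ALL_FRAMES)


class TestKeyResidueFilter:
    def test_fifty_percent_threshold(self):
        profile = ResidueContactProfile(
            contact_probability={1: 0.6, 2: 0.4, 3: 0.5, 4: 1.0}
        )
        # strictly greater than 0.5: residue 3 at exactly 0.5 is excluded
        assert key_residue_filter(profile) == [1, 4]

    def test_empty_profile(self):
        assert key_residue_filter(ResidueContactProfile()) == []

    def test_zero_threshold_returns_all_positive(self):
        got = key_residue_filter({5: 0.1, 2: 0.9, 9: 0.2}, threshold=0.0)
        assert got == [2, 5, 9]


class TestSasa:
    def test_single_sphere_closed_form(self):
        r = 1.7
        got = sasa(np.zeros((1, 3)), np.array([r]))
        assert got[0] == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=1e-3)

    def test_distant_atoms_are_isolated_spheres(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        got = sasa(coords, radii)
        for a, r in zip(got, radii):
            assert a == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=1e-3)

    def test_overlapping_spheres_match_dense_oracle(self):
        """Two overlapping atoms: production point count agrees with a
        100k-point brute-force burial test within 2%."""
        coords = np.array([[0.0, 0, 0], [2.0, 0.5, 0.3]])
        radii = np.array([1.7, 1.55])
        got = sasa(coords, radii, n_points=960)
        dense = sasa(coords, radii, n_points=100_000)
        np.testing.assert_allclose(got, dense, rtol=0.02)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(scale=2.0, size=(6, 3))
        radii = np.full(6, 1.7)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 9.0])
        # discretization-limited: 2% at the production point count,
        # tightening as the sphere grid is refined
        np.testing.assert_allclose(
            sasa(coords, radii), sasa(moved, radii), rtol=0.02
        )
        np.testing.assert_allclose(
            sasa(coords, radii, n_points=5000),
            sasa(moved, radii, n_points=5000),
            rtol=0.01,
        )

    def test_two_atom_approach_buries_area(self):
        radii = np.array([1.7, 1.7])
        areas = [
            sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), radii).sum()
            for d in (6.5, 5.0, 3.0, 1.5)
        ]
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.empty((0, 3)), np.array([]))


class TestContactAreaRatio:
    def test_separated_chains_all_zero(self, two_chain_traj):
        # final frame: every residue out of contact, 26 Å apart
        prof = contact_area_ratio(two_chain_traj, "P", "R", frame=9,
                                  n_points=240)
        assert all(v == 0.0 for v in prof.contact_area_ratio.values())

    def test_enclosed_atom_fully_buried(self):
        """A peptide atom caged inside a tight receptor shell loses
        essentially all accessible surface (ratio ≈ 1)."""
        shell = []
        golden = math.pi * (3 - math.sqrt(5))
        for i in range(40):  # tight cage of receptor atoms at 3.0 Å
            z = 1 - 2 * (i + 0.5) / 40
            rho = math.sqrt(1 - z * z)
            shell.append([3.0 * rho * math.cos(golden * i),
                          3.0 * rho * math.sin(golden * i), 3.0 * z])
        coords = np.vstack([[[0.0, 0.0, 0.0]], shell])
        tab = atoms(41, chain=["P"] + ["R"] * 40,
                    resid=[1] + [i + 1 for i in range(40)])
        traj = Trajectory(coords[None], tab)
        prof = contact_area_ratio(traj, "P", "R", n_points=480)
        assert prof.contact_area_ratio[1] == pytest.approx(1.0, abs=0.02)

    def test_matches_dense_point_oracle(self):
        coords = np.array([
            [0.0, 0, 0], [3.2, 0, 0],      # chain P, residues 1-2
            [1.5, 2.4, 0.5], [4.0, 2.2, -0.4],  # chain R
        ])
        tab = atoms(4, chain=["P", "P", "R", "R"], resid=[1, 2, 1, 2])
        traj = Trajectory(coords[None], tab)
        fast = contact_area_ratio(traj, "P", "R", n_points=960)
        dense = contact_area_ratio(traj, "P", "R", n_points=50_000)
        for r in (1, 2):
            assert fast.contact_area_ratio[r] == pytest.approx(
                dense.contact_area_ratio[r], abs=0.02
            )

    def test_global_rigid_motion_invariance(self, two_chain_traj):
        rot = Rotation.random(random_state=5).as_matrix()
        moved = Trajectory(
            two_chain_traj.coords @ rot.T + np.array([10.0, 0.0, -4.0]),
            two_chain_traj.atoms,
        )
        a = contact_area_ratio(two_chain_traj, "P", "R", frame=0,
                               n_points=240)
        b = contact_area_ratio(moved, "P", "R", frame=0, n_points=240)
        for r in a.contact_area_ratio:
            assert a.contact_area_ratio[r] == pytest.approx(
                b.contact_area_ratio[r], abs=0.02
            )

    def test_values_within_unit_interval(self, two_chain_traj):
        prof = contact_area_ratio(two_chain_traj, "P", "R", frame=0,
                                  n_points=240)
        assert all(0.0 <= v <= 1.0 for v in prof.contact_area_ratio.values())


class TestPairDistances:
    def test_three_four_five_triangle(self):
        traj = Trajectory(
            np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]]),
            atoms(2, chain=["A", "B"]),
        )
        np.testing.assert_allclose(
            pair_distance_series(traj, "A", "B"), [5.0]
        )

    def test_overlapping_distinct_atoms_give_zero(self):
        traj = Trajectory(
            np.array([[[1.0, 1, 1], [1.0, 1, 1]]]),
            atoms(2, chain=["A", "B"]),
        )
        assert pair_distance_series(traj, "A", "B")[0] == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(scale=4.0, size=(3, 10, 3))
        tab = atoms(10, chain=["A"] * 4 + ["B"] * 6)
        traj = Trajectory(coords, tab)
        got = pair_distance_series(traj, "A", "B")
        for f in range(3):
            brute = min(
                np.linalg.norm(coords[f, i] - coords[f, j])
                for i in range(4) for j in range(4, 10)
            )
            assert got[f] == pytest.approx(brute)

    def test_series_length_is_frame_count(self, two_chain_traj):
        got = pair_distance_series(two_chain_traj, "P:1", "R:1")
        assert got.shape == (two_chain_traj.n_frames,)


class TestHydrogenBonds:
    def _donor_system(self, acceptor_xyz):
        # donor N at origin with H at (1,0,0); acceptor O per frame
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0], acceptor_xyz]])
        tab = make_atom_table(
            names=["N", "H", "O"], resids=[1, 1, 2],
            resnames=["ASN", "ASN", "SER"], chains=["A", "A", "B"],
            elements=["N", "H", "O"],
        )
        return Trajectory(coords, tab)

    def test_collinear_bond_full_occupancy(self):
        traj = self._donor_system([2.8, 0.0, 0.0])
        occ = hydrogen_bond_occupancy(traj, "A:1", "B:2")
        assert occ["occupancy"].tolist() == [1.0]

    def test_long_distance_zero(self):
        traj = self._donor_system([5.0, 0.0, 0.0])
        occ = hydrogen_bond_occupancy(traj, "A:1", "B:2")
        assert occ["occupancy"].tolist() == [0.0]

    def test_bent_geometry_zero(self):
        # acceptor at right angle from the D-H axis, 2.8 Å from donor
        traj = self._donor_system([0.0, 2.8, 0.0])
        occ = hydrogen_bond_occupancy(traj, "A:1", "B:2")
        assert occ["occupancy"].tolist() == [0.0]

    def test_donor_without_hydrogen_rejected(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 0, 0]]])
        tab = make_atom_table(
            names=["N", "O"], resids=[1, 2], resnames=["ASN", "SER"],
            chains=["A", "B"], elements=["N", "O"],
        )
        traj = Trajectory(coords, tab)
        with pytest.raises(ValueError, match="A:1:N"):
            hydrogen_bond_occupancy(traj, "A:1", "B:2")


class TestKabschRmsd:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        y = x @ rot.T + np.array([2.0, -1.0, 0.5])
        assert kabsch_rmsd(x, y) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, 3))
        y = x + rng.normal(scale=0.3, size=(5, 3))
        assert kabsch_rmsd(x, y) == pytest.approx(kabsch_rmsd(y, x))

    def test_simultaneous_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(5, 3))
        y = x + rng.normal(scale=0.4, size=(5, 3))
        rot = Rotation.random(random_state=11).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        assert kabsch_rmsd(x @ rot.T + t, y @ rot.T + t) == pytest.approx(
            kabsch_rmsd(x, y), abs=1e-9
        )

    def test_four_atom_toy_matches_rotation_grid_oracle(self):
        """Exhaustive search over a fine SO(3) Euler grid cannot beat the
        closed-form Kabsch optimum by more than the grid resolution."""
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0],
                        [0.3, 0.4, 1.8]])
        rng = np.random.default_rng(12)
        mob = ref + rng.normal(scale=0.4, size=ref.shape)
        got = kabsch_rmsd(ref, mob)
        rc = ref - ref.mean(axis=0)
        mc = mob - mob.mean(axis=0)

        def rmsd_at(euler):
            rot = Rotation.from_euler("zyz", euler).as_matrix()
            return math.sqrt((((mc @ rot.T) - rc) ** 2).sum() / 4)

        # coarse Euler grid followed by local zooming refinement
        grid = [
            (a, b, c)
            for a in np.linspace(0, 2 * math.pi, 13, endpoint=False)
            for b in np.linspace(0, math.pi, 7)
            for c in np.linspace(0, 2 * math.pi, 13, endpoint=False)
        ]
        best = min(grid, key=rmsd_at)
        width = math.pi / 6
        for _ in range(8):
            a0, b0, c0 = best
            local = [
                (a, b, c)
                for a in np.linspace(a0 - width, a0 + width, 7)
                for b in np.linspace(b0 - width, b0 + width, 7)
                for c in np.linspace(c0 - width, c0 + width, 7)
            ]
            best = min(local, key=rmsd_at)
            width /= 3
        oracle = rmsd_at(best)
        assert got <= oracle + 1e-9
        assert got == pytest.approx(oracle, abs=1e-3)

    def test_against_mdanalysis_oracle(self):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(13)
        x = rng.normal(size=(7, 3))
        y = x + rng.normal(scale=0.5, size=(7, 3))
        theirs = mda_rms.rmsd(y, x, center=True, superposition=True)
        assert kabsch_rmsd(x, y) == pytest.approx(theirs, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_rmsd(line, line)
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, two_chain_traj):
        static = Trajectory(
            np.repeat(two_chain_traj.coords[:1], 5, axis=0),
            two_chain_traj.atoms,
        )
        got = rmsd_series(static)
        assert got.shape == (5,)
        np.testing.assert_allclose(got, 0.0, atol=1e-9)

    def test_matches_framewise_recomputation(self, two_chain_traj):
        got = rmsd_series(two_chain_traj)
        ref = two_chain_traj.coords[0]
        brute = [
            kabsch_rmsd(ref, two_chain_traj.coords[f])
            for f in range(two_chain_traj.n_frames)
        ]
        np.testing.assert_allclose(got, brute)
        assert tail_mean(got, 0.5) == pytest.approx(
            float(np.mean(brute[5:]))
        )
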