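import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bdascan import (
    cluster, compare, find_hbonds, fixtures, hbond_conservation, kabsch,
    rmsd_series, rmsf,
)
from bdascan.structio import Atom, Residue, Structure, Trajectory
from bdascan.trajanalysis import HBondCriteria, pairwise_rmsd


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        res = kabsch(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        res = kabsch(pts, pts + [5.0, 0.0, 0.0])
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.translation, [-5.0, 0.0, 0.0],
                                   atol=1e-9)

    def test_rotation_is_proper_orthogonal(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            res = kabsch(a, b)
            np.testing.assert_allclose(res.rotation @ res.rotation.T,
                                       np.eye(3), atol=1e-9)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0,
                                                                abs=1e-9)

    def test_reflection_is_corrected(self):
        pts = np.random.default_rng(3).normal(size=(5, 3))
        mirrored = pts * [-1.0, 1.0, 1.0]
        res = kabsch(pts, mirrored)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_rotated_copy_beats_rotation_grid_oracle(self):
        """Kabsch must be at or below a brute-force search over a dense
        Euler-angle grid, and within the expected noise band."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(4, 3))
        true_rot = Rotation.random(random_state=rng)
        noisy = true_rot.apply(pts) + rng.normal(0.0, 0.1, size=(4, 3))
        res = kabsch(pts, noisy)
        assert 0.0 <= res.rmsd <= 0.35

        ref_c = pts - pts.mean(axis=0)
        mov_c = noisy - noisy.mean(axis=0)
        grid = np.deg2rad(np.arange(0.0, 360.0, 10.0))
        half = np.deg2rad(np.arange(0.0, 180.0, 10.0))
        best = np.inf
        for a in grid:
            for b in half:
                for c in grid:
                    rot = Rotation.from_euler("zyz", [a, b, c])
                    r = np.sqrt(((mov_c @ rot.as_matrix().T - ref_c) ** 2
                                 ).sum(axis=1).mean())
                    best = min(best, r)
        assert res.rmsd <= best + 1e-9

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        res = kabsch(a, b)
        rot, _ = Rotation.align_vectors(a - a.mean(axis=0),
                                        b - b.mean(axis=0))
        np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-7)

    def test_superposed_never_exceeds_unsuperposed(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(size=(7, 3))
            b = rng.normal(size=(7, 3)) + rng.normal(0, 3, size=3)
            raw = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
            assert kabsch(a, b).rmsd <= raw + 1e-9

    def test_too_few_or_collinear_points_raise(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                         [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line + 1.0)


class TestRmsdSeries:
    def test_copies_of_reference_give_zero(self, tyr_peptide):
        base = tyr_peptide.coords()
        traj = Trajectory(tyr_peptide, [base.copy() for _ in range(4)])
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-10)

    def test_rigid_rotations_give_zero(self, tyr_peptide):
        rng = np.random.default_rng(7)
        base = tyr_peptide.coords()
        frames = [Rotation.random(random_state=rng).apply(base) +
                  rng.normal(0, 5, 3) for _ in range(5)]
        traj = Trajectory(tyr_peptide, frames)
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-8)

    def test_gaussian_noise_matches_closed_form(self):
        """E|Δr|² = 3σ² per atom, so RMSD ≈ σ√3 for many atoms."""
        s = fixtures.make_structure(sequence="Y" * 45)
        assert s.n_atoms >= 500
        sigma = 0.3
        traj = fixtures.make_noisy_trajectory(s, sigma, 20, seed=8)
        series = rmsd_series(traj, selection="all")
        assert series.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_empty_selection_raises(self, tyr_peptide):
        traj = Trajectory(tyr_peptide, [tyr_peptide.coords()])
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, selection=np.array([], dtype=int))

    def test_invariant_under_global_rototranslation(self, tyr_peptide):
        rng = np.random.default_rng(9)
        traj = fixtures.make_noisy_trajectory(tyr_peptide, 0.4, 6, seed=10)
        ref = rmsd_series(traj)
        rot = Rotation.random(random_state=rng)
        shift = rng.normal(0, 10, 3)
        moved = Trajectory(tyr_peptide,
                           [rot.apply(f) + shift for f in traj.frames])
        np.testing.assert_allclose(rmsd_series(moved), ref, atol=1e-8)


class TestRmsf:
    def test_static_trajectory_is_zero(self, tyr_peptide):
        base = tyr_peptide.coords()
        traj = Trajectory(tyr_peptide, [base.copy(), base.copy()])
        np.testing.assert_allclose(rmsf(traj, "all"), 0.0, atol=1e-12)

    def test_single_frame_raises(self, tyr_peptide):
        traj = Trajectory(tyr_peptide, [tyr_peptide.coords()])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj)

    def test_one_mobile_atom_recovers_displacement(self):
        """One atom oscillating ±d among many anchored atoms: its RMSF is
        d, the rest stay at 0."""
        rng = np.random.default_rng(11)
        n = 40
        base = rng.normal(0, 5, size=(n, 3))
        residues = [Residue("A", i + 1, "GLY",
                            [Atom(i + 1, "CA", "C", base[i])])
                    for i in range(n)]
        topo = Structure([residues])
        d = 0.8
        frames = []
        for t in range(50):
            f = base.copy()
            f[0, 0] += d if t % 2 == 0 else -d
            frames.append(f)
        values = rmsf(Trajectory(topo, frames), "all", n_iter=0)
        assert values[0] == pytest.approx(d, abs=1e-9)
        np.testing.assert_allclose(values[1:], 0.0, atol=1e-9)

    def test_gaussian_noise_matches_closed_form(self):
        s = fixtures.make_structure(sequence="Y" * 20)
        sigma = 0.5
        traj = fixtures.make_noisy_trajectory(s, sigma, 600, seed=12)
        values = rmsf(traj, "all")
        assert values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestHBonds:
    def test_planted_ideal_bond_found(self):
        s, planted = fixtures.make_hbond_fixture(1, seed=13)
        found = find_hbonds(None, s)
        assert len(found) == 1
        assert (found[0].donor_res, found[0].acceptor_res) == planted[0]

    def test_long_bond_rejected_by_distance_cutoff(self):
        s, _ = fixtures.make_hbond_fixture(1, seed=13)
        # stretch every acceptor 0.8 Å further out: 2.8 → 3.6 Å > 3.0
        for res in s.residues:
            if res.resname == "ACC":
                o = res.atom("O")
                donor_n = s.residues[0].atom("N").xyz
                u = (o.xyz - donor_n) / np.linalg.norm(o.xyz - donor_n)
                for a in res.atoms:
                    a.xyz = a.xyz + 0.8 * u
        assert find_hbonds(None, s) == []
        assert len(find_hbonds(None, s, HBondCriteria(d_max=4.0))) == 1

    def test_exact_recovery_with_decoys(self):
        s, planted = fixtures.make_hbond_fixture(7, seed=14, n_decoys=12)
        found = find_hbonds(None, s)
        assert {(h.donor_res, h.acceptor_res) for h in found} == \
            set(planted)

    def test_heavy_mode_uses_distance_only(self):
        s, planted = fixtures.make_hbond_fixture(2, seed=15)
        # drop all hydrogens, as in an H-free trajectory
        for res in s.residues:
            res.atoms = [a for a in res.atoms if not a.is_hydrogen]
        assert find_hbonds(None, s) == []
        heavy = find_hbonds(None, s, HBondCriteria(d_max=3.0, mode="heavy"))
        assert {(h.donor_res, h.acceptor_res) for h in heavy} == \
            set(planted)


def _three_partner_fixture(drop_partner=None, n_frames=3):
    """A central residue donating three H-bonds to three acceptors;
    optionally one acceptor is displaced far away in every frame."""
    center = []
    serial = 0
    residues = []
    site_atoms = []
    directions = np.eye(3)
    for i, u in enumerate(directions):
        serial += 2
        site_atoms += [Atom(serial - 1, f"N{i + 1}", "N", 10.0 * u),
                       Atom(serial, f"H{i + 1}", "H", 10.0 * u + 1.0 * u)]
    residues.append(Residue("A", 1, "CTR", site_atoms))
    for i, u in enumerate(directions):
        serial += 1
        pos = 10.0 * u + 2.8 * u
        if drop_partner == i:
            pos = pos + 30.0 * u
        residues.append(Residue("A", 2 + i, "ACC",
                                [Atom(serial, "O", "O", pos)]))
    topo = Structure([residues])
    base = topo.coords()
    return Trajectory(topo, [base.copy() for _ in range(n_frames)])


class TestHBondConservation:
    def test_identical_trajectories_give_one(self):
        wt = _three_partner_fixture()
        mut = _three_partner_fixture()
        c, wt_set, mut_set = hbond_conservation(wt, mut, ("A", 1, ""))
        assert c == 1.0
        assert len(wt_set) == 3 and wt_set == mut_set

    def test_displaced_partner_lowers_conservation_to_two_thirds(self):
        wt = _three_partner_fixture()
        mut = _three_partner_fixture(drop_partner=2)
        c, wt_set, mut_set = hbond_conservation(wt, mut, ("A", 1, ""))
        assert c == pytest.approx(2.0 / 3.0)
        assert len(mut_set) == 2

    def test_all_partners_displaced_gives_zero(self):
        wt = _three_partner_fixture()
        residues = [r.copy() for r in wt.topology.models[0]]
        for r in residues:
            if r.resname == "ACC":
                for a in r.atoms:
                    a.xyz = a.xyz + 40.0
        topo = Structure([residues])
        mut = Trajectory(topo, [topo.coords()] * 3)
        c, _, mut_set = hbond_conservation(wt, mut, ("A", 1, ""))
        assert c == 0.0 and mut_set == set()

    def test_missing_site_raises(self):
        wt = _three_partner_fixture()
        with pytest.raises(KeyError, match="not present"):
            hbond_conservation(wt, wt, ("Z", 99, ""))


class TestCluster:
    def test_identical_frames_form_one_full_cluster(self, tyr_peptide):
        base = tyr_peptide.coords()
        traj = Trajectory(tyr_peptide, [base.copy() for _ in range(6)])
        res = cluster(traj, "CA", cutoff=1.0)
        assert res.n_clusters == 1
        assert res.populations[0] == pytest.approx(1.0)
        assert res.representative_frames[0] == 0

    def test_two_state_populations_recovered(self):
        s = fixtures.make_structure(sequence="AYAYAYAYAG")
        traj, labels = fixtures.make_two_state_trajectory(
            s, (0.7, 0.3), displacement=6.0, sigma=0.3, n_frames=200,
            seed=16)
        res = cluster(traj, "CA", cutoff=1.5)
        top = res.populations.max()
        true_top = max((labels == 0).mean(), (labels == 1).mean())
        assert top == pytest.approx(true_top, abs=0.02)

    def test_leader_matches_brute_force_neighbor_counting(self):
        """Independent re-derivation: repeatedly maximize neighbor counts
        on the raw RMSD matrix with explicit loops."""
        s = fixtures.make_structure(sequence="AYAYA")
        traj, _ = fixtures.make_two_state_trajectory(
            s, (0.6, 0.4), displacement=5.0, sigma=0.4, n_frames=40,
            seed=17)
        cutoff = 1.5
        res = cluster(traj, "CA", cutoff)
        mat = pairwise_rmsd(traj, "CA")
        remaining = set(range(traj.n_frames))
        labels = {}
        cid = 0
        reps = []
        while remaining:
            best_frame, best_count = None, -1
            for f in sorted(remaining):
                count = sum(1 for g in remaining if mat[f, g] <= cutoff)
                if count > best_count:
                    best_frame, best_count = f, count
            members = [g for g in sorted(remaining)
                       if mat[best_frame, g] <= cutoff]
            for g in members:
                labels[g] = cid
                remaining.discard(g)
            reps.append(best_frame)
            cid += 1
        assert res.representative_frames == reps
        assert [labels[i] for i in range(traj.n_frames)] == \
            res.labels.tolist()

    def test_populations_sum_to_one(self):
        s = fixtures.make_structure(sequence="AYAYA")
        traj, _ = fixtures.make_two_state_trajectory(
            s, (0.5, 0.5), displacement=4.0, sigma=0.5, n_frames=30,
            seed=18)
        res = cluster(traj, "CA", cutoff=0.8)
        assert res.populations.sum() == pytest.approx(1.0, abs=1e-9)
        for c, rep in enumerate(res.representative_frames):
            assert res.labels[rep] == c


class TestCompare:
    def test_wt_against_itself_is_null_comparison(self, tyr_peptide):
        traj = fixtures.make_noisy_trajectory(tyr_peptide, 0.2, 12, seed=19)
        rep = compare(traj, traj, site=("A", 3, ""))
        assert rep.rmsd_mean_wt == rep.rmsd_mean_mut
        np.testing.assert_array_equal(rep.rmsd_wt, rep.rmsd_mut)
        assert rep.hbond_conservation == 1.0
        assert rep.top_cluster_population_wt == \
            rep.top_cluster_population_mut
        assert rep.representative_rmsd == pytest.approx(0.0, abs=1e-9)
        assert all(v == 0.0 for v in rep.rmsf_delta.values())

    def test_report_row_counts_match_frame_counts(self, tyr_peptide):
        wt = fixtures.make_noisy_trajectory(tyr_peptide, 0.2, 10, seed=20)
        mut = fixtures.make_noisy_trajectory(tyr_peptide, 0.2, 14, seed=21)
        rep = compare(wt, mut)
        assert len(rep.rmsd_wt) == 10 and len(rep.rmsd_mut) == 14
        assert len(rep.hbond_counts_wt) == 10
        assert len(rep.hbond_counts_mut) == 14

    def test_identical_dynamics_give_similar_mean_rmsd(self, tyr_peptide):
        wt = fixtures.make_noisy_trajectory(tyr_peptide, 0.3, 30, seed=22)
        mut = fixtures.make_noisy_trajectory(tyr_peptide, 0.3, 30, seed=23)
        rep = compare(wt, mut)
        noise_floor = 0.1 * rep.rmsd_mean_wt + 0.05
        assert abs(rep.rmsd_mean_wt - rep.rmsd_mean_mut) < noise_floor
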