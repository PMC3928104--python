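"""Geometry tests: distances, pocket calls, H-bonds, helices, RMSD/RMSF."""

import numpy as np
import pytest

from conftest import random_rotation
from fretmd.restraints import FretTableRow
from fretmd.sitemap import SiteMap, SiteMappingError
from fretmd.structure_metrics import (
    DegenerateAxisError,
    assign_helices,
    ca_distance,
    compare_to_fret,
    detect_hbonds,
    helix_axis_angle,
    kabsch_rmsd,
    pocket_openness,
    rmsf,
    scan_pair_distances,
)
from fretmd.structures import StructureModel
from fretmd.synthetic import ToyStructureSpec, make_structure, make_trajectory


def rigid_copy(structure: StructureModel, seed: int = 0) -> StructureModel:
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    shift = rng.uniform(-30, 30, size=3)
    return StructureModel(
        chains=structure.chains.copy(),
        resnums=structure.resnums.copy(),
        resnames=structure.resnames.copy(),
        names=structure.names.copy(),
        frames=structure.frames @ rot.T + shift,
    )


def simple_map() -> SiteMap:
    return SiteMap(copies=[{"A": "A", "B": "B"}])


class TestCaDistance:
    def test_identical_sites_give_zero(self, ideal_helix_12):
        m = SiteMap(copies=[{"A": "A"}])
        assert ca_distance(ideal_helix_12, ("A", 3), ("A", 3), m) == 0.0

    def test_symmetric_and_matches_hand_calculation(self, ideal_helix_12):
        m = SiteMap(copies=[{"A": "A"}])
        d_ab = ca_distance(ideal_helix_12, ("A", 2), ("A", 7), m)
        d_ba = ca_distance(ideal_helix_12, ("A", 7), ("A", 2), m)
        p2 = ideal_helix_12.coords[ideal_helix_12.atom_index("A", 2, "CA")]
        p7 = ideal_helix_12.coords[ideal_helix_12.atom_index("A", 7, "CA")]
        assert d_ab == d_ba == pytest.approx(float(np.linalg.norm(p2 - p7)))

    def test_unresolved_site_raises(self, ideal_helix_12):
        m = SiteMap(copies=[{"A": "A"}])
        with pytest.raises(SiteMappingError):
            ca_distance(ideal_helix_12, ("A", 2), ("A", 99), m)

    def test_invariant_under_rigid_motion(self, ideal_helix_12):
        m = SiteMap(copies=[{"A": "A"}])
        moved = rigid_copy(ideal_helix_12, seed=4)
        assert ca_distance(moved, ("A", 2), ("A", 9), m) == pytest.approx(
            ca_distance(ideal_helix_12, ("A", 2), ("A", 9), m), abs=1e-9
        )


class TestPocketOpenness:
    def dumbbell_with_separation(self, d: float) -> StructureModel:
        s = make_structure(
            ToyStructureSpec(kind="two_domain_dumbbell", n_residues=10,
                             inter_site_distances=((1, 1, d),))
        )
        return s

    def make_map(self) -> SiteMap:
        # pocket residues 13/51 mapped onto the two dumbbell reference sites
        return SiteMap(
            copies=[{"cTnC": "A"}],
            overrides={
                "cTnC:13": {"chain": "A", "resnum": 1},
                "cTnC:51": {"chain": "B", "resnum": 1},
            },
        )

    @pytest.mark.parametrize(
        "d,expected", [(29.06, "open"), (19.21, "closed"), (24.0, "open")]
    )
    def test_threshold_classification(self, d, expected):
        state = pocket_openness(self.dumbbell_with_separation(d), self.make_map())
        assert state.d_13_51 == pytest.approx(d, abs=1e-6)
        assert state.state == expected

    def test_pure_threshold_function_of_distance(self):
        # classification must agree with ca_distance >= threshold exactly
        for d in (18.0, 23.999, 24.0, 24.001, 35.0):
            structure = self.dumbbell_with_separation(d)
            m = self.make_map()
            state = pocket_openness(structure, m)
            dist = ca_distance(structure, ("cTnC", 13), ("cTnC", 51), m)
            assert (state.state == "open") == (dist >= state.threshold)

    def test_missing_residue_raises(self, ideal_helix_12):
        with pytest.raises(SiteMappingError):
            pocket_openness(ideal_helix_12, SiteMap(copies=[{"cTnC": "Z"}]))


class TestScanPairDistances:
    def test_finds_prescribed_inter_chain_pair(self):
        s = make_structure(
            ToyStructureSpec(kind="two_domain_dumbbell", n_residues=10,
                             inter_site_distances=((1, 1, 40.0),))
        )
        hits = scan_pair_distances(s, 1, 1, same_chain=False)
        assert any(abs(d - 40.0) < 1e-6 for _, _, d in hits)


class TestHBonds:
    def test_ideal_helix_has_complete_i_i4_pattern(self, ideal_helix_12):
        bonds = detect_hbonds(ideal_helix_12)
        turn = {
            (b.acceptor[1], b.donor[1])
            for b in bonds
            if b.acceptor[2] == "O" and b.donor[2] == "N"
        }
        for i in range(1, 9):
            assert (i, i + 4) in turn

    def test_pair_just_beyond_cutoff_not_reported(self):
        # two isolated atoms at d_cut + 0.01: no bond
        structure = StructureModel(
            chains=np.array(["A", "B"]),
            resnums=np.array([1, 1]),
            resnames=np.array(["GLY", "GLY"]),
            names=np.array(["N", "O"]),
            frames=np.array([[[0.0, 0.0, 0.0], [3.51, 0.0, 0.0]]]),
        )
        assert detect_hbonds(structure, d_cut=3.5) == []

    def test_invariant_under_rigid_motion(self, ideal_helix_12):
        ref = detect_hbonds(ideal_helix_12)
        moved = detect_hbonds(rigid_copy(ideal_helix_12, seed=8))
        assert [(b.donor, b.acceptor) for b in ref] == [
            (b.donor, b.acceptor) for b in moved
        ]
        for a, b in zip(ref, moved):
            assert b.distance == pytest.approx(a.distance, abs=1e-9)


class TestAssignHelices:
    def test_single_segment_on_ideal_helix(self, ideal_helix_12):
        assignment = assign_helices(ideal_helix_12)
        assert len(assignment.segments) == 1
        chain, start, end = assignment.segments[0]
        assert chain == "A" and end - start + 1 >= 8

    def test_extended_chain_has_no_helix(self, extended_chain_12):
        assignment = assign_helices(extended_chain_12)
        assert assignment.segments == []
        assert assignment.n_helical() == 0

    def test_displaced_core_splits_segment(self):
        # perturbation oracle: push 3 central residues 3 Å off the helix
        helix = make_structure(ToyStructureSpec(kind="ideal_helix", n_residues=24))
        frames = helix.frames.copy()
        moved = np.isin(helix.resnums, [12, 13, 14])
        frames[0, moved, :] += np.array([3.0, 0.0, 0.0])
        perturbed = StructureModel(
            chains=helix.chains, resnums=helix.resnums,
            resnames=helix.resnames, names=helix.names, frames=frames,
        )
        n_before = len(assign_helices(helix).segments)
        n_after = len(assign_helices(perturbed).segments)
        assert n_before == 1
        assert n_after == 2

    def test_interior_length_covariance(self):
        # n-residue helix -> interior segment of n - k for a fixed end effect
        lengths = {}
        for n in (10, 14, 18, 22):
            helix = make_structure(ToyStructureSpec(kind="ideal_helix", n_residues=n))
            (chain, start, end), = assign_helices(helix).segments
            lengths[n] = end - start + 1
        ks = {n - l for n, l in lengths.items()}
        assert len(ks) == 1


class TestHelixAxisAngle:
    def test_segment_against_itself_is_zero(self, ideal_helix_12):
        assert helix_axis_angle(
            ideal_helix_12, ("A", 1, 12), ("A", 1, 12)
        ) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_helices_read_ninety_degrees(self):
        a = make_structure(ToyStructureSpec(kind="ideal_helix", n_residues=11))
        # rotate a copy by exactly 90 degrees about an axis perpendicular to
        # the helix axis (rotating about an arbitrary axis would not map the
        # helix direction onto an orthogonal one) and label it chain B
        ca = a.frames[0][a.select(names=["CA"])]
        u = ca[-1] - ca[0]
        u /= np.linalg.norm(u)
        w = np.cross(u, [0.0, 0.0, 1.0])
        w /= np.linalg.norm(w)
        wx = np.array(
            [[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]]
        )
        rot = np.eye(3) + wx + wx @ wx  # Rodrigues at 90 degrees
        b_frames = a.frames @ rot.T + np.array([30.0, 0.0, 0.0])
        combined = StructureModel(
            chains=np.concatenate([a.chains, np.full(a.n_atoms, "B")]),
            resnums=np.concatenate([a.resnums, a.resnums]),
            resnames=np.concatenate([a.resnames, a.resnames]),
            names=np.concatenate([a.names, a.names]),
            frames=np.concatenate([a.frames, b_frames], axis=1),
        )
        angle = helix_axis_angle(combined, ("A", 1, 11), ("B", 1, 11))
        assert angle == pytest.approx(90.0, abs=2.0)

    def test_angle_unchanged_when_both_segments_rotate(self):
        a = make_structure(ToyStructureSpec(kind="ideal_helix", n_residues=16))
        angle_ref = helix_axis_angle(a, ("A", 1, 8), ("A", 9, 16))
        moved = rigid_copy(a, seed=3)
        angle_moved = helix_axis_angle(moved, ("A", 1, 8), ("A", 9, 16))
        assert angle_moved == pytest.approx(angle_ref, abs=1e-6)

    def test_short_segment_rejected(self, ideal_helix_12):
        with pytest.raises(DegenerateAxisError):
            helix_axis_angle(ideal_helix_12, ("A", 1, 4), ("A", 5, 12))


def quaternion_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Independent oracle: optimal superposition via the quaternion method."""
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (p**2).sum() + (q**2).sum()
    n = p.shape[0]
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / n))


class TestKabschRmsd:
    def test_rigid_motion_gives_zero(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(50, 3)) * 10.0
        rot = random_rotation(rng)
        frame = ref @ rot.T + np.array([5.0, -3.0, 12.0])
        assert kabsch_rmsd(frame[None], ref)[0] < 1e-8

    def test_single_atom_displacement_closed_form(self):
        # one atom moved 1 Å among N=100: RMSD = sqrt(1/N) = 0.1.  The
        # displacement is made radial (along the atom's centered position) so
        # it exerts no torque and the optimal rotation stays the identity;
        # re-centering alone then gives exactly 0.1 * sqrt(1 - 1/N).
        rng = np.random.default_rng(6)
        ref = rng.normal(size=(100, 3)) * 50.0
        frame = ref.copy()
        radial = ref[0] - ref.mean(axis=0)
        frame[0] += radial / np.linalg.norm(radial)
        rmsd = kabsch_rmsd(frame[None], ref)[0]
        assert rmsd == pytest.approx(0.1 * np.sqrt(1.0 - 0.01), rel=1e-6)
        assert rmsd == pytest.approx(0.1, rel=0.01)

    def test_matches_quaternion_oracle_on_small_configurations(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ref = rng.normal(size=(4, 3)) * 8.0
            frame = ref + rng.normal(size=(4, 3))
            ours = kabsch_rmsd(frame[None], ref)[0]
            oracle = quaternion_superpose_rmsd(frame, ref)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((1, 2, 3)), np.zeros((2, 3)))


class TestRmsf:
    def test_identical_frames_give_zero(self, ideal_helix_12):
        traj = make_trajectory(
            ideal_helix_12, np.zeros(12), n_frames=10, seed=0
        )
        assert np.all(rmsf(traj.frames) < 1e-12)

    def test_isotropic_jitter_recovers_sqrt3_sigma(self, ideal_helix_12):
        sigma = np.zeros(12)
        sigma[5] = 1.0
        traj = make_trajectory(ideal_helix_12, sigma, n_frames=2000, seed=42)
        mask = ideal_helix_12.select(names=["CA"])
        values = rmsf(traj.frames, mask)
        assert values[5] == pytest.approx(np.sqrt(3.0), rel=0.05)
        assert np.all(values[:5] < 1e-12) and np.all(values[6:] < 1e-12)

    def test_doubling_amplitude_doubles_rmsf(self, ideal_helix_12):
        mask = ideal_helix_12.select(names=["CA"])
        base = rmsf(
            make_trajectory(ideal_helix_12, np.full(12, 0.5), 800, seed=9).frames,
            mask,
        )
        double = rmsf(
            make_trajectory(ideal_helix_12, np.full(12, 1.0), 800, seed=9).frames,
            mask,
        )
        np.testing.assert_allclose(double, 2.0 * base, rtol=1e-9)

    def test_per_residue_amplitude_profile_recovered(self):
        # Pearson correlation > 0.99 between prescribed and recovered profiles
        helix = make_structure(ToyStructureSpec(kind="ideal_helix", n_residues=30))
        rng = np.random.default_rng(13)
        sigma = rng.uniform(0.2, 2.5, size=30)
        traj = make_trajectory(helix, sigma, n_frames=2000, seed=77)
        values = rmsf(traj.frames, helix.select(names=["CA"]))
        r = np.corrcoef(sigma * np.sqrt(3.0), values)[0, 1]
        assert r > 0.99

    def test_equilibration_frames_dropped(self, ideal_helix_12):
        traj = make_trajectory(ideal_helix_12, np.full(12, 1.0), 50, seed=2)
        # freezing the first 30 frames at the base changes the statistics
        frames = traj.frames.copy()
        frames[:30] = traj.frames[0]
        with_equil = rmsf(frames, equilibration_frames=30)
        assert np.all(with_equil > 0.0)


class TestCompareToFret:
    def test_exact_match_flags_agreement(self):
        s = make_structure(
            ToyStructureSpec(kind="two_domain_dumbbell", n_residues=10,
                             inter_site_distances=((1, 1, 48.1),))
        )
        rows = [FretTableRow(("A", 1), ("B", 1), "ca_saturated", 48.1, 10.2)]
        report = compare_to_fret(rows, s, simple_map())
        assert report["deviation_A"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert bool(report["within_tolerance"].iloc[0])

    def test_deviations_match_brute_force(self, ideal_helix_12):
        site_map = SiteMap(copies=[{"X": "A"}])
        rows = [
            FretTableRow(("X", 2), ("X", 8), "ca_free", 10.0, 5.0),
            FretTableRow(("X", 1), ("X", 12), "ca_free", 20.0, 5.0),
        ]
        report = compare_to_fret(rows, ideal_helix_12, site_map)
        for row, (_, rep) in zip(rows, report.iterrows()):
            i = ideal_helix_12.atom_index("A", row.donor_site[1], "CA")
            j = ideal_helix_12.atom_index("A", row.acceptor_site[1], "CA")
            d = float(
                np.linalg.norm(ideal_helix_12.coords[i] - ideal_helix_12.coords[j])
            )
            assert rep["model_A"] == pytest.approx(d)
            assert rep["deviation_A"] == pytest.approx(d - row.rbar)

    def test_unmapped_rows_reported_not_fatal(self, ideal_helix_12):
        site_map = SiteMap(copies=[{"X": "A"}])
        rows = [FretTableRow(("Y", 2), ("X", 8), "ca_free", 10.0, 5.0)]
        report = compare_to_fret(rows, ideal_helix_12, site_map)
        assert len(report) == 1
        assert np.isnan(report["model_A"].iloc[0])
        assert not bool(report["within_tolerance"].iloc[0])
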