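"""Distance, contact, hydrogen-bond and torsion descriptors vs brute force."""

import mdtraj as md
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mabshape import (
    SyntheticSpec,
    basic_descriptors,
    ch2_distance,
    generate_hbond_fixture,
    generate_toy_mab,
    glycan_com_displacement,
    glycan_min_distance,
    glycosidic_dihedrals,
    hydrogen_bonds,
    residue_contacts,
)
from mabshape.groups import AtomGroupConfig


def kabsch_rmsd(a, b):
    """Independent minimal-RMSD oracle: center + SVD rotation."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return float(np.sqrt(np.mean(np.sum((a - b @ r.T) ** 2, axis=1))))


class TestBasicDescriptors:
    def test_identical_frames_are_silent(self, chain_traj_factory):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(12, 3))
        t = chain_traj_factory(np.repeat(frame[None], 5, axis=0))
        rmsd, rmsf, rg = basic_descriptors(t)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-6)
        np.testing.assert_allclose(rmsf, 0.0, atol=1e-6)
        assert np.all(rg > 0)

    def test_rigid_motion_removed_by_superposition(self, chain_traj_factory):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(15, 3))
        rot = Rotation.random(random_state=rng).as_matrix()
        t = chain_traj_factory(np.stack([frame, frame @ rot.T + 2.0]))
        rmsd, _, _ = basic_descriptors(t)
        assert rmsd[1] < 1e-5

    def test_single_central_atom_displacement_closed_form(self, chain_traj_factory):
        """27-atom cube, center atom (at the centroid) displaced by d:
        optimal superposition is the identity and RMSD = d*sqrt(26)/27."""
        grid = np.array(
            [[x, y, z] for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)],
            float,
        )
        center = int(np.flatnonzero((grid == 0).all(axis=1))[0])
        d = 0.4
        moved = grid.copy()
        moved[center, 0] += d
        t = chain_traj_factory(np.stack([grid, moved]))
        rmsd, _, _ = basic_descriptors(t)
        assert rmsd[1] == pytest.approx(d * np.sqrt(26.0) / 27.0, rel=1e-4)

    def test_rmsd_matches_kabsch_oracle(self, chain_traj_factory):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(4, 10, 3))
        t = chain_traj_factory(frames)
        rmsd, _, _ = basic_descriptors(t)
        # single-precision trajectory storage bounds the agreement near zero
        for i in range(4):
            assert rmsd[i] == pytest.approx(kabsch_rmsd(frames[0], frames[i]), abs=1e-3)

    def test_empty_selection_rejected(self, chain_traj_factory):
        t = chain_traj_factory(np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            basic_descriptors(t, selection=np.array([], dtype=int))


class TestCh2Distance:
    def test_fixed_geometry(self):
        toy = generate_toy_mab(
            SyntheticSpec(seed=3, n_frames=20, ch2_mean_nm=3.1, ch2_sd_nm=1e-9)
        )
        d = ch2_distance(toy.traj, toy.groups)
        assert d.median == pytest.approx(3.1, abs=1e-5)

    def test_generator_round_trip_median(self):
        toy = generate_toy_mab(
            SyntheticSpec(seed=4, n_frames=3000, ch2_mean_nm=4.8, ch2_sd_nm=0.3)
        )
        d = ch2_distance(toy.traj, toy.groups)
        # sampling error of the median at n=3000: ~1.25*sd/sqrt(n) ~ 0.007
        assert d.median == pytest.approx(4.8, abs=0.03)

    def test_translation_invariance(self):
        toy = generate_toy_mab(SyntheticSpec(seed=5, n_frames=10, rigid_motion=False))
        base = ch2_distance(toy.xyz, toy.groups)
        shifted = ch2_distance(toy.xyz + np.array([1.0, -2.0, 3.0]), toy.groups)
        np.testing.assert_allclose(shifted.values, base.values, atol=1e-12)

    def test_missing_groups_rejected(self, toy_static_frame):
        coords, groups = toy_static_frame
        with pytest.raises(ValueError):
            ch2_distance(coords[None], groups)


class TestGlycanMinDistance:
    def _groups(self, n_a, n_b, n_total):
        return AtomGroupConfig(
            fc=[0], fab1=[1], fab2=[2], hinge=[0], ch2_a=[1], ch2_b=[2],
            glycan_a=list(range(3, 3 + n_a)),
            glycan_b=list(range(3 + n_a, 3 + n_a + n_b)),
        )

    def test_two_single_atoms(self, chain_traj_factory):
        xyz = np.zeros((1, 5, 3))
        xyz[0, 3] = [0, 0, 0]
        xyz[0, 4] = [1.0, 0, 0]
        g = self._groups(1, 1, 5)
        d = glycan_min_distance(chain_traj_factory(xyz), g)
        assert d.values[0] == pytest.approx(1.0, abs=1e-6)

    def test_overlapping_atoms_give_zero(self, chain_traj_factory):
        xyz = np.zeros((1, 5, 3))
        g = self._groups(1, 1, 5)
        d = glycan_min_distance(chain_traj_factory(xyz), g)
        assert d.values[0] == 0.0

    def test_matches_exhaustive_pair_scan(self, chain_traj_factory):
        rng = np.random.default_rng(6)
        xyz = rng.normal(size=(3, 43, 3))
        g = self._groups(20, 20, 43)
        d = glycan_min_distance(chain_traj_factory(xyz), g)
        for f in range(3):
            best = min(
                np.linalg.norm(xyz[f, a] - xyz[f, b])
                for a in range(3, 23)
                for b in range(23, 43)
            )
            assert d.values[f] == pytest.approx(best, abs=1e-6)


class TestGlycanComDisplacement:
    def test_static_system_is_zero(self):
        toy = generate_toy_mab(
            SyntheticSpec(seed=7, n_frames=8, glycan_jitter_nm=1e-9, rigid_motion=False)
        )
        d = glycan_com_displacement(toy.traj, toy.groups, chain="a")
        np.testing.assert_allclose(d.values, 0.0, atol=1e-5)

    def test_pure_rigid_motion_removed_by_alignment(self):
        toy = generate_toy_mab(
            SyntheticSpec(seed=8, n_frames=8, glycan_jitter_nm=1e-9, rigid_motion=True)
        )
        d = glycan_com_displacement(toy.traj, toy.groups, chain="b")
        np.testing.assert_allclose(d.values, 0.0, atol=1e-5)

    def test_planted_translation_recovered(self, chain_traj_factory):
        rng = np.random.default_rng(9)
        fc = rng.normal(size=(6, 3))
        xyz = np.zeros((2, 8, 3))
        xyz[:, :6] = fc  # static Fc
        xyz[:, 6] = [0, 0, 1.0]
        xyz[:, 7] = [0, 0, 1.2]
        xyz[1, 6:] += [2.0, 0, 0]  # glycan moved 2 nm, Fc static
        g = AtomGroupConfig(
            fc=list(range(6)), fab1=[6], fab2=[7], hinge=[0], ch2_a=[1], ch2_b=[2],
            glycan_a=[6, 7],
        )
        d = glycan_com_displacement(chain_traj_factory(xyz), g, chain="a")
        assert d.values[1] == pytest.approx(2.0, abs=1e-5)


class TestResidueContacts:
    def test_far_apart_counts_zero(self, chain_traj_factory):
        xyz = np.zeros((2, 4, 3))
        xyz[:, 2:] += 10.0
        g = AtomGroupConfig(
            fc=[0], fab1=[1], fab2=[2], hinge=[0, 1], ch2_a=[0], ch2_b=[1],
            lc_cterm=[2, 3],
        )
        table = residue_contacts(chain_traj_factory(xyz), g)
        assert np.all(table.counts == 0)

    def test_hand_built_pair_count(self, chain_traj_factory):
        # residues 3 and 4 vs hinge atoms 0,1,2: 2+2 pairs under 0.4 nm
        xyz = np.zeros((1, 5, 3))
        xyz[0, 0] = [0.0, 0, 0]
        xyz[0, 1] = [0.3, 0, 0]
        xyz[0, 2] = [5.0, 0, 0]
        xyz[0, 3] = [0.1, 0.2, 0]  # near atoms 0 and 1
        xyz[0, 4] = [0.35, 0.1, 0]  # near atom 1 only (0.36 from atom 0... check)
        g = AtomGroupConfig(
            fc=[2], fab1=[3], fab2=[4], hinge=[0, 1, 2], ch2_a=[0], ch2_b=[1],
            lc_cterm=[3, 4],
        )
        table = residue_contacts(chain_traj_factory(xyz), g, cutoff=0.4)
        # oracle: exhaustive scan
        expected = np.zeros(2, int)
        for k, a in enumerate((3, 4)):
            for b in (0, 1, 2):
                if np.linalg.norm(xyz[0, a] - xyz[0, b]) <= 0.4:
                    expected[k] += 1
        np.testing.assert_array_equal(table.counts[0], expected)
        assert table.counts.sum() == 4  # 2 + 2 pairs by construction

    def test_monotone_in_cutoff(self, chain_traj_factory):
        rng = np.random.default_rng(10)
        xyz = rng.normal(scale=0.3, size=(2, 8, 3))
        g = AtomGroupConfig(
            fc=[0], fab1=[4], fab2=[5], hinge=[0, 1, 2, 3], ch2_a=[0], ch2_b=[1],
            lc_cterm=[4, 5, 6, 7],
        )
        t = chain_traj_factory(xyz)
        prev = residue_contacts(t, g, cutoff=0.2).counts
        for c in (0.4, 0.6, 1.0):
            cur = residue_contacts(t, g, cutoff=c).counts
            assert np.all(cur >= prev)
            prev = cur

    def test_zero_cutoff_counts_only_coincident(self, chain_traj_factory):
        xyz = np.zeros((1, 4, 3))
        xyz[0, 3] = [1, 0, 0]
        g = AtomGroupConfig(
            fc=[1], fab1=[2], fab2=[3], hinge=[0, 1], ch2_a=[0], ch2_b=[1],
            lc_cterm=[2, 3],
        )
        table = residue_contacts(chain_traj_factory(xyz), g, cutoff=0.0)
        assert table.counts[0].tolist() == [2, 0]  # atom2 coincides with hinge 0,1


class TestHydrogenBonds:
    def test_ideal_linear_bond_detected(self):
        t = generate_hbond_fixture(occupancy=1.0, n_frames=3, seed=0)
        hb = hydrogen_bonds(t)
        assert len(hb.table) == 1
        assert hb.table.frequency.iloc[0] == 1.0

    def test_bent_geometry_rejected(self):
        t = generate_hbond_fixture(occupancy=1.0, n_frames=1, seed=0)
        xyz = t.xyz.copy()
        # put acceptor at 90 deg from the O-H axis, same H...A distance
        xyz[0, 2] = [0.10, 0.20, 0.0]
        t.xyz = xyz
        hb = hydrogen_bonds(t)
        assert len(hb.table) == 0

    def test_planted_occupancy_recovered_exactly(self):
        t = generate_hbond_fixture(occupancy=0.6, n_frames=50, seed=1)
        hb = hydrogen_bonds(t)
        assert hb.table.frequency.iloc[0] == pytest.approx(0.60, abs=1e-12)

    def test_matches_exhaustive_geometric_scan(self):
        rng = np.random.default_rng(11)
        t = generate_hbond_fixture(occupancy=0.5, n_frames=20, seed=2)
        xyz = t.xyz.copy()
        xyz += rng.normal(scale=0.03, size=xyz.shape).astype(np.float32)
        t.xyz = xyz
        hb = hydrogen_bonds(t)
        # oracle: direct scan of the (O_d, H, O_a) triplet
        hits = 0
        for f in range(20):
            od, h, oa = xyz[f]
            r = np.linalg.norm(od - oa)
            v1, v2 = od - h, oa - h
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if r <= 0.35 and np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 120:
                hits += 1
        freq = hb.table.frequency.iloc[0] if len(hb.table) else 0.0
        assert freq == pytest.approx(hits / 20, abs=1e-12)

    def test_topology_without_hydrogens_rejected(self, chain_traj_factory):
        t = chain_traj_factory(np.zeros((1, 3, 3)))
        with pytest.raises(ValueError, match="hydrogens"):
            hydrogen_bonds(t)


def torsion_oracle(p0, p1, p2, p3):
    """Independent dihedral formula (atan2 of the half-plane normals)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w))


class TestGlycosidicDihedrals:
    def _traj_with_torsion(self, chain_traj_factory, angle_deg):
        p0 = np.array([1.0, -1.0, 0.0])
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([1.5, 0.0, 0.0])
        # rotate the p0 half-plane direction (-y) about the central bond
        a = np.radians(angle_deg)
        p3 = p2 + np.array([0.5, -np.cos(a), -np.sin(a)])
        xyz = np.stack([p0, p1, p2, p3])[None]
        return chain_traj_factory(xyz, atom_names=["O5", "C1", "O4", "C4"]), (p0, p1, p2, p3)

    @pytest.mark.parametrize("angle", [60.0, 0.0, -120.0, 179.0])
    def test_known_torsion_recovered(self, chain_traj_factory, angle):
        t, pts = self._traj_with_torsion(chain_traj_factory, angle)
        linkages = [{"name": "lk", "phi": [0, 1, 2, 3], "psi": [0, 1, 2, 3]}]
        d = glycosidic_dihedrals(t, linkages)
        oracle = torsion_oracle(*pts)
        assert d.phi[0, 0] == pytest.approx(oracle, abs=1e-3)
        # the constructed geometry realizes the requested angle exactly
        assert d.phi[0, 0] == pytest.approx(angle, abs=1e-3)

    def test_in_range_fraction(self, toy_small):
        linkages = [dict(lk) for lk in toy_small.linkages]
        for lk in linkages:
            lk["phi_range"] = [-180.0, 180.0]
            lk["psi_range"] = [-180.0, 180.0]
        d = glycosidic_dihedrals(toy_small.traj, linkages)
        np.testing.assert_allclose(d.phi_in_range, 1.0)
        np.testing.assert_allclose(d.psi_in_range, 1.0)

    def test_wrapped_range(self, chain_traj_factory):
        t, _ = self._traj_with_torsion(chain_traj_factory, 175.0)
        linkages = [
            {"name": "lk", "phi": [0, 1, 2, 3], "psi": [0, 1, 2, 3],
             "phi_range": [170.0, -170.0]}
        ]
        d = glycosidic_dihedrals(t, linkages)
        assert d.phi_in_range[0] == 1.0

    def test_unknown_atom_is_named_in_error(self, toy_small):
        linkages = [
            {"name": "bad", "phi": [[0, "OX9"]] * 4, "psi": [[0, "OX9"]] * 4}
        ]
        with pytest.raises(KeyError, match="bad"):
            glycosidic_dihedrals(toy_small.traj, linkages)
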