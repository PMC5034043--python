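"""Hydrogen-bond geometry, frame detection, and occupancy statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from alkylbind.hbond import (
    HBondCriterion,
    classify_site_by_phb,
    detect_hbond,
    frame_bonded,
    occupancy,
)
from alkylbind.trajectory import Atom, Trajectory

D = np.array([0.0, 0.0, 0.0])
H = np.array([1.0, 0.0, 0.0])


class TestDetect:
    def test_distance_failure(self):
        geo = detect_hbond(D, H, np.array([5.0, 0.0, 0.0]))
        assert not geo.bonded
        assert geo.d_da == pytest.approx(5.0)

    def test_ideal_collinear_geometry(self):
        geo = detect_hbond(D, H, np.array([2.8, 0.0, 0.0]))
        assert geo.bonded
        assert geo.deviation_deg == pytest.approx(0.0, abs=1e-9)

    def test_angle_failure_despite_distance(self):
        """Explicit vector arithmetic: A=(2.4, 2.1, 0) gives d=3.19 A
        (inside the cutoff) but a 41.2 degree deviation (outside)."""
        geo = detect_hbond(D, H, np.array([2.4, 2.1, 0.0]))
        assert geo.d_da == pytest.approx(np.sqrt(2.4**2 + 2.1**2), abs=1e-9)
        assert geo.deviation_deg == pytest.approx(
            np.degrees(np.arctan2(2.1, 2.4)), abs=1e-9
        )
        assert geo.deviation_deg > 40.0
        assert not geo.bonded

    def test_ties_at_cutoffs_count_as_bonded(self):
        geo = detect_hbond(D, H, np.array([3.3, 0.0, 0.0]))
        assert geo.d_da == 3.3 and geo.bonded
        # angle tie: a criterion whose cutoff equals the computed deviation
        a = 3.0 * np.array([np.cos(np.radians(40)), np.sin(np.radians(40)), 0.0])
        dev = detect_hbond(D, H, a).deviation_deg
        assert detect_hbond(D, H, a, HBondCriterion(3.3, dev)).bonded

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            detect_hbond(D, D, np.array([2.0, 0.0, 0.0]))

    def test_supplement_convention(self):
        """The alternative convention measures deviation of D-H...A from
        linearity at the hydrogen."""
        crit = HBondCriterion(convention="dha-supplement")
        # A almost in line with D->H beyond H: D-H...A nearly linear
        geo = detect_hbond(D, H, np.array([2.9, 0.1, 0.0]))
        geo_alt = detect_hbond(D, H, np.array([2.9, 0.1, 0.0]), crit)
        assert geo_alt.bonded
        assert geo_alt.deviation_deg == pytest.approx(
            180.0 - np.degrees(
                np.arccos(
                    np.dot(D - H, np.array([1.9, 0.1, 0.0]))
                    / (1.0 * np.linalg.norm([1.9, 0.1, 0.0]))
                )
            ),
            abs=1e-9,
        )
        assert geo.bonded  # default convention agrees here


def _toy_traj(site_acceptor, n_frames=1, site_donor=None, lig_o=(0.0, 0.0, 0.0)):
    """Minimal ligand (O-H donor) + site for direct frame tests."""
    atoms = [
        Atom("lig_O", "O", "donor", "ligand"),
        Atom("lig_H", "H", "hydrogen", "ligand", parent="lig_O"),
        Atom("site_A", "O", "acceptor", "site"),
    ]
    o = np.asarray(lig_o, dtype=float)
    frame = [o, o + np.array([1.0, 0.0, 0.0]), np.asarray(site_acceptor, dtype=float)]
    if site_donor is not None:
        d, h = site_donor
        atoms += [
            Atom("site_D", "N", "donor", "site"),
            Atom("site_DH", "H", "hydrogen", "site", parent="site_D"),
        ]
        frame += [np.asarray(d, float), np.asarray(h, float)]
    coords = np.tile(np.stack(frame), (n_frames, 1, 1))
    return Trajectory(atoms=atoms, coords=coords)


class TestFrameBonded:
    def test_no_partner_in_range(self):
        traj = _toy_traj(site_acceptor=(8.0, 0.0, 0.0))
        assert not frame_bonded(traj, 0)

    def test_single_qualifying_triple(self):
        traj = _toy_traj(site_acceptor=(2.9, 0.2, 0.0))
        assert frame_bonded(traj, 0)

    def test_ligand_as_acceptor_only(self):
        """Site donor-H pointing at the ligand O at 2.9 A, ~10 degrees."""
        ang = np.radians(10.0)
        d = np.array([2.9 * np.cos(ang), 2.9 * np.sin(ang), 0.0])
        h = d - np.array([1.0, 0.0, 0.0])  # H points back toward ligand O
        traj = _toy_traj(site_acceptor=(9.0, 9.0, 0.0), site_donor=(d, h))
        # ligand's own donor direction cannot reach the far site acceptor
        assert frame_bonded(traj, 0)

    def test_empty_partner_group_rejected(self):
        atoms = [
            Atom("lig_O", "O", "donor", "ligand"),
            Atom("lig_H", "H", "hydrogen", "ligand", parent="lig_O"),
        ]
        traj = Trajectory(atoms=atoms, coords=np.zeros((1, 2, 3)) + np.arange(2)[:, None])
        with pytest.raises(ValueError, match="partner"):
            frame_bonded(traj, 0)


class TestOccupancy:
    def _traj_with_indicator(self, indicator):
        """Frame i bonded iff indicator[i]: move the acceptor in or out."""
        n = len(indicator)
        traj = _toy_traj(site_acceptor=(2.9, 0.0, 0.0), n_frames=n)
        coords = traj.coords.copy()
        for i, b in enumerate(indicator):
            if not b:
                coords[i, 2] = [9.0, 9.0, 9.0]
        return Trajectory(atoms=traj.atoms, coords=coords)

    def test_prescribed_indicator_sequence(self):
        rng = np.random.default_rng(5)
        indicator = rng.random(200) < 0.35
        traj = self._traj_with_indicator(indicator)
        occ = occupancy(traj, burn_in_fraction=0.25)
        assert occ.frames_excluded == 50
        assert occ.p_hb == pytest.approx(indicator[50:].mean())

    def test_sixty_of_hundred_fifty(self):
        indicator = np.zeros(200, dtype=bool)
        indicator[50:110] = True  # 60 bonded frames in the retained window
        traj = self._traj_with_indicator(indicator)
        occ = occupancy(traj, burn_in_fraction=0.25)
        assert occ.p_hb == pytest.approx(0.4)
        assert occ.frames_used == 150

    def test_all_bonded(self):
        traj = self._traj_with_indicator(np.ones(40, dtype=bool))
        assert occupancy(traj, burn_in_fraction=0.25).p_hb == 1.0

    def test_invalid_burn_in_fraction_rejected(self):
        traj = self._traj_with_indicator(np.ones(1, dtype=bool))
        with pytest.raises(ValueError, match="burn_in_fraction"):
            occupancy(traj, burn_in_fraction=1.0)
        with pytest.raises(ValueError, match="burn_in_fraction"):
            occupancy(traj, burn_in_fraction=-0.1)

    def test_matches_exhaustive_frame_enumeration(self, thermo):
        """Vectorized occupancy equals a python loop over frame_bonded."""
        from alkylbind.systems import demo_interface_system
        from alkylbind.toysim import sample_trajectory

        traj = sample_trajectory(
            demo_interface_system("beta+/alpha-"), thermo, 1.0, 80, seed=21
        )
        occ = occupancy(traj, burn_in_fraction=0.25)
        flags = [frame_bonded(traj, i) for i in range(20, 80)]
        assert occ.p_hb == pytest.approx(np.mean(flags))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        indicator = rng.random(60) < 0.5
        traj = self._traj_with_indicator(indicator)
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        shift = np.array([5.0, -2.0, 11.0])
        moved = Trajectory(
            atoms=traj.atoms, coords=traj.coords @ R.T + shift
        )
        assert occupancy(moved, burn_in_fraction=0.25).p_hb == pytest.approx(
            occupancy(traj, burn_in_fraction=0.25).p_hb
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        d1=st.floats(min_value=2.0, max_value=5.0),
        d2=st.floats(min_value=2.0, max_value=5.0),
        a1=st.floats(min_value=10.0, max_value=170.0),
        a2=st.floats(min_value=10.0, max_value=170.0),
    )
    def test_monotone_in_criterion(self, d1, d2, a1, a2):
        """Enlarging either cutoff never decreases P_hb."""
        rng = np.random.default_rng(9)
        traj = _toy_traj(site_acceptor=(2.9, 0.4, 0.0), n_frames=30)
        coords = traj.coords + rng.normal(0, 0.8, traj.coords.shape)
        traj = Trajectory(atoms=traj.atoms, coords=coords)
        lo = HBondCriterion(min(d1, d2), min(a1, a2))
        hi = HBondCriterion(max(d1, d2), max(a1, a2))
        assert (
            occupancy(traj, hi, burn_in_fraction=0.0).p_hb
            >= occupancy(traj, lo, burn_in_fraction=0.0).p_hb
        )


@pytest.mark.parametrize(
    "p,expected",
    [
        (0.85, "high"),
        (0.25, "low"),
        (0.55, "intermediate"),
        (0.8, "intermediate"),  # thresholds are strict
        (0.3, "intermediate"),
        (1.0, "high"),
        (0.0, "low"),
    ],
)
def test_classification_thresholds(p, expected):
    assert classify_site_by_phb(p) == expected


def test_classification_rejects_invalid_probability():
    with pytest.raises(ValueError):
        classify_site_by_phb(1.2)
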