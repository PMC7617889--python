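"""Hydrogen-bond detection, network occupancy and RMSF statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kdelsolv.network import (
    DEFAULT_NETWORK,
    HBondCriterion,
    OccupancyReport,
    hbond_present,
    network_occupancy,
    pair_occupancy,
    rmsf,
)
from kdelsolv.toy_models import Frame, Trajectory, make_network_trajectory

from conftest import random_rotation


def dha_frame(d_a_distance, angle_deviation_deg=0.0):
    """Donor at origin, acceptor on x; hydrogen placed to give the
    requested donor–H–acceptor deviation from linearity."""
    d = np.array([0.0, 0.0, 0.0])
    a = np.array([d_a_distance, 0.0, 0.0])
    # isoceles construction: H midway in x, lifted so the D-H-A angle
    # equals 180° − deviation
    theta = np.radians(180.0 - angle_deviation_deg)
    half = d_a_distance / 2.0
    hy = half / np.tan(theta / 2.0) if theta < np.pi else 0.0
    h = np.array([half, hy, 0.0])
    labels = (("D", "don"), ("H", "hyd"), ("A", "acc"))
    return Frame(atom_labels=labels, coords=np.array([d, h, a]))


class TestHBondPresent:
    def test_inside_default_cutoffs(self):
        assert hbond_present(dha_frame(2.8, 10.0), "don", "acc", "hyd")

    def test_distance_boundary(self):
        assert not hbond_present(dha_frame(3.6, 0.0), "don", "acc", "hyd")

    def test_angle_boundary(self):
        assert not hbond_present(dha_frame(2.8, 45.0), "don", "acc", "hyd")

    def test_distance_only_mode_ignores_missing_hydrogen(self):
        crit = HBondCriterion(require_hydrogen=False)
        assert hbond_present(dha_frame(3.4), "don", "acc", criterion=crit)

    def test_strict_mode_demands_hydrogen(self):
        with pytest.raises(ValueError, match="hydrogen"):
            hbond_present(dha_frame(2.8), "don", "acc")

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            HBondCriterion(max_da_distance=-1.0)
        with pytest.raises(ValueError):
            HBondCriterion(max_angle_deviation=0.0)


class TestPairOccupancy:
    @pytest.mark.parametrize("n_bonded,expected", [(100, 1.0), (37, 0.37), (0, 0.0)])
    def test_frame_counting(self, n_bonded, expected):
        frames = [dha_frame(2.8 if i < n_bonded else 5.0) for i in range(100)]
        traj = Trajectory(frames=tuple(frames))
        occ = pair_occupancy(traj, "don", "acc", "hyd")
        assert occ == expected


class TestNetworkOccupancy:
    @pytest.mark.parametrize("fraction", [1.0, 0.6, 0.25, 0.0])
    def test_planted_fraction_recovered_exactly(self, fraction):
        traj = make_network_trajectory(100, fraction, seed=17)
        report = network_occupancy(traj)
        assert report.network_fraction == pytest.approx(fraction, abs=1e-12)

    def test_fully_bonded_fixture_per_pair(self):
        traj = make_network_trajectory(50, 1.0, seed=2)
        report = network_occupancy(traj)
        assert report.network_fraction == 1.0
        assert all(v == 1.0 for v in report.per_pair.values())

    @given(
        fraction=st.floats(0.0, 1.0),
        seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_network_fraction_bounded_by_pairs(self, fraction, seed):
        traj = make_network_trajectory(
            40, fraction, fluctuation_amplitudes=0.15, seed=seed
        )
        report = network_occupancy(traj)
        assert report.network_fraction <= min(report.per_pair.values()) + 1e-12

    def test_water_outside_region_breaks_network(self):
        traj = make_network_trajectory(10, 1.0, seed=3)
        # move W2 outside the pocket region but keep it H-bonded distance-wise
        frames = []
        w2 = traj.frames[0].index_of("W2:O")
        pep = traj.frames[0].index_of("PEP:C-term")
        for f in traj.frames:
            coords = f.coords.copy()
            shift = np.array([0.0, 4.0, 0.0])
            coords[w2] += shift
            coords[pep] = coords[w2] + np.array([2.8, 0.0, 0.0])
            frames.append(Frame(atom_labels=f.atom_labels, coords=coords))
        moved = Trajectory(frames=tuple(frames), region=traj.region)
        report = network_occupancy(moved)
        assert report.network_fraction == 0.0

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError, match="per-pair"):
            OccupancyReport(
                per_pair={("a", "b"): 0.3}, network_fraction=0.5, n_frames=10
            )


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        traj = make_network_trajectory(10, 1.0, seed=4)
        values = rmsf(traj)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in values.values())

    def test_two_point_alternation(self):
        a = 0.7
        labels = (("X", "atom"),)
        frames = tuple(
            Frame(atom_labels=labels, coords=[[(a if t % 2 else -a), 0.0, 0.0]])
            for t in range(10)
        )
        values = rmsf(Trajectory(frames=frames))
        assert values["atom"] == pytest.approx(a)

    def test_planted_amplitude_recovered(self):
        traj = make_network_trajectory(
            10000, 1.0, fluctuation_amplitudes={"PEP:C-term": 1.0}, seed=5
        )
        values = rmsf(traj)
        assert values["PEP:C-term"] == pytest.approx(1.0, rel=0.05)
        assert values["W1:O"] == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_ordering_preserved(self):
        traj = make_network_trajectory(
            4000, 1.0,
            fluctuation_amplitudes={"PEP:C-term": 1.5, "D9:O": 0.5},
            seed=6,
        )
        values = rmsf(traj)
        assert values["PEP:C-term"] > values["D9:O"]

    def test_single_frame_rejected(self):
        traj = make_network_trajectory(1, 1.0, seed=7)
        with pytest.raises(ValueError, match="two frames"):
            rmsf(traj)

    def test_translation_invariance_and_superposed_rotation_invariance(self):
        base = make_network_trajectory(200, 1.0, fluctuation_amplitudes=0.3, seed=8)
        rng = np.random.default_rng(9)
        const_shift = np.array([5.0, -3.0, 12.0])
        shifted, rotated = [], []
        for f in base.frames:
            t = rng.uniform(-3, 3, 3)
            R = random_rotation(rng)
            shifted.append(
                Frame(atom_labels=f.atom_labels, coords=f.coords + const_shift)
            )
            rotated.append(
                Frame(atom_labels=f.atom_labels, coords=f.coords @ R.T + t)
            )
        v0 = rmsf(base)
        v_shift = rmsf(Trajectory(frames=tuple(shifted)))
        for role in v0:
            assert v_shift[role] == pytest.approx(v0[role], abs=1e-9)
        v0_sup = rmsf(base, superpose=True)
        v_rot = rmsf(Trajectory(frames=tuple(rotated)), superpose=True)
        for role in v0:
            assert v_rot[role] == pytest.approx(v0_sup[role], abs=1e-9)
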