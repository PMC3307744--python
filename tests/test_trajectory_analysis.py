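"""Channel statistics, gate dihedral events, contacts, force profile, RMSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egresslab import (ChannelSpec, Trajectory, WorkSeries, channel_statistics,
                       classify_exit_channel, contact_series, force_profile,
                       gate_dihedral_series, rmsd_series)
from egresslab.ramd_engine import RAMDResult, RAMDParams

#: printed per-channel, per-snapshot success counts of the worked example
#: (three equilibrated snapshots, 135 runs total, 91 successful egresses)
EXAMPLE_COUNTS = pd.DataFrame(
    {
        "7ns": [9, 8, 3, 2, 3, 2, 1, 1, 1],
        "8ns": [8, 10, 2, 4, 0, 2, 3, 1, 1],
        "9ns": [12, 7, 3, 1, 1, 3, 2, 1, 0],
    },
    index=["2c", "2a", "2b", "2f", "3", "solvent", "water", "1", "2d"],
)


def _result(exit_vector, success=True):
    traj = Trajectory(times=np.array([0.0]),
                      positions=np.zeros((1, 2, 3)),
                      potential=np.zeros(1), kinetic=np.zeros(1))
    return RAMDResult(success=success, egress_time=1.0 if success else None,
                      exit_vector=np.asarray(exit_vector, dtype=float)
                      if success else None,
                      channel_label=None, n_redirections=0,
                      trajectory=traj, seed=0, params=RAMDParams())


CHANNELS = [ChannelSpec("2a", (0.0, 0.0, 1.0), 2.5),
            ChannelSpec("2c", (1.0, 0.0, 0.0), 2.5)]


class TestClassifyExitChannel:
    def test_exact_axis(self):
        assert classify_exit_channel(_result([0, 0, 9.0]), CHANNELS) == "2a"

    def test_orthogonal_is_other(self):
        assert classify_exit_channel(_result([0, 5.0, 0]), CHANNELS) == "other"

    def test_tie_broken_by_list_order(self):
        v = np.array([1.0, 0.0, 1.0])          # 45° from both axes
        assert classify_exit_channel(_result(v), CHANNELS,
                                     max_angle=50.0) == "2a"

    def test_failed_result_rejected(self):
        with pytest.raises(ValueError):
            classify_exit_channel(_result(None, success=False), CHANNELS)

    @given(st.floats(min_value=0.01, max_value=1e6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_magnitude(self, scale):
        v = np.array([0.1, 0.0, 1.0])
        v /= np.linalg.norm(v)
        assert classify_exit_channel(_result(v * scale), CHANNELS) == "2a"


class TestChannelStatistics:
    def test_worked_example_ratios(self):
        stats = channel_statistics(EXAMPLE_COUNTS)
        assert stats.grand_total == 91
        assert stats.table.loc["2c", "percent_0.1"] == pytest.approx(31.9)
        assert stats.table.loc["2a", "percent_0.1"] == pytest.approx(27.5)
        assert stats.table.loc["2c", "percent_int"] == 32
        assert stats.table.loc["2a", "percent_int"] == 27

    def test_combined_two_major_channels(self):
        stats = channel_statistics(EXAMPLE_COUNTS)
        combined = stats.ratio("2c") + stats.ratio("2a")
        assert round(100 * combined, 1) == pytest.approx(59.3)
        assert round(100 * combined) == 59

    def test_single_channel_hundred_percent(self):
        counts = pd.DataFrame({"s0": [5]}, index=["only"])
        stats = channel_statistics(counts)
        assert stats.ratio("only") == 1.0
        assert stats.table.loc["only", "percent_int"] == 100

    def test_ratios_sum_to_one(self):
        stats = channel_statistics(EXAMPLE_COUNTS)
        assert stats.table["ratio"].sum() == pytest.approx(1.0)
        assert abs(stats.table["percent_0.1"].sum() - 100.0) <= 0.2

    def test_all_zero_rejected(self):
        counts = pd.DataFrame({"s0": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            channel_statistics(counts)

    def test_negative_rejected(self):
        counts = pd.DataFrame({"s0": [3, -1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            channel_statistics(counts)


def _traj_from_positions(P):
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    return Trajectory(times=np.arange(n, dtype=float), positions=P,
                      potential=np.zeros(n), kinetic=np.zeros(n))


class TestGateDihedral:
    def _rotating_traj(self, total_deg, n_frames):
        """Terminal bead revolving about the z axis through (1,0,0)."""
        base = np.array([[0.0, -1.0, 0.0], [0.0, 0.0, 0.0],
                         [0.0, 0.0, 1.0], [1.0, 0.0, 1.5]])
        P = np.repeat(base[None, :, :], n_frames, axis=0)
        ang = np.radians(np.linspace(0.0, total_deg, n_frames))
        P[:, 3, 0] = np.cos(ang)
        P[:, 3, 1] = np.sin(ang)
        return _traj_from_positions(P)

    def test_static_cis_zero_no_events(self):
        base = np.array([[1.0, 0.0, -1.0], [0.0, 0.0, 0.0],
                         [0.0, 0.0, 1.0], [1.0, 0.0, 2.0]])
        traj = _traj_from_positions(np.repeat(base[None], 50, axis=0))
        ang, unw, events = gate_dihedral_series(traj, [0, 1, 2, 3])
        assert np.allclose(ang, 0.0, atol=1e-9)
        assert events == []

    def test_full_rotation_one_event(self):
        traj = self._rotating_traj(360.0, 400)
        _, unw, events = gate_dihedral_series(traj, [0, 1, 2, 3])
        assert len(events) == 1

    def test_constant_60_degrees_no_events(self):
        traj = self._rotating_traj(0.0, 100)
        P = traj.positions.copy()
        ang0 = np.radians(60.0)
        P[:, 3, 0] = np.cos(ang0)
        P[:, 3, 1] = np.sin(ang0)
        _, _, events = gate_dihedral_series(_traj_from_positions(P),
                                            [0, 1, 2, 3])
        assert events == []

    def test_two_rotations_two_events(self):
        traj = self._rotating_traj(720.0, 800)
        _, _, events = gate_dihedral_series(traj, [0, 1, 2, 3])
        assert len(events) == 2

    def test_collinear_frames_recorded_missing(self):
        base = np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 0.0],
                         [0.0, 0.0, 1.0], [0.0, 0.0, 2.0]])
        traj = _traj_from_positions(np.repeat(base[None], 5, axis=0))
        ang, _, _ = gate_dihedral_series(traj, [0, 1, 2, 3])
        assert np.all(np.isnan(ang))

    def test_duplicate_beads_rejected(self):
        traj = self._rotating_traj(0.0, 3)
        with pytest.raises(ValueError):
            gate_dihedral_series(traj, [0, 1, 1, 3])


class TestContactSeries:
    def test_contact_and_no_contact(self):
        P = np.zeros((2, 2, 3))
        P[0, 1, 0] = 2.0
        P[1, 1, 0] = 10.0
        out = contact_series(_traj_from_positions(P), [(0, 1)], cutoff=3.5)
        assert out[0, 0] and not out[1, 0]

    def test_radii_shift_surface_distance(self):
        P = np.zeros((1, 2, 3))
        P[0, 1, 0] = 5.0
        no_r = contact_series(_traj_from_positions(P), [(0, 1)], cutoff=3.5)
        with_r = contact_series(_traj_from_positions(P), [(0, 1)], cutoff=3.5,
                                radii=np.array([1.0, 1.0]))
        assert not no_r[0, 0] and with_r[0, 0]

    def test_bound_run_has_more_contacts_than_after_egress(self):
        # ligand sits next to a receptor bead, then leaves
        frames = 40
        P = np.zeros((frames, 2, 3))
        P[:, 1, 0] = np.concatenate([np.full(20, 2.0),
                                     np.linspace(2.0, 30.0, 20)])
        out = contact_series(_traj_from_positions(P), [(0, 1)], cutoff=3.5)
        assert out[:20].mean() > out[20:].mean()


class TestForceProfile:
    def _series(self, force):
        n = len(force)
        lam = np.linspace(0.0, 1.0 * (n - 1), n)
        return WorkSeries(times=lam.copy(), lam=lam, x_proj=lam,
                          force=np.asarray(force, dtype=float),
                          work=np.zeros(n))

    def test_window_one_identity(self):
        f = np.sin(np.linspace(0, 3, 50))
        lam, out = force_profile(self._series(f), 1)
        assert np.array_equal(out, f)

    def test_constant_preserved(self):
        lam, out = force_profile(self._series(np.full(30, 2.0)), 7)
        assert np.allclose(out, 2.0)

    def test_triangular_peak_position_preserved(self):
        f = np.concatenate([np.linspace(0, 5, 20), np.linspace(5, 0, 20)[1:]])
        w = 7
        lam, out = force_profile(self._series(f), w)
        assert abs(int(np.argmax(out)) - int(np.argmax(f))) <= w // 2

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            force_profile(self._series(np.ones(10)), 4)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            force_profile(self._series(np.ones(5)), 7)


class TestRmsdSeries:
    def test_self_reference_zero(self):
        rng = np.random.default_rng(0)
        P = np.repeat(rng.standard_normal((1, 6, 3)), 4, axis=0)
        assert np.allclose(rmsd_series(_traj_from_positions(P), 0, fit=True),
                           0.0, atol=1e-9)

    def test_rigid_translation_removed_by_fit(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((6, 3))
        P = np.stack([base, base + np.array([3.0, -2.0, 7.0])])
        out = rmsd_series(_traj_from_positions(P), 0, fit=True)
        assert out[1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_removed_by_fit(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(2)
        base = rng.standard_normal((8, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
        P = np.stack([base, base @ R.T])
        out = rmsd_series(_traj_from_positions(P), 0, fit=True)
        assert out[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_bead_arithmetic(self):
        n = 5
        base = np.zeros((n, 3))
        base[:, 0] = np.arange(n)
        moved = base.copy()
        moved[2, 1] += 2.0
        out = rmsd_series(_traj_from_positions(np.stack([base, moved])),
                          0, fit=False)
        assert out[1] == pytest.approx(2.0 / np.sqrt(n))

    def test_fitted_never_exceeds_unfitted(self):
        rng = np.random.default_rng(3)
        P = rng.standard_normal((5, 7, 3))
        fit = rmsd_series(_traj_from_positions(P), 0, fit=True)
        raw = rmsd_series(_traj_from_positions(P), 0, fit=False)
        assert np.all(fit <= raw + 1e-9)

    def test_too_few_beads_for_fit(self):
        P = np.zeros((2, 2, 3))
        with pytest.raises(ValueError):
            rmsd_series(_traj_from_positions(P), 0, fit=True)
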