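"""Pattern labeling, periodic centroids, kinematics and classification."""

import numpy as np
import pandas as pd
import pytest

from nfwaves import ModelParams
from nfwaves.simulator import Movie
from nfwaves.tracking import (
    KinematicSeries,
    Trajectory,
    center_of_mass,
    classify_state,
    kinematics,
    label_patterns,
    periodic_displacement,
    switching_lifetimes,
    track_patterns,
)


def _blob(n, cx, cy, sigma=3.0, spacing=1.0):
    x = np.arange(n) * spacing
    dom = n * spacing
    rx = (x - cx + dom / 2) % dom - dom / 2
    ry = (x - cy + dom / 2) % dom - dom / 2
    return np.exp(-(rx[:, None] ** 2 + ry[None, :] ** 2) / (2 * sigma ** 2))


class TestLabelPatterns:
    def test_single_blob_single_component(self):
        labs = label_patterns(_blob(64, 32, 32), 0.5)
        assert labs.max() == 1

    def test_wrapped_blob_not_split(self):
        # a blob straddling the domain edge is one component, not two
        labs = label_patterns(_blob(64, 1.0, 32.0), 0.5)
        assert labs.max() == 1

    def test_wrap_matches_flood_fill_oracle(self):
        # oracle: roll the field so the blob is interior, then label naively
        from scipy import ndimage

        f = _blob(64, 2.0, 62.0)
        labs = label_patterns(f, 0.5)
        rolled = np.roll(f, (30, -30), axis=(0, 1))
        oracle, n = ndimage.label(rolled > 0.5, structure=np.ones((3, 3)))
        assert labs.max() == n == 1
        assert (labs > 0).sum() == (oracle > 0).sum()

    def test_empty_field(self):
        assert label_patterns(np.zeros((32, 32)), 0.5).max() == 0

    def test_small_components_discarded(self):
        f = np.zeros((32, 32))
        f[5, 5] = 1.0  # single cell: below the 4-cell floor
        assert label_patterns(f, 0.5).max() == 0

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            label_patterns(np.zeros((8, 8)), 0.0)


class TestCenterOfMass:
    def test_symmetric_blob(self):
        f = _blob(64, 20.0, 44.0)
        com = center_of_mass(f > 0.3, f)
        assert com[0] == pytest.approx(20.0, abs=0.1)
        assert com[1] == pytest.approx(44.0, abs=0.1)

    def test_wrapped_blob_matches_unwrap_oracle(self):
        f = _blob(64, 1.5, 32.0)
        com = center_of_mass(f > 0.3, f)
        # oracle: shift by half the domain, compute the plain weighted mean,
        # shift back
        shifted = np.roll(f, 32, axis=0)
        mask = shifted > 0.3
        w = np.where(mask, shifted, 0.0)
        ix = np.sum(w.sum(axis=1) * np.arange(64)) / w.sum()
        expected_x = (ix - 32) % 64
        assert com[0] == pytest.approx(expected_x, abs=0.05)

    def test_two_cells_midpoint_shorter_arc(self):
        f = np.zeros((16, 16))
        f[0, 8] = 1.0
        f[15, 8] = 1.0  # neighbors across the wrap: midpoint at 15.5
        com = center_of_mass(f > 0, f)
        assert com[0] == pytest.approx(15.5, abs=1e-9)

    def test_empty_component(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros((8, 8), bool), np.zeros((8, 8)))


def _make_movie(coms, n=64, spacing=1.0, dt=0.5):
    frames = np.stack([
        sum(_blob(n, cx, cy, spacing=spacing) for cx, cy in pts)
        for pts in coms
    ])
    return Movie(frames=frames, times=np.arange(len(coms)) * dt, spacing=spacing)


class TestTracking:
    def test_no_identity_swap_for_separated_patterns(self):
        # two patterns far apart moving slowly: ids must stay put
        T = 30
        coms = [[(10.0 + 0.3 * t, 16.0), (40.0, 48.0)] for t in range(T)]
        movie = _make_movie(coms)
        trajs = track_patterns(movie, 0.5, 1.0)
        assert len(trajs) == 2
        trajs.sort(key=lambda tr: tr.x[0])
        moving, still = trajs
        assert len(moving.times) == T and len(still.times) == T
        assert moving.x[-1] - moving.x[0] == pytest.approx(0.3 * (T - 1), abs=0.2)
        assert abs(still.x[-1] - still.x[0]) < 0.2

    def test_trajectory_times_validated(self):
        with pytest.raises(ValueError):
            Trajectory(0, np.array([0.0, 0.0]), np.zeros(2), np.zeros(2), 64.0)

    def test_unwrap_crosses_boundary(self):
        T = 40
        coms = [[((60.0 + 0.5 * t) % 64, 32.0)] for t in range(T)]
        movie = _make_movie(coms)
        tr = track_patterns(movie, 0.5, 1.0)[0]
        ux, _ = tr.unwrapped()
        assert ux[-1] - ux[0] == pytest.approx(0.5 * (T - 1), abs=0.3)


class TestKinematics:
    def _traj(self, xs, ys, dt=0.5, dom=1000.0):
        t = np.arange(len(xs)) * dt
        return Trajectory(0, t, np.asarray(xs, float), np.asarray(ys, float), dom)

    def test_linear_motion(self):
        s = 1.7
        t = np.arange(60) * 0.5
        kin = kinematics(self._traj(5 + s * t, np.full_like(t, 3.0)))
        core = slice(15, -15)  # away from smoothing edge effects
        assert np.allclose(kin.v_tot[core], s, rtol=1e-6)
        assert np.allclose(kin.a_tot[core], 0.0, atol=1e-6)

    def test_circular_motion(self):
        R, om = 5.0, 0.3
        t = np.arange(200) * 0.2
        kin = kinematics(self._traj(50 + R * np.cos(om * t), 50 + R * np.sin(om * t),
                                    dt=0.2))
        core = slice(30, -30)
        assert np.allclose(kin.v_tot[core], R * om, rtol=0.02)
        assert np.allclose(kin.a_tot[core], R * om ** 2, rtol=0.05)

    def test_stationary(self):
        kin = kinematics(self._traj(np.full(40, 7.0), np.full(40, 9.0)))
        assert np.all(kin.v_tot == 0)
        assert np.all(kin.a_tot == 0)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            kinematics(self._traj(np.arange(10.0), np.arange(10.0)))


class TestClassifyState:
    def _kin(self, xs, ys, dt=0.2):
        t = np.arange(len(xs)) * dt
        tr = Trajectory(0, t, np.asarray(xs, float), np.asarray(ys, float), 1e6)
        return kinematics(tr)

    def test_circle_is_rotating(self):
        t = np.arange(400) * 0.2
        kin = self._kin(50 + 5 * np.cos(0.4 * t), 50 + 5 * np.sin(0.4 * t))
        df = classify_state(kin, v_eps=0.1, a_eps=0.1)
        mid = df[(df.t_mid > 10) & (df.t_mid < 70)]
        assert (mid.label == "rotating").mean() > 0.9

    def test_line_is_traveling(self):
        t = np.arange(400) * 0.2
        kin = self._kin(2 * t, np.zeros_like(t))
        df = classify_state(kin, v_eps=0.1, a_eps=0.1)
        mid = df[(df.t_mid > 10) & (df.t_mid < 70)]
        assert (mid.label == "traveling").mean() > 0.9

    def test_still_is_bump(self):
        kin = self._kin(np.full(200, 3.0), np.full(200, 4.0))
        df = classify_state(kin, v_eps=0.1, a_eps=0.1)
        assert (df.label == "bump").all()


class TestSwitchingLifetimes:
    def _states(self, labels, window=2.0):
        t = np.arange(len(labels)) * window / 2
        return pd.DataFrame({
            "t_start": t, "t_mid": t + window / 2,
            "v_tot": 1.0, "a_tot": 0.0, "label": labels,
        })

    def test_single_state_single_dwell(self):
        rep = switching_lifetimes(self._states(["rotating"] * 40), transient=0.0)
        assert rep.transitions == 0
        assert rep.n_dwells == {"rotating": 1}

    def test_dwells_partition_duration(self):
        labels = ["rotating"] * 20 + ["traveling"] * 15 + ["rotating"] * 25
        rep = switching_lifetimes(self._states(labels), transient=0.0,
                                  min_dwell_windows=2)
        total = sum(d[2] for d in rep.dwells)
        assert total == pytest.approx((len(labels) - 1) * 1.0 + 1.0, rel=0.1)
        assert rep.transitions == 2

    def test_flicker_absorbed(self):
        labels = ["rotating"] * 30 + ["traveling"] * 2 + ["rotating"] * 30
        rep = switching_lifetimes(self._states(labels), transient=0.0,
                                  min_dwell_windows=4)
        assert rep.transitions == 0
        assert set(rep.n_dwells) == {"rotating"}

    def test_empty_series(self):
        rep = switching_lifetimes(self._states([]), transient=0.0)
        assert rep.transitions == 0 and rep.dwells == []


class TestPeriodicDisplacement:
    def test_minimal_image(self):
        assert periodic_displacement((1.0, 1.0), (63.0, 63.0), 64.0) == (2.0, 2.0)
        assert periodic_displacement((10.0, 5.0), (12.0, 5.0), 64.0) == (-2.0, 0.0)
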