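"""Pattern tracking, kinematics and dynamical-state classification.

Localized patterns are extracted per frame as thresholded connected
components (8-connectivity with periodic wrap), tracked across frames by
nearest periodic center-of-mass distance, and classified from their
velocity/acceleration signatures:

* **bump** — essentially stationary (v_tot below threshold),
* **traveling** — steady motion with negligible total acceleration,
* **rotating** — steady motion on a curved orbit: positive, near-constant
  v_tot and a_tot.

At the level of a whole simulation the dominant behavior defines a regime:
I rotating, II traveling, III unstable/splitting (component count grows),
IV global (activity spans the domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulator import Movie

__all__ = [
    "Trajectory",
    "KinematicSeries",
    "label_patterns",
    "center_of_mass",
    "periodic_displacement",
    "track_patterns",
    "kinematics",
    "classify_state",
    "classify_regime",
    "RegimeReport",
    "switching_lifetimes",
    "LifetimeReport",
]

REGIMES = ("I", "II", "III", "IV")


def label_patterns(f: np.ndarray, threshold: float, min_cells: int = 4) -> np.ndarray:
    """Connected components of {f > threshold} with periodic 8-connectivity.

    Returns an int grid: 0 background, 1..k component ids.  Components
    smaller than ``min_cells`` cells are discarded.  ``threshold`` is an
    absolute level; callers typically pass a fraction of the bump interior
    value f_in.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    mask = f > threshold
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels
    # merge labels that touch across the periodic edges (union-find)
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    nrow, ncol = labels.shape
    for j in range(ncol):
        for dj in (-1, 0, 1):
            a, b = labels[0, j], labels[-1, (j + dj) % ncol]
            if a and b:
                union(a, b)
    for i in range(nrow):
        for di in (-1, 0, 1):
            a, b = labels[i, 0], labels[(i + di) % nrow, -1]
            if a and b:
                union(a, b)

    roots = np.array([find(a) for a in range(n + 1)])
    labels = roots[labels]
    # drop small components and relabel densely
    out = np.zeros_like(labels)
    next_id = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        if m.sum() < min_cells:
            continue
        out[m] = next_id
        next_id += 1
    return out


def center_of_mass(mask: np.ndarray, f: np.ndarray, spacing: float = 1.0):
    """f-weighted centroid of a component via the circular mean per axis,
    exact for components wrapped across the periodic boundary."""
    w = np.where(mask, f, 0.0)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("component has zero total weight")
    out = []
    for axis in (0, 1):
        n = f.shape[axis]
        ang = 2.0 * np.pi * np.arange(n) / n
        wa = w.sum(axis=1 - axis)
        z = np.sum(wa * np.exp(1j * ang)) / tot
        out.append((np.angle(z) % (2 * np.pi)) / (2 * np.pi) * n * spacing)
    return tuple(out)


def periodic_displacement(a, b, domain: float):
    """Minimal-image displacement a - b on a periodic square of side domain."""
    return tuple((ai - bi + domain / 2) % domain - domain / 2 for ai, bi in zip(a, b))


@dataclass
class Trajectory:
    """Center-of-mass path of one tracked pattern."""

    pattern_id: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    domain: float

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def unwrapped(self):
        """(x, y) lifted off the torus by accumulating minimal-image steps."""
        ux = [self.x[0]]
        uy = [self.y[0]]
        for i in range(1, len(self.x)):
            dx, dy = periodic_displacement(
                (self.x[i], self.y[i]), (self.x[i - 1], self.y[i - 1]), self.domain
            )
            ux.append(ux[-1] + dx)
            uy.append(uy[-1] + dy)
        return np.asarray(ux), np.asarray(uy)


def track_patterns(
    movie: Movie, threshold_frac: float, f_in: float, min_cells: int = 4
) -> list[Trajectory]:
    """Track components across frames by nearest periodic COM matching.

    A component inherits the id of the closest pattern in the previous frame
    (greedy, nearest first); unmatched components open new tracks.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold fraction must lie in (0, 1)")
    dom = movie.domain
    thresh = threshold_frac * f_in
    tracks: dict[int, dict] = {}
    prev: dict[int, tuple[float, float]] = {}
    next_id = 0
    for i in range(movie.n_frames):
        f = movie.frames[i]
        labs = label_patterns(f, thresh, min_cells=min_cells)
        coms = []
        for lab in range(1, labs.max() + 1):
            coms.append(center_of_mass(labs == lab, f, movie.spacing))
        pairs = []
        for j, com in enumerate(coms):
            for pid, pcom in prev.items():
                d = np.hypot(*periodic_displacement(com, pcom, dom))
                pairs.append((d, j, pid))
        pairs.sort()
        assigned_j: set[int] = set()
        assigned_p: set[int] = set()
        current: dict[int, tuple[float, float]] = {}
        for d, j, pid in pairs:
            if j in assigned_j or pid in assigned_p:
                continue
            assigned_j.add(j)
            assigned_p.add(pid)
            current[pid] = coms[j]
            tracks[pid]["t"].append(movie.times[i])
            tracks[pid]["x"].append(coms[j][0])
            tracks[pid]["y"].append(coms[j][1])
        for j, com in enumerate(coms):
            if j in assigned_j:
                continue
            pid = next_id
            next_id += 1
            tracks[pid] = {"t": [movie.times[i]], "x": [com[0]], "y": [com[1]]}
            current[pid] = com
        prev = current
    return [
        Trajectory(
            pattern_id=pid,
            times=np.asarray(tr["t"]),
            x=np.asarray(tr["x"]),
            y=np.asarray(tr["y"]),
            domain=dom,
        )
        for pid, tr in tracks.items()
        if len(tr["t"]) > 1
    ]


@dataclass
class KinematicSeries:
    """Smoothed velocity and acceleration series of one trajectory.

    Velocities are central differences of the unwrapped path, smoothed with
    a 10-point moving average; accelerations are central differences of the
    smoothed velocity, smoothed the same way.  Units: field units per
    rescaled time (and per rescaled time squared)."""

    times: np.ndarray
    v_x: np.ndarray
    v_y: np.ndarray
    v_tot: np.ndarray
    a_tot: np.ndarray


def _moving_average(x, w=10):
    kern = np.ones(w) / w
    return np.convolve(x, kern, mode="same")


def kinematics(traj: Trajectory, smooth: int = 10) -> KinematicSeries:
    """Velocity/acceleration series from a trajectory (>= 21 samples)."""
    if len(traj.times) < 21:
        raise ValueError("trajectory too short for kinematics (need >= 21 samples)")
    ux, uy = traj.unwrapped()
    t = traj.times
    dt = float(np.mean(np.diff(t)))
    vx = np.gradient(ux, dt)
    vy = np.gradient(uy, dt)
    vx = _moving_average(vx, smooth)
    vy = _moving_average(vy, smooth)
    ax = _moving_average(np.gradient(vx, dt), smooth)
    ay = _moving_average(np.gradient(vy, dt), smooth)
    return KinematicSeries(
        times=t, v_x=vx, v_y=vy,
        v_tot=np.hypot(vx, vy), a_tot=np.hypot(ax, ay),
    )


def classify_state(
    kin: KinematicSeries,
    v_eps: float,
    a_eps: float,
    window: float = 2.0,
    rel_std_max: float = 0.25,
) -> pd.DataFrame:
    """Label 50%-overlapping windows as bump / traveling / rotating.

    bump: mean v_tot < v_eps.  traveling: moving with mean a_tot < a_eps.
    rotating: both means above threshold and near-constant (relative std of
    v_tot below ``rel_std_max``).  Everything else is 'unclassified'.
    ``window`` is in rescaled time units (2.0 = 20 ms at tau = 10 ms).
    """
    t = kin.times
    rows = []
    start = t[0]
    while start + window <= t[-1] + 1e-12:
        m = (t >= start) & (t < start + window)
        if m.sum() >= 2:
            v = kin.v_tot[m]
            a = kin.a_tot[m]
            vm, am = v.mean(), a.mean()
            if vm < v_eps:
                lab = "bump"
            elif am < a_eps:
                lab = "traveling"
            elif v.std() < rel_std_max * vm:
                lab = "rotating"
            else:
                lab = "unclassified"
            rows.append({
                "t_start": start, "t_mid": start + window / 2,
                "v_tot": vm, "a_tot": am, "label": lab,
            })
        start += window / 2
    return pd.DataFrame(rows)


@dataclass
class RegimeReport:
    regime: str
    component_counts: np.ndarray
    state_votes: dict = field(default_factory=dict)


def classify_regime(
    movie: Movie,
    f_in: float,
    threshold_frac: float = 0.5,
    transient: float = 5.0,
    v_eps: float | None = None,
    a_eps: float | None = None,
    area_frac_global: float = 0.25,
) -> RegimeReport:
    """Assign one of the four dynamical regimes to a movie.

    IV (global) if any component covers > ``area_frac_global`` of the domain;
    III (unstable/splitting) if the post-transient component count grows;
    otherwise I (rotating) or II (traveling) by majority vote of windowed
    state labels of the longest-lived pattern.  ``transient`` is skipped
    (rescaled time; 5.0 = 50 ms at tau = 10 ms).
    """
    if movie.times[-1] <= transient:
        raise ValueError("movie shorter than the transient window")
    thresh = threshold_frac * f_in
    post = movie.times >= transient
    n_cells = movie.frames.shape[1] * movie.frames.shape[2]

    counts = []
    max_area_frac = 0.0
    for i in np.where(post)[0]:
        labs = label_patterns(movie.frames[i], thresh)
        k = labs.max()
        counts.append(k)
        if k:
            areas = np.bincount(labs.ravel())[1:]
            max_area_frac = max(max_area_frac, areas.max() / n_cells)
    counts = np.asarray(counts)

    if max_area_frac > area_frac_global:
        return RegimeReport("IV", counts)
    early = counts[: max(1, len(counts) // 5)]
    late = counts[-max(1, len(counts) // 5):]
    if np.median(late) > np.median(early) and late.max() > 1:
        return RegimeReport("III", counts)

    if v_eps is None:
        v_eps = 0.05 * movie.spacing * movie.tau  # 0.05 cells/ms
    if a_eps is None:
        a_eps = 0.2 * v_eps
    trajs = track_patterns(movie, threshold_frac, f_in)
    trajs = [tr for tr in trajs if len(tr.times) >= 21]
    if not trajs:
        return RegimeReport("I", counts, {"note": "no trackable pattern"})
    main = max(trajs, key=lambda tr: len(tr.times))
    kin = kinematics(main)
    states = classify_state(kin, v_eps=v_eps, a_eps=a_eps)
    states = states[states["t_mid"] >= transient]
    votes = states["label"].value_counts().to_dict()
    rot = votes.get("rotating", 0)
    trav = votes.get("traveling", 0)
    regime = "I" if rot > trav else "II"
    return RegimeReport(regime, counts, votes)


@dataclass
class LifetimeReport:
    """Dwell-time statistics of the rotating/traveling label series."""

    mean_lifetime: dict  # label -> mean dwell, rescaled time units
    n_dwells: dict
    transitions: int
    dwells: list  # (label, start, duration)

    def mean_lifetime_ms(self, tau: float = 10.0) -> dict:
        return {k: v * tau for k, v in self.mean_lifetime.items()}


def switching_lifetimes(
    states: pd.DataFrame,
    transient: float = 5.0,
    min_dwell_windows: int = 2,
) -> LifetimeReport:
    """Segment a windowed label series into dwell intervals per state.

    Dwells shorter than ``min_dwell_windows`` consecutive windows are merged
    into their neighbors (label flicker at the classification threshold is
    not a physical transition).  Lifetimes are means of the dwell durations;
    open-ended final dwells are included.
    """
    seq = states[states["t_mid"] >= transient].reset_index(drop=True)
    if seq.empty:
        return LifetimeReport({}, {}, 0, [])
    labels = list(seq["label"])
    times = list(seq["t_start"])
    step = times[1] - times[0] if len(times) > 1 else 0.0

    # collapse runs, absorbing runs shorter than min_dwell_windows
    runs: list[list] = []  # [label, n_windows]
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (lab, cnt) in enumerate(runs):
            if cnt < min_dwell_windows:
                neighbor = i - 1 if i > 0 else i + 1
                runs[neighbor][1] += cnt
                runs.pop(i)
                changed = True
                break
        merged = []
        for lab, cnt in runs:
            if merged and merged[-1][0] == lab:
                merged[-1][1] += cnt
            else:
                merged.append([lab, cnt])
        runs = merged

    dwells = []
    t = times[0]
    for lab, cnt in runs:
        dwells.append((lab, t, cnt * step))
        t += cnt * step
    mean_lt: dict[str, float] = {}
    n_dw: dict[str, int] = {}
    for lab in set(r[0] for r in runs):
        durs = [d for (l, _s, d) in dwells if l == lab]
        mean_lt[lab] = float(np.mean(durs))
        n_dw[lab] = len(durs)
    return LifetimeReport(mean_lt, n_dw, transitions=len(runs) - 1, dwells=dwells)
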