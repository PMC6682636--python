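"""Direct numerical integration of the two-variable neural field.

The field evolves the firing probability f and refractory deficit h on a
periodic square lattice,

    df/dt = -f + (1 - f - h) H(u - kappa) [+ mu]
    dh/dt = -p h + f                      [- mu]

with u = w * f computed by circular FFT convolution with the sampled kernel
and H the Heaviside step with H(0) = 1.  Time is in rescaled (membrane-tau)
units; multiplicative noise mu = f * xi (xi i.i.d. Gaussian per cell, held
fixed within each Runge-Kutta step) models fluctuating drive that vanishes
where the field is silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.fft import irfft2, rfft2

from .kernel import KernelParams, eval_kernel
from .solutions import ModelParams

__all__ = [
    "FieldState",
    "NoiseSpec",
    "SimConfig",
    "Movie",
    "sample_kernel_grid",
    "synaptic_input",
    "rk4_step",
    "simulate",
    "make_initial",
    "save_movie",
    "load_movie",
]

_NOISE_MODES = ("off", "single_kick", "continuous")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise configuration: standard deviation sigma_xi, RNG seed, and mode
    (off / single_kick / continuous)."""

    sigma_xi: float = 0.0
    seed: int = 0
    mode: str = "off"

    def __post_init__(self):
        if self.sigma_xi < 0:
            raise ValueError("sigma_xi must be non-negative")
        if self.mode not in _NOISE_MODES:
            raise ValueError(f"noise mode must be one of {_NOISE_MODES}")


@dataclass(frozen=True)
class FieldState:
    """The (f, h) occupation grids at one instant on a periodic square grid."""

    f: np.ndarray
    h: np.ndarray
    spacing: float
    time: float = 0.0

    def __post_init__(self):
        if self.f.shape != self.h.shape or self.f.ndim != 2:
            raise ValueError("f and h must be 2D grids of identical shape")
        if np.any(self.f < 0) or np.any(self.h < 0) or np.any(self.f + self.h > 1 + 1e-9):
            raise ValueError("state must satisfy 0 <= f, 0 <= h, f + h <= 1")

    @property
    def domain(self) -> float:
        """Side length of the periodic square, field units."""
        return self.f.shape[0] * self.spacing


@dataclass(frozen=True)
class SimConfig:
    """Grid, step and model configuration for a simulation run.

    Defaults mirror the reference setup: 601 x 601 cells at 0.1 mm spacing
    (1 field unit per cell), dt = 0.01 rescaled time (0.1 ms at tau = 10 ms),
    kappa = 1, p = 0.42.
    """

    grid_n: int = 601
    spacing: float = 1.0
    dt: float = 0.01
    duration: float = 1.0
    snapshot_stride: int = 10
    kernel: KernelParams = field(
        default_factory=lambda: KernelParams(144.4, 73.7, 1.87, 3.24)
    )
    model: ModelParams = field(default_factory=ModelParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.grid_n < 8:
            raise ValueError("grid_n must be at least 8")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def sample_kernel_grid(config: SimConfig) -> np.ndarray:
    """Sample the radial kernel on the periodic lattice (minimal-image
    distances), scaled by the cell area so that FFT convolution is the
    Riemann sum of the continuum integral."""
    n, dx = config.grid_n, config.spacing
    x = np.arange(n) * dx
    dmin = np.minimum(x, n * dx - x)
    r = np.hypot(dmin[:, None], dmin[None, :])
    return eval_kernel(r, config.kernel) * dx * dx


def synaptic_input(f: np.ndarray, kernel_grid: np.ndarray) -> np.ndarray:
    """u = w * f by circular convolution; kernel_grid from sample_kernel_grid."""
    if f.shape != kernel_grid.shape:
        raise ValueError("field and kernel grid shapes differ")
    return irfft2(rfft2(kernel_grid) * rfft2(f), s=f.shape)


class _StepWorkspace:
    """Precomputed kernel FFT reused across steps."""

    def __init__(self, config: SimConfig):
        self.kernel_fft = rfft2(sample_kernel_grid(config))
        self.shape = (config.grid_n, config.grid_n)
        self.clamp_count = 0

    def u(self, f):
        return irfft2(self.kernel_fft * rfft2(f), s=self.shape)


def _rhs(f, h, mu, ws: _StepWorkspace, model: ModelParams):
    act = ws.u(f) >= model.kappa  # Heaviside with H(0) = 1
    df = -f + (1.0 - f - h) * act
    dh = -model.p * h + f
    if mu is not None:
        df = df + mu
        dh = dh - mu
    return df, dh


def rk4_step(
    state: FieldState,
    config: SimConfig,
    workspace: _StepWorkspace | None = None,
    rng: np.random.Generator | None = None,
) -> FieldState:
    """One classical fourth-order Runge-Kutta step.

    In continuous-noise mode a fresh mu = f * xi grid is drawn at the start
    of the step and held fixed through the four stages.  After the update the
    probabilistic bounds are restored by clamping (events are counted on the
    workspace).  Raises FloatingPointError on NaN/Inf.
    """
    ws = workspace if workspace is not None else _StepWorkspace(config)
    model, dt = config.model, config.dt

    mu = None
    if config.noise.mode == "continuous" and config.noise.sigma_xi > 0:
        if rng is None:
            rng = np.random.default_rng(config.noise.seed)
        mu = state.f * (config.noise.sigma_xi * rng.standard_normal(state.f.shape))

    f, h = state.f, state.h
    k1f, k1h = _rhs(f, h, mu, ws, model)
    k2f, k2h = _rhs(f + 0.5 * dt * k1f, h + 0.5 * dt * k1h, mu, ws, model)
    k3f, k3h = _rhs(f + 0.5 * dt * k2f, h + 0.5 * dt * k2h, mu, ws, model)
    k4f, k4h = _rhs(f + dt * k3f, h + dt * k3h, mu, ws, model)
    fn = f + dt / 6.0 * (k1f + 2 * k2f + 2 * k3f + k4f)
    hn = h + dt / 6.0 * (k1h + 2 * k2h + 2 * k3h + k4h)

    if not (np.isfinite(fn).all() and np.isfinite(hn).all()):
        raise FloatingPointError(
            f"non-finite field values at t = {state.time + dt:.4f}"
        )

    # clamp back to the probabilistic simplex
    bad = (fn < 0) | (fn > 1) | (hn < 0) | (hn > 1)
    np.clip(fn, 0.0, 1.0, out=fn)
    np.clip(hn, 0.0, 1.0, out=hn)
    over = fn + hn > 1.0
    if over.any():
        hn[over] = 1.0 - fn[over]
    ws.clamp_count += int(bad.sum() + over.sum())

    return FieldState(f=fn, h=hn, spacing=state.spacing, time=state.time + dt)


@dataclass
class Movie:
    """A snapshot sequence of f (and optionally h) grids."""

    frames: np.ndarray  # (T, n, n)
    times: np.ndarray  # rescaled time units
    spacing: float
    h_frames: np.ndarray | None = None
    tau: float = 10.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def domain(self) -> float:
        return self.frames.shape[1] * self.spacing

    @property
    def frame_interval(self) -> float:
        """Interval between stored frames in rescaled time units."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def center_of_mass(self, i: int) -> tuple[float, float]:
        """f-weighted circular centroid of frame i (whole-field)."""
        f = self.frames[i]
        tot = f.sum()
        if tot <= 0:
            raise ValueError("empty frame has no center of mass")
        n = f.shape[0]
        ang = 2.0 * np.pi * np.arange(n) / n
        out = []
        for axis_weights in (f.sum(axis=1), f.sum(axis=0)):
            z = np.sum(axis_weights * np.exp(1j * ang)) / tot
            out.append((np.angle(z) % (2 * np.pi)) / (2 * np.pi) * n * self.spacing)
        return tuple(out)


def simulate(
    initial: FieldState, config: SimConfig, keep_h: bool = False
) -> tuple[Movie, dict]:
    """Integrate the field for ``config.duration``, storing every
    ``snapshot_stride``-th step (snapshot 0 is the initial state).

    Returns the movie and a metadata dict with step/clamp counts and the
    noise seed.  Bit-reproducible for a fixed seed and config.
    """
    ws = _StepWorkspace(config)
    rng = np.random.default_rng(config.noise.seed)

    state = initial
    if config.noise.mode == "single_kick" and config.noise.sigma_xi > 0:
        kicked = state.f + config.noise.sigma_xi * rng.standard_normal(state.f.shape)
        np.clip(kicked, 0.0, 1.0, out=kicked)
        h = np.minimum(state.h, 1.0 - kicked)
        state = replace(state, f=kicked, h=h)

    frames = [state.f.copy()]
    hs = [state.h.copy()] if keep_h else None
    times = [state.time]
    for step in range(1, config.n_steps + 1):
        state = rk4_step(state, config, workspace=ws, rng=rng)
        if step % config.snapshot_stride == 0:
            frames.append(state.f.copy())
            times.append(state.time)
            if keep_h:
                hs.append(state.h.copy())
    movie = Movie(
        frames=np.asarray(frames),
        times=np.asarray(times),
        spacing=config.spacing,
        h_frames=np.asarray(hs) if keep_h else None,
        tau=config.model.tau,
    )
    meta = {
        "n_steps": config.n_steps,
        "clamp_count": ws.clamp_count,
        "noise_mode": config.noise.mode,
        "sigma_xi": config.noise.sigma_xi,
        "seed": config.noise.seed,
    }
    return movie, meta


# -- initial-condition builders -------------------------------------------

def make_initial(kind: str, config: SimConfig, seed: int | None = None, **spec) -> FieldState:
    """Build an initial FieldState.

    kinds:
      * ``bump`` (spec: rho, center) — rasterized stationary bump
      * ``wave1d_strip`` (spec: wave, front_x) — planar wave, front along y
      * ``wave2d`` (spec: shape, center, angle) — teardrop traveling wave
      * ``random_waves`` (spec: shape, n) — n teardrops at random positions
        and orientations, rejection-sampled so patterns keep a pairwise
        margin of 2 sigma_I
    """
    from .solutions import wave1d_profile  # local to avoid import cycles
    from .wave2d import build_wave2d_state

    n, dx = config.grid_n, config.spacing
    dom = n * dx
    model = config.model
    rng = np.random.default_rng(seed)

    if kind == "bump":
        rho = spec["rho"]
        center = spec.get("center", (dom / 2, dom / 2))
        x = np.arange(n) * dx
        rx = (x - center[0] + dom / 2) % dom - dom / 2
        ry = (x - center[1] + dom / 2) % dom - dom / 2
        r = np.hypot(rx[:, None], ry[None, :])
        inside = r <= rho
        f = np.where(inside, model.f_in, 0.0)
        h = np.where(inside, model.h_in, 0.0)
        return FieldState(f=f, h=h, spacing=dx)

    if kind == "wave1d_strip":
        wave = spec["wave"]
        front_x = spec.get("front_x", dom * 0.5)
        x = np.arange(n) * dx
        xi = (x - front_x + dom / 2) % dom - dom / 2
        F, H = wave1d_profile(xi, wave, model)
        f = np.repeat(F[:, None], n, axis=1)
        h = np.repeat(H[:, None], n, axis=1)
        return FieldState(f=f, h=h, spacing=dx)

    if kind == "wave2d":
        shape = spec["shape"]
        center = spec.get("center", (dom / 2, dom / 2))
        angle = spec.get("angle", 0.0)
        return build_wave2d_state(shape, model, config, direction=angle, center=center)

    if kind == "random_waves":
        shape = spec["shape"]
        count = spec.get("n", 7)
        margin = 2.0 * config.kernel.sigma_I
        radius = max(shape.L_f, shape.L_t, shape.L_w)
        placed: list[tuple[float, float]] = []
        f = np.zeros((n, n))
        h = np.zeros((n, n))
        attempts = 0
        while len(placed) < count:
            attempts += 1
            if attempts > 1000:
                raise RuntimeError(
                    f"could not place {count} waves after 1000 attempts"
                )
            c = tuple(rng.uniform(0, dom, size=2))
            if any(
                np.hypot((c[0] - q[0] + dom / 2) % dom - dom / 2,
                         (c[1] - q[1] + dom / 2) % dom - dom / 2)
                < 2 * radius + margin
                for q in placed
            ):
                continue
            ang = rng.uniform(0, 2 * np.pi)
            st = build_wave2d_state(shape, model, config, direction=ang, center=c)
            f += st.f
            h += st.h
            placed.append(c)
        np.clip(f, 0.0, 1.0, out=f)
        h = np.minimum(h, 1.0 - f)
        return FieldState(f=f, h=h, spacing=dx)

    raise ValueError(f"unknown initial-condition kind: {kind!r}")


def perturb_multiplicative(state: FieldState, amplitude: float, seed: int) -> FieldState:
    """Apply a single multiplicative perturbation f -> f (1 + amplitude xi),
    xi i.i.d. standard Gaussian per cell — the one-shot analogue of the
    model's mu = f * xi noise.  Silent regions stay silent."""
    rng = np.random.default_rng(seed)
    f = np.clip(state.f * (1.0 + amplitude * rng.standard_normal(state.f.shape)), 0.0, 1.0)
    return replace(state, f=f, h=np.minimum(state.h, 1.0 - f))


def simulate_line(
    wave,
    params: KernelParams,
    model: ModelParams,
    n: int = 1024,
    spacing: float = 0.25,
    dt: float = 0.01,
    duration: float = 40.0,
    snapshot_stride: int = 100,
):
    """Integrate the field on a periodic 1D line seeded with a traveling wave.

    Uses the same transverse-integrated kernel as the 1D solver, so a solved
    (c, L) wave should propagate at its analytic speed.  Returns (times,
    center positions unwrapped, measured speed) where the speed is the slope
    of the center-of-mass path after discarding the first quarter of the run.
    """
    from .solutions import line_kernel, wave1d_profile

    dom = n * spacing
    x = np.arange(n) * spacing
    xi = (x - 0.3 * dom + dom / 2) % dom - dom / 2
    f, h = wave1d_profile(xi, wave, model)
    f = f.copy()
    h = h.copy()

    dmin = np.minimum(x, dom - x)
    ker = line_kernel(dmin, params) * spacing
    kf = np.fft.rfft(ker)

    def u_of(ff):
        return np.fft.irfft(kf * np.fft.rfft(ff), n=n)

    def rhs(ff, hh):
        act = u_of(ff) >= model.kappa
        return -ff + (1.0 - ff - hh) * act, -model.p * hh + ff

    times = []
    centers = []
    ang = 2.0 * np.pi * x / dom
    for step in range(int(round(duration / dt)) + 1):
        if step % snapshot_stride == 0:
            z = np.sum(f * np.exp(1j * ang)) / max(f.sum(), 1e-300)
            times.append(step * dt)
            centers.append((np.angle(z) % (2 * np.pi)) / (2 * np.pi) * dom)
        k1 = rhs(f, h)
        k2 = rhs(f + 0.5 * dt * k1[0], h + 0.5 * dt * k1[1])
        k3 = rhs(f + 0.5 * dt * k2[0], h + 0.5 * dt * k2[1])
        k4 = rhs(f + dt * k3[0], h + dt * k3[1])
        f += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        h += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        np.clip(f, 0.0, 1.0, out=f)
        np.clip(h, 0.0, 1.0, out=h)

    times = np.asarray(times)
    centers = np.unwrap(np.asarray(centers) * 2 * np.pi / dom) * dom / (2 * np.pi)
    m = times >= duration / 4.0
    speed = float(np.polyfit(times[m], centers[m], 1)[0])
    return times, centers, speed


# -- persistence -----------------------------------------------------------

def save_movie(movie: Movie, path: str | Path, config: SimConfig | None = None,
               meta: dict | None = None) -> None:
    """Store a movie in HDF5 (datasets f, [h], times; config as attributes)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("f", data=movie.frames, compression="gzip")
        fh.create_dataset("times", data=movie.times)
        if movie.h_frames is not None:
            fh.create_dataset("h", data=movie.h_frames, compression="gzip")
        fh.attrs["spacing"] = movie.spacing
        fh.attrs["tau"] = movie.tau
        if config is not None:
            k, m, nz = config.kernel, config.model, config.noise
            fh.attrs.update({
                "grid_n": config.grid_n, "dt": config.dt,
                "duration": config.duration,
                "snapshot_stride": config.snapshot_stride,
                "W_E": k.W_E, "W_I": k.W_I,
                "sigma_E": k.sigma_E, "sigma_I": k.sigma_I,
                "p": m.p, "kappa": m.kappa,
                "sigma_xi": nz.sigma_xi, "noise_seed": nz.seed,
                "noise_mode": nz.mode,
            })
        if meta is not None:
            for key, val in meta.items():
                fh.attrs[f"meta_{key}"] = val


def load_movie(path: str | Path) -> Movie:
    with h5py.File(path, "r") as fh:
        return Movie(
            frames=fh["f"][...],
            times=fh["times"][...],
            spacing=float(fh.attrs["spacing"]),
            h_frames=fh["h"][...] if "h" in fh else None,
            tau=float(fh.attrs.get("tau", 10.0)),
        )
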