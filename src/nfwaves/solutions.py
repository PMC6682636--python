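"""Semi-analytic solutions of the refractory neural field.

Two families are covered:

* radially symmetric **bumps** with constant interior occupation
  (f, h) = (p/(1+2p), 1/(1+2p)), whose radius rho solves a threshold
  condition at the boundary, and
* **1D traveling waves** described by a speed c and active length L, whose
  interior profile follows from the co-moving ODE system and whose (c, L)
  are pinned by requiring the synaptic input to equal the firing threshold
  kappa at the front (x = 0) and at the back of the active region (x = -L).

The 1D reduction uses the transverse-integrated 2D kernel
(int K0(sqrt(x^2+y^2)) dy = pi e^{-|x|}), so the two boundary conditions are
exact for planar fronts of the two-dimensional field.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import i0, i1, k0, k1
from scipy.stats import qmc

from .kernel import KernelParams, eval_kernel, zero_crossing_radius

__all__ = [
    "ModelParams",
    "BumpSolution",
    "Wave1D",
    "Wave1DUnconvergedError",
    "bump_profile",
    "bump_boundary_input",
    "bump_existence_residual",
    "solve_bump_radii",
    "shift_growth_rate",
    "GrowthRateResult",
    "line_kernel",
    "wave1d_profile",
    "solve_wave1d",
    "disc_input",
]


@dataclass(frozen=True)
class ModelParams:
    """Field parameters: refractory recovery rate p, threshold kappa, and the
    membrane time constant tau (ms), used only to convert rescaled time to
    wall time."""

    p: float = 0.42
    kappa: float = 1.0
    tau: float = 10.0

    def __post_init__(self):
        if not (self.p > 0 and self.kappa > 0 and self.tau > 0):
            raise ValueError("p, kappa and tau must all be strictly positive")

    @property
    def f_in(self) -> float:
        """Interior firing fraction of a bump, p/(1+2p)."""
        return self.p / (1.0 + 2.0 * self.p)

    @property
    def h_in(self) -> float:
        """Interior resting deficit of a bump, 1/(1+2p)."""
        return 1.0 / (1.0 + 2.0 * self.p)


@dataclass(frozen=True)
class BumpSolution:
    """A stationary radially symmetric bump of radius rho (field units)."""

    rho: float
    f_in: float
    h_in: float
    branch: str  # "smaller" (unstable) or "larger" (stable radius branch)
    growth_rate: float | None = None


def bump_profile(rho: float, model: ModelParams, branch: str = "larger") -> BumpSolution:
    """Piecewise-constant bump: (f_in, h_in) inside radius rho, zero outside."""
    if not rho > 0:
        raise ValueError("rho must be positive")
    return BumpSolution(rho=rho, f_in=model.f_in, h_in=model.h_in, branch=branch)


# -- closed-form disc integrals -------------------------------------------
# K0 is (2 pi x) the Green's function of (lap - 1) in 2D, which gives the
# classical closed forms for its integral over a disc of radius a:
#   int_{|r'|<a} K0(|r - r'|) dr' = 2 pi [1 - a K1(a) I0(r)]   for r <= a
#                                 = 2 pi a I1(a) K0(r)          for r >= a

def _k0_disc(a: float, r: float) -> float:
    if r <= a:
        return 2.0 * np.pi * (1.0 - a * k1(a) * i0(r))
    return 2.0 * np.pi * a * i1(a) * k0(r)


def disc_input(rho: float, r: float, params: KernelParams) -> float:
    """Integral of the kernel over a disc of radius rho, evaluated at distance
    r from the disc center.  Exact (Bessel identities), no quadrature."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    total = 0.0
    for W, s, sign in (
        (params.W_E, params.sigma_E, 1.0),
        (params.W_I, params.sigma_I, -1.0),
    ):
        # wK(r/s) = (2/3pi)[K0(r/s) - K0(r/(s/2))]
        t1 = s ** 2 * _k0_disc(rho / s, r / s)
        t2 = (s / 2.0) ** 2 * _k0_disc(2.0 * rho / s, 2.0 * r / s)
        total += sign * W * (2.0 / (3.0 * np.pi)) * (t1 - t2)
    return total


def bump_boundary_input(rho: float, params: KernelParams, model: ModelParams) -> float:
    """Synaptic input u(rho) at the boundary of a bump of radius rho."""
    return model.f_in * disc_input(rho, rho, params)


def bump_existence_residual(rho: float, params: KernelParams, model: ModelParams) -> float:
    """Left-hand side of the bump existence condition,

        p/(1+2p) * [ INT_disc w - 2 kappa ] - kappa,

    whose roots are the admissible bump radii.  The disc integral is the
    kernel integrated over the bump interior, evaluated at a boundary point.
    """
    if not rho > 0:
        raise ValueError("rho must be positive")
    W = disc_input(rho, rho, params)
    return model.f_in * (W - 2.0 * model.kappa) - model.kappa


def solve_bump_radii(
    params: KernelParams, model: ModelParams, n_scan: int = 400
) -> list[BumpSolution]:
    """All bump radii on (0, 20 sigma_I]: sign-change bracketing on a log grid
    followed by root polishing.  Returns zero, one, or two solutions; when two
    exist the smaller is the unstable branch and the larger the stable one.
    """
    r_max = 20.0 * params.sigma_I
    rs = np.geomspace(1e-3 * params.sigma_E, r_max, n_scan)
    vals = np.array([bump_existence_residual(r, params, model) for r in rs])
    roots = []
    for i in np.where(np.diff(np.sign(vals)) != 0)[0]:
        root = brentq(
            lambda r: bump_existence_residual(r, params, model),
            rs[i], rs[i + 1], rtol=1e-10,
        )
        roots.append(root)
    roots.sort()
    sols = []
    for j, rho in enumerate(roots):
        branch = "smaller" if (len(roots) > 1 and j == 0) else "larger"
        sols.append(bump_profile(rho, model, branch=branch))
    return sols


@dataclass(frozen=True)
class GrowthRateResult:
    """Shift-perturbation growth rate estimated from direct simulation."""

    rate: float
    distinguishable: bool
    times: np.ndarray
    displacements: np.ndarray


def shift_growth_rate(
    bump: BumpSolution,
    params: KernelParams,
    model: ModelParams,
    grid_n: int = 128,
    spacing: float = 0.25,
    dt: float = 0.01,
    horizon: float = 30.0,
    shift_cells: float = 0.2,
    floor_cells: float = 0.01,
    ceil_cells: float = 1.0,
) -> GrowthRateResult:
    """Estimate the exponential growth rate of a sub-grid shift perturbation.

    The bump is rasterized, displaced by ``shift_cells`` grid cells via a
    spectral (Fourier) shift, and evolved noise-free; the slope of
    log |COM displacement| vs. time is fitted over the window where the
    displacement grows from ``floor_cells`` to ``ceil_cells``.  A positive
    rate means the bump is unstable to drift (the bump-to-wave transition).

    The default spacing (0.25 units/cell) matters: on coarser lattices the
    discrete threshold crossing cannot advance and marginally unstable bumps
    pin to the grid, reporting a rate near zero.
    """
    from .simulator import SimConfig, NoiseSpec, make_initial, simulate
    from .tracking import periodic_displacement

    if bump.branch != "smaller" and bump.rho * 2 > grid_n * spacing / 2:
        raise ValueError("bump does not fit the simulation domain")

    config = SimConfig(
        grid_n=grid_n, spacing=spacing, dt=dt, duration=horizon,
        snapshot_stride=25, kernel=params, model=model,
        noise=NoiseSpec(sigma_xi=0.0, seed=0, mode="off"),
    )
    state = make_initial("bump", config, rho=bump.rho)
    # sub-grid shift of both fields along x via Fourier phase ramp
    n = config.grid_n
    kx = np.fft.fftfreq(n)[:, None]
    phase = np.exp(-2j * np.pi * kx * shift_cells)
    state = replace(
        state,
        f=np.real(np.fft.ifft2(np.fft.fft2(state.f) * phase)).clip(0.0, 1.0),
        h=np.real(np.fft.ifft2(np.fft.fft2(state.h) * phase)).clip(0.0, 1.0),
    )
    movie, _meta = simulate(state, config)

    dom = config.grid_n * config.spacing
    com0 = movie.center_of_mass(0)
    disp = np.array([
        np.hypot(*periodic_displacement(movie.center_of_mass(i), com0, dom))
        for i in range(movie.n_frames)
    ])
    times = movie.times

    lo, hi = floor_cells * spacing, ceil_cells * spacing
    window = (disp >= lo) & (disp <= hi) & (times > 0)
    if window.sum() < 3:
        return GrowthRateResult(0.0, False, times, disp)
    slope = np.polyfit(times[window], np.log(disp[window]), 1)[0]
    return GrowthRateResult(float(slope), True, times, disp)


# -- 1D traveling waves ----------------------------------------------------

@dataclass(frozen=True)
class Wave1D:
    """A 1D traveling wave: speed c, active length L, and the profile
    coefficients alpha, beta, A, B determined by the refractory rate p."""

    c: float
    L: float
    p: float
    alpha: float
    beta: float
    A: float
    B: float
    objective: float = 0.0

    @classmethod
    def from_cl(cls, c: float, L: float, model: ModelParams, objective: float = 0.0):
        p = model.p
        if not p < 4:
            raise ValueError("oscillatory profile requires p < 4")
        if not (c > 0 and L > 0):
            raise ValueError("c and L must be positive")
        alpha = (2.0 + p) / 2.0
        beta = np.sqrt(p * (4.0 - p)) / 2.0
        A = (2.0 - alpha + 1.0 / p) / beta
        B = (alpha - 2.0 - p * ((alpha - 2.0) ** 2 + beta ** 2)) / beta
        return cls(c=c, L=L, p=p, alpha=alpha, beta=beta, A=A, B=B,
                   objective=objective)


def line_kernel(x, params: KernelParams):
    """Transverse-integrated 2D kernel: the effective 1D coupling felt by a
    planar front.  Uses int K0(sqrt(x^2+y^2)) dy = pi exp(-|x|), so each
    Bessel term becomes a pure exponential."""
    ax = np.abs(np.asarray(x, dtype=float))

    def term(s):
        return s * (2.0 / 3.0) * (np.exp(-ax / s) - 0.5 * np.exp(-2.0 * ax / s))

    return params.W_E * term(params.sigma_E) - params.W_I * term(params.sigma_I)


def wave1d_profile(x, wave: Wave1D, model: ModelParams):
    """Evaluate the wave-frame profile (F, H) at positions x.

    Front at the origin, wave moving toward positive x; the active region is
    -L <= x <= 0.  Inside it the profile is the co-moving-ODE solution

        F = f_in (1 - e^{alpha x / c} [cos(beta x / c) + A sin(beta x / c)])

    (and likewise H with B); behind the wave both fields decay exponentially.
    The sign of the sine coefficient is fixed by requiring the profile to
    satisfy dF/dx = (2F + H - 1)/c, dH/dx = (pH - F)/c with F(0) = H(0) = 0.
    """
    p = model.p
    if not p < 4:
        raise ValueError("oscillatory profile requires p < 4")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    c, L = wave.c, wave.L
    al, be, A, B = wave.alpha, wave.beta, wave.A, wave.B
    f_in, h_in = model.f_in, model.h_in

    F = np.zeros_like(x)
    H = np.zeros_like(x)

    mid = (x <= 0) & (x >= -L)
    e = np.exp(al * x[mid] / c)
    cs = np.cos(be * x[mid] / c)
    sn = np.sin(be * x[mid] / c)
    F[mid] = f_in * (1.0 - e * (cs + A * sn))
    H[mid] = h_in * (1.0 - e * (cs + B * sn))

    eL = np.exp(-al * L / c)
    csL = np.cos(be * L / c)
    snL = np.sin(be * L / c)
    FL = f_in * (1.0 - eL * (csL - A * snL))
    HL = h_in * (1.0 - eL * (csL - B * snL))

    tail = x < -L
    F[tail] = FL * np.exp((x[tail] + L) / c)
    H[tail] = (HL + FL / (1.0 - p)) * np.exp(p * (x[tail] + L) / c) - (
        FL / (1.0 - p)
    ) * np.exp((x[tail] + L) / c)
    return F, H


class Wave1DUnconvergedError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def _boundary_residuals(c, L, params, model, n_quad=3001):
    wave = Wave1D.from_cl(c, L, model)
    x = np.linspace(-(L + 40.0 * c), 0.0, n_quad)
    F, _ = wave1d_profile(x, wave, model)
    u0 = np.trapezoid(line_kernel(x, params) * F, x)
    uL = np.trapezoid(line_kernel(x + L, params) * F, x)
    return u0 - model.kappa, uL - model.kappa


def solve_wave1d(
    params: KernelParams,
    model: ModelParams,
    init: tuple[float, float] | None = None,
    n_starts: int = 24,
    seed: int = 0,
    tol_factor: float = 1e-10,
    c_range: tuple[float, float] = (0.01, 50.0),
    L_range: tuple[float, float] = (0.05, 30.0),
) -> list[Wave1D]:
    """Solve the two threshold conditions u(0) = u(-L) = kappa for (c, L).

    Multi-start least squares over a Latin-hypercube of log(c), log(L)
    (deterministic under ``seed``); all distinct minima with summed squared
    residual below ``tol_factor * kappa^2`` are returned sorted by (c, L),
    largest last.  Raises Wave1DUnconvergedError (carrying the best
    candidate) if no start converges.
    """
    tol = tol_factor * model.kappa ** 2

    def residual(q):
        c, L = np.exp(q)
        if not (c_range[0] / 10 < c < c_range[1] * 10 and
                L_range[0] / 10 < L < L_range[1] * 10):
            return [1e3, 1e3]
        return list(_boundary_residuals(c, L, params, model))

    starts = []
    if init is not None:
        starts.append(np.log(np.asarray(init, dtype=float)))
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    pts = sampler.random(n_starts)
    lo = np.log([c_range[0], L_range[0]])
    hi = np.log([c_range[1], L_range[1]])
    starts.extend(lo + pts * (hi - lo))

    found: dict[tuple[float, float], Wave1D] = {}
    best = None
    for q0 in starts:
        sol = least_squares(residual, q0, method="lm", xtol=1e-15, ftol=1e-15)
        cost = 2.0 * sol.cost  # least_squares cost is half the sum of squares
        c, L = np.exp(sol.x)
        if best is None or cost < best.objective:
            best = Wave1D.from_cl(max(c, 1e-12), max(L, 1e-12), model,
                                  objective=cost)
        if cost < tol and c_range[0] <= c <= c_range[1] and L_range[0] <= L <= L_range[1]:
            key = (round(float(c), 6), round(float(L), 6))
            found.setdefault(key, Wave1D.from_cl(c, L, model, objective=cost))
    if not found:
        raise Wave1DUnconvergedError(
            f"no (c, L) solution below tolerance {tol:.1e} "
            f"(best objective {best.objective:.3e} at c={best.c:.4g}, L={best.L:.4g})",
            best=best,
        )
    return sorted(found.values(), key=lambda w: (w.c, w.L))
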