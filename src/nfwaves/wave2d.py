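"""Teardrop-shaped 2D traveling waves.

A localized traveling wave has a comet shape: an elliptical front (half-axes
L_f along the propagation axis and L_w across it) joined at the widest point
to a curved tail whose polar radius is

    rho_tail(theta) = L_w - L_a [1 - 1/(1 - L_b cos^2 theta)],  0 < L_b < 1.

Together with the speed c this gives five parameters (c, L_f, L_w, L_a, L_b).
The interior (f, h) fields are filled chord-by-chord with the 1D wave-frame
profile, using the local chord length L = sigma_+(y) - sigma_-(y); the five
parameters are fitted by requiring the synaptic input to equal the firing
threshold kappa along the discretized boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kernel import KernelParams
from .solutions import ModelParams, Wave1D, wave1d_profile

__all__ = [
    "Wave2DShape",
    "boundary_radius",
    "build_wave2d_state",
    "fit_wave2d",
    "Wave2DFitResult",
]


@dataclass(frozen=True)
class Wave2DShape:
    """Five-parameter teardrop boundary plus propagation speed.

    The derived tail length is reported two ways because the defining
    relations disagree: ``L_t`` uses L_w + L_a L_b/(1 - L_b^2) while the
    boundary itself gives rho_tail(pi) = L_w + L_a L_b/(1 - L_b).  ``L_t`` is
    a descriptive label only and never enters the fitting.
    """

    c: float
    L_f: float
    L_w: float
    L_a: float
    L_b: float

    def __post_init__(self):
        if not (0 < self.L_b < 1):
            raise ValueError("L_b must lie strictly between 0 and 1")
        if not (self.L_f > 0 and self.L_w > 0 and self.L_a > 0 and self.c > 0):
            raise ValueError("c, L_f, L_w, L_a must be positive")

    @property
    def L_t(self) -> float:
        """Derived tail length, L_w + L_a L_b / (1 - L_b^2)."""
        return self.L_w + self.L_a * self.L_b / (1.0 - self.L_b ** 2)

    @property
    def tail_apex(self) -> float:
        """rho_tail(pi) = L_w + L_a L_b / (1 - L_b): the boundary's own tail
        extent, which differs from L_t whenever L_b > 0."""
        return self.L_w + self.L_a * self.L_b / (1.0 - self.L_b)

    @property
    def length(self) -> float:
        """Total extent along the propagation axis, L_f + rho_tail(pi)."""
        return self.L_f + self.tail_apex


def boundary_radius(theta, shape: Wave2DShape):
    """Polar boundary radius for theta in [-pi/2, 3pi/2).

    Front branch (theta <= pi/2, including the join): ellipse
    L_f L_w / sqrt(L_w^2 cos^2 + L_f^2 sin^2); tail branch beyond.  Both
    branches equal L_w at theta = pi/2.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    th = (th + np.pi / 2) % (2 * np.pi) - np.pi / 2  # wrap into [-pi/2, 3pi/2)
    front = th <= np.pi / 2
    r = np.empty_like(th)
    Lf, Lw, La, Lb = shape.L_f, shape.L_w, shape.L_a, shape.L_b
    r[front] = Lf * Lw / np.sqrt(
        Lw ** 2 * np.cos(th[front]) ** 2 + Lf ** 2 * np.sin(th[front]) ** 2
    )
    t = ~front
    r[t] = Lw - La * (1.0 - 1.0 / (1.0 - Lb * np.cos(th[t]) ** 2))
    return r if np.ndim(theta) else float(r[0])


def _boundary_interpolants(shape: Wave2DShape, n_theta: int = 1024):
    """(y, x) samples of the front and tail branches, each sorted by y."""
    th_f = np.linspace(-np.pi / 2, np.pi / 2, n_theta)
    rf = boundary_radius(th_f, shape)
    xf, yf = rf * np.cos(th_f), rf * np.sin(th_f)
    th_t = np.linspace(np.pi / 2, 3 * np.pi / 2, n_theta, endpoint=False)[1:]
    rt = boundary_radius(th_t, shape)
    xt, yt = rt * np.cos(th_t), rt * np.sin(th_t)
    of, ot = np.argsort(yf), np.argsort(yt)
    return (yf[of], xf[of]), (yt[ot], xt[ot])


def build_wave2d_state(
    shape: Wave2DShape,
    model: ModelParams,
    config,
    direction: float | tuple[float, float] = 0.0,
    center: tuple[float, float] | None = None,
):
    """Rasterize a teardrop wave into a FieldState.

    ``direction`` is the propagation direction: an angle in radians or a
    2-vector.  Interior (f, h) values come from the 1D wave-frame profile
    evaluated along the propagation axis with the local chord length
    L = sigma_+(y) - sigma_-(y); the field is exactly zero outside the
    boundary (nearest-grid-point rasterization, no anti-aliasing).
    """
    from .simulator import FieldState

    n, dx = config.grid_n, config.spacing
    dom = n * dx
    if center is None:
        center = (dom / 2, dom / 2)
    extent = max(shape.L_f, shape.tail_apex, shape.L_w)
    if 2 * extent + 2 * config.kernel.sigma_I > dom:
        raise ValueError(
            f"wave (extent {extent:.2f}) does not fit the domain "
            f"({dom:.2f}) with a 2 sigma_I margin"
        )
    angle = (
        float(np.arctan2(direction[1], direction[0]))
        if np.ndim(direction) else float(direction)
    )

    xg = np.arange(n) * dx
    rx = (xg[:, None] - center[0] + dom / 2) % dom - dom / 2
    ry = (xg[None, :] - center[1] + dom / 2) % dom - dom / 2
    ca, sa = np.cos(angle), np.sin(angle)
    # rotate into the wave frame (propagation along +x)
    xr = ca * rx + sa * ry
    yr = -sa * rx + ca * ry

    (yf, xf), (yt, xt) = _boundary_interpolants(shape)
    sig_p = np.interp(yr, yf, xf, left=np.nan, right=np.nan)
    sig_m = np.interp(yr, yt, xt, left=np.nan, right=np.nan)
    with np.errstate(invalid="ignore"):
        inside = (
            (np.abs(yr) <= shape.L_w)
            & ~np.isnan(sig_p) & ~np.isnan(sig_m)
            & (xr <= sig_p) & (xr >= sig_m)
        )

    f = np.zeros((n, n))
    h = np.zeros((n, n))
    if inside.any():
        xi = xr[inside] - sig_p[inside]  # wave-frame coordinate, <= 0 inside
        L_loc = np.maximum(sig_p[inside] - sig_m[inside], 1e-9)
        p = model.p
        al = (2.0 + p) / 2.0
        be = np.sqrt(p * (4.0 - p)) / 2.0
        A = (2.0 - al + 1.0 / p) / be
        B = (al - 2.0 - p * ((al - 2.0) ** 2 + be ** 2)) / be
        c = shape.c
        e = np.exp(al * xi / c)
        cs = np.cos(be * xi / c)
        sn = np.sin(be * xi / c)
        fv = model.f_in * (1.0 - e * (cs + A * sn))
        hv = model.h_in * (1.0 - e * (cs + B * sn))
        # chords are clipped at the tail boundary; values past the local
        # chord would belong to the exponential tail and stay small
        mask_tail = xi < -L_loc
        if mask_tail.any():
            wave = Wave1D.from_cl(c, 1.0, model)
            for idx in np.where(mask_tail)[0]:
                w = replace(wave, L=float(L_loc[idx]))
                Fv, Hv = wave1d_profile(np.array([xi[idx]]), w, model)
                fv[idx], hv[idx] = Fv[0], Hv[0]
        f[inside] = np.clip(fv, 0.0, 1.0)
        h[inside] = np.clip(hv, 0.0, 1.0)
        over = f + h > 1.0
        h[over] = 1.0 - f[over]
    return FieldState(f=f, h=h, spacing=dx)


@dataclass(frozen=True)
class Wave2DFitResult:
    shape: Wave2DShape
    objective: float
    max_abs_residual: float
    converged: bool


def _boundary_objective(shape, params, model, config, n_boundary):
    from .simulator import sample_kernel_grid, synaptic_input

    state = build_wave2d_state(shape, model, config)
    u = synaptic_input(state.f, sample_kernel_grid(config))
    n, dx = config.grid_n, config.spacing
    dom = n * dx
    thetas = -np.pi / 2 + np.arange(n_boundary) * (2 * np.pi / n_boundary)
    r = boundary_radius(thetas, shape)
    bx = (dom / 2 + r * np.cos(thetas)) / dx
    by = (dom / 2 + r * np.sin(thetas)) / dx
    ui = u[np.round(bx).astype(int) % n, np.round(by).astype(int) % n]
    res = ui - model.kappa
    return float(np.sum(res ** 2)), float(np.max(np.abs(res)))


def fit_wave2d(
    params: KernelParams,
    model: ModelParams,
    init: Wave2DShape,
    config=None,
    n_boundary: int = 64,
    seed: int = 0,
    n_starts: int = 3,
    max_iter: int = 200,
    tol: float | None = None,
    fit_speed: bool = True,
) -> list[Wave2DFitResult]:
    """Fit the five shape parameters so the boundary sits on the threshold.

    Minimizes sum_i [u(theta_i) - kappa]^2 over the ``n_boundary`` discretized
    boundary points with a derivative-free compass (pattern) search in log /
    logit coordinates; multi-start (deterministic under ``seed``) because the
    objective has many local minima.  Returns all multi-start results sorted
    by objective, best first.

    With ``fit_speed=False`` the speed c is held at the initial value and only
    the four boundary parameters are searched.  The boundary objective
    constrains c only weakly (it enters through the interior fill alone), and
    letting it float can walk the search into the degenerate c -> 0 corner of
    the family, which is a rasterized stationary bump rather than a wave.
    """
    from .simulator import SimConfig, NoiseSpec

    if n_boundary < 32:
        raise ValueError("n_boundary must be at least 32")
    if config is None:
        config = SimConfig(
            grid_n=128, spacing=0.25, duration=0.0, kernel=params, model=model,
            noise=NoiseSpec(),
        )
    else:
        config = replace(config, kernel=params, model=model)
    if tol is None:
        tol = n_boundary * (0.05 * model.kappa) ** 2

    def pack(s: Wave2DShape):
        return np.array([
            np.log(s.c), np.log(s.L_f), np.log(s.L_w), np.log(s.L_a),
            np.log(s.L_b / (1 - s.L_b)),
        ])

    def unpack(q) -> Wave2DShape:
        return Wave2DShape(
            c=float(np.exp(q[0])), L_f=float(np.exp(q[1])),
            L_w=float(np.exp(q[2])), L_a=float(np.exp(q[3])),
            L_b=float(1 / (1 + np.exp(-q[4]))),
        )

    def safe_obj(q):
        try:
            return _boundary_objective(unpack(q), params, model, config, n_boundary)
        except (ValueError, FloatingPointError):
            return np.inf, np.inf

    rng = np.random.default_rng(seed)
    results = []
    for start in range(n_starts):
        q = pack(init)
        if start > 0:
            q = q + rng.normal(0.0, 0.15, size=q.size)
        fval, mres = safe_obj(q)
        step = 0.25
        evals = 0
        dims = range(q.size) if fit_speed else range(1, q.size)
        while step > 1e-3 and evals < max_iter:
            improved = False
            for d in dims:
                for sgn in (+1.0, -1.0):
                    qt = q.copy()
                    qt[d] += sgn * step
                    ft, mt = safe_obj(qt)
                    evals += 1
                    if ft < fval:
                        q, fval, mres = qt, ft, mt
                        improved = True
                        break
            if not improved:
                step *= 0.5
        results.append(
            Wave2DFitResult(
                shape=unpack(q), objective=fval, max_abs_residual=mres,
                converged=bool(fval < tol),
            )
        )
    return sorted(results, key=lambda r: r.objective)
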