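"""Mexican-hat coupling kernel built from modified Bessel functions.

The lateral coupling of the neural field is a difference of two radially
symmetric Bessel profiles,

    w(r) = W_E * wK(r / sigma_E) - W_I * wK(r / sigma_I),
    wK(r) = (2 / 3*pi) * [K0(r) - K0(2r)],

giving short-range excitation and longer-range inhibition.  The net
excitatory and inhibitory drives are summarized by the signed integrals
g_plus (over the excitatory disc r < r0) and g_minus (over the inhibitory
annulus r > r0), where r0 is the unique sign change of w.  All lengths are
in field units (one unit = one grid cell = 0.1 mm at the reference
resolution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq, least_squares
from scipy.special import k0

__all__ = [
    "KernelParams",
    "EIPoint",
    "KernelError",
    "NoInhibitoryRegionError",
    "NonMexicanHatError",
    "InversionError",
    "bessel_profile",
    "eval_kernel",
    "is_mexican_hat",
    "zero_crossing_radius",
    "ei_integrals",
    "invert_ei",
    "sample_kernels_mc",
    "kernels_to_csv",
]

#: small-argument limit of K0(x) - K0(2x)
_LOG2 = float(np.log(2.0))


class KernelError(ValueError):
    """Base class for kernel-shape errors."""


class NoInhibitoryRegionError(KernelError):
    """The profile never becomes negative (no inhibitory region)."""


class NonMexicanHatError(KernelError):
    """The profile has more than one sign change."""


class InversionError(RuntimeError):
    """g+/g- inversion failed to reach tolerance; carries the best residual."""

    def __init__(self, message: str, best_params=None, residual=None):
        super().__init__(message)
        self.best_params = best_params
        self.residual = residual


@dataclass(frozen=True)
class KernelParams:
    """Coupling-strength and spatial-scale parameters of the kernel.

    W_E, W_I are dimensionless coupling strengths; sigma_E, sigma_I are
    spatial scales in field units.  All must be strictly positive.
    """

    W_E: float
    W_I: float
    sigma_E: float
    sigma_I: float

    def __post_init__(self):
        for name in ("W_E", "W_I", "sigma_E", "sigma_I"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def scaled(self, coupling: float = 1.0, length: float = 1.0) -> "KernelParams":
        """Return a copy with couplings and/or lengths rescaled."""
        return KernelParams(
            self.W_E * coupling,
            self.W_I * coupling,
            self.sigma_E * length,
            self.sigma_I * length,
        )


@dataclass(frozen=True)
class EIPoint:
    """Integrated excitation/inhibition coordinates of a kernel.

    g_plus > 0 is the integral of w over the excitatory disc, g_minus < 0
    the integral over the inhibitory annulus, and r0 the sign-change radius.
    """

    g_plus: float
    g_minus: float
    r0: float

    def __post_init__(self):
        if not (self.g_plus > 0 and self.g_minus < 0 and self.r0 > 0):
            raise ValueError(
                "EIPoint requires g_plus > 0, g_minus < 0, r0 > 0; got "
                f"({self.g_plus}, {self.g_minus}, {self.r0})"
            )


def bessel_profile(x):
    """The base profile wK(x) = (2/3pi)[K0(x) - K0(2x)], finite at x = 0.

    The x -> 0 limit of K0(x) - K0(2x) is ln 2, used in place of the
    (divergent) individual Bessel terms.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("radial argument must be non-negative")
    out = np.full(x.shape, _LOG2)
    m = x > 1e-8
    xm = x[m]
    out[m] = k0(xm) - k0(2.0 * xm)
    return (2.0 / (3.0 * np.pi)) * out


def eval_kernel(r, params: KernelParams):
    """Evaluate w(r) = W_E wK(r/sigma_E) - W_I wK(r/sigma_I) for r >= 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be non-negative")
    return params.W_E * bessel_profile(r / params.sigma_E) - params.W_I * bessel_profile(
        r / params.sigma_I
    )


def _radial_scan(params: KernelParams, n: int = 2000):
    rmax = 20.0 * params.sigma_I
    rs = np.geomspace(1e-6 * params.sigma_E, rmax, n)
    return rs, eval_kernel(rs, params)


def is_mexican_hat(params: KernelParams) -> bool:
    """True if w > 0 near the origin with exactly one sign change."""
    rs, vals = _radial_scan(params)
    if vals[0] <= 0:
        return False
    sign_changes = np.count_nonzero(np.diff(np.sign(vals)) != 0)
    return sign_changes == 1


def zero_crossing_radius(params: KernelParams) -> float:
    """Radius r0 of the excitation/inhibition transition, w(r0) = 0.

    Raises NoInhibitoryRegionError if w never becomes negative and
    NonMexicanHatError if the profile changes sign more than once (or is
    negative at the origin).
    """
    rs, vals = _radial_scan(params)
    if vals[0] <= 0:
        raise NonMexicanHatError("kernel is not excitatory at the origin")
    idx = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(idx) == 0:
        raise NoInhibitoryRegionError(
            "kernel has no inhibitory region (w(r) > 0 everywhere)"
        )
    if len(idx) > 1:
        raise NonMexicanHatError(f"kernel changes sign {len(idx)} times")
    i = idx[0]
    return brentq(
        lambda r: float(eval_kernel(r, params)), rs[i], rs[i + 1],
        xtol=1e-300, rtol=1e-12,
    )


def ei_integrals(params: KernelParams) -> EIPoint:
    """Signed disc/annulus integrals g+ = 2pi INT_0^r0 r w dr, g- beyond r0.

    The improper outer integral is truncated at 20 sigma_I, beyond which the
    exponentially decaying Bessel terms are negligible (|w| < 1e-12 |w(0)|).
    """
    r0 = zero_crossing_radius(params)
    rmax = 20.0 * params.sigma_I

    def integrand(r):
        return 2.0 * np.pi * r * float(eval_kernel(r, params))

    g_plus, _ = quad(integrand, 0.0, r0, limit=200)
    g_minus, _ = quad(integrand, r0, rmax, limit=200)
    return EIPoint(g_plus=g_plus, g_minus=g_minus, r0=r0)


def invert_ei(
    g_plus: float,
    g_minus: float,
    init: KernelParams | None = None,
    seed: int = 0,
    n_starts: int = 12,
    tol: float = 1e-6,
) -> tuple[KernelParams, float]:
    """Find kernel parameters whose g+/g- match the target.

    The map (W_E, W_I, sigma_E, sigma_I) -> (g+, g-) is many-to-one, so any
    feasible parameter set is acceptable.  Minimizes the sum of squared
    residuals to the target with multi-start least squares; returns
    (params, max-abs residual).  Raises InversionError when no start reaches
    ``tol`` on both coordinates.
    """
    if not g_plus > 0:
        raise ValueError("target g_plus must be positive")
    if not g_minus < 0:
        raise ValueError("target g_minus must be negative")

    rng = np.random.default_rng(seed)

    def residual_at(sig_e, sig_i, logw):
        we, wi = np.exp(logw)
        try:
            p = KernelParams(we, wi, sig_e, sig_i)
            if not is_mexican_hat(p):
                return [1e3, 1e3]
            ei = ei_integrals(p)
        except (KernelError, ValueError):
            return [1e3, 1e3]
        return [ei.g_plus - g_plus, ei.g_minus - g_minus]

    # the map is many-to-one: fix the spatial scales per start and solve the
    # well-posed 2x2 problem in the coupling strengths
    starts: list[tuple[float, float, float, float]] = []
    if init is not None:
        starts.append((init.sigma_E, init.sigma_I, init.W_E, init.W_I))
    while len(starts) < n_starts:
        sig_e = float(np.exp(rng.uniform(np.log(0.5), np.log(6.0))))
        sig_i = sig_e * float(np.exp(rng.uniform(np.log(1.3), np.log(3.0))))
        starts.append((sig_e, sig_i, 100.0, 50.0))

    best = None
    for sig_e, sig_i, we0, wi0 in starts:
        sol = least_squares(
            lambda q: residual_at(sig_e, sig_i, q),
            np.log([we0, wi0]), method="lm", xtol=1e-15, ftol=1e-15,
        )
        res = float(np.max(np.abs(sol.fun)))
        if best is None or res < best[1]:
            we, wi = np.exp(sol.x)
            best = (KernelParams(we, wi, sig_e, sig_i), res)
        if res < tol:
            return best
    raise InversionError(
        f"inversion unconverged after {len(starts)} starts "
        f"(best residual {best[1]:.3e})",
        best_params=best[0],
        residual=best[1],
    )


def sample_kernels_mc(
    n: int, seed: int, low: float = 0.0, high: float = 150.0, max_draws: int | None = None
) -> list[tuple[KernelParams, EIPoint]]:
    """Rejection-sample n Mexican-hat kernels, parameters uniform on (low, high).

    Draws (W_E, W_I, sigma_E, sigma_I) i.i.d. uniform and keeps those passing
    the Mexican-hat predicate.  Aborts if the running acceptance rate falls
    below 1e-4.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if max_draws is None:
        max_draws = max(10_000, int(n / 1e-4))
    out: list[tuple[KernelParams, EIPoint]] = []
    draws = 0
    while len(out) < n:
        if draws >= max_draws:
            raise RuntimeError(
                f"kernel sampling acceptance rate below 1e-4: "
                f"{len(out)} accepted in {draws} draws"
            )
        draws += 1
        vals = rng.uniform(low, high, size=4)
        if np.any(vals <= 0):
            continue
        cand = KernelParams(*vals)
        if not is_mexican_hat(cand):
            continue
        out.append((cand, ei_integrals(cand)))
    return out


def kernels_to_csv(
    samples: list[tuple[KernelParams, EIPoint]],
    path: str | Path,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write sampled kernels with their EI coordinates to CSV.

    When a seed is given, a sidecar ``<path>.meta.json`` records it.
    """
    rows = [
        {
            "W_E": k.W_E, "W_I": k.W_I,
            "sigma_E": k.sigma_E, "sigma_I": k.sigma_I,
            "g_plus": e.g_plus, "g_minus": e.g_minus, "r0": e.r0,
        }
        for k, e in samples
    ]
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False)
    if seed is not None:
        meta = {"seed": int(seed), "n": len(samples)}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))
    return df
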