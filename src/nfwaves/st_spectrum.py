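"""Spatiotemporal spectral analysis of field movies.

A movie f(x, y, t) on a periodic domain is Fourier-transformed in all three
dimensions (Hann window along time only — the spatial axes are periodic and
need none), the modulus taken, and the two spatial-frequency axes reduced to
a single radial axis by annulus-averaging.  Rigid translation at speed v
concentrates power along the line v*f + omega = 0, so summing the spectrum
along lines of constant velocity yields a velocity-power profile whose peak
estimates the dominant propagation speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fftfreq, fftn

from .simulator import Movie

__all__ = [
    "STSpectrum",
    "VelocityPowerProfile",
    "spatiotemporal_spectrum",
    "velocity_power_profile",
]


@dataclass(frozen=True)
class STSpectrum:
    """Radially averaged spatiotemporal power.

    ``power[i, j]`` is the mean |FFT| power in spatial-frequency annulus i
    (cycles per field unit) at temporal frequency j (Hz, signed frequencies
    folded onto omega >= 0)."""

    spatial_freqs: np.ndarray
    temporal_freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        if self.power.shape != (len(self.spatial_freqs), len(self.temporal_freqs)):
            raise ValueError("power matrix does not match the frequency axes")


@dataclass(frozen=True)
class VelocityPowerProfile:
    """Total spectral power along lines omega = v * f."""

    velocities: np.ndarray  # field units per second
    power: np.ndarray
    peak_velocity: float | None
    peak_power: float | None


def spatiotemporal_spectrum(movie: Movie, detrend_mean: bool = True) -> STSpectrum:
    """Radially averaged 3D power spectrum of a movie.

    Needs at least 64 frames.  The temporal axis is Hann-windowed; spatial
    frequencies are binned into annuli one spatial-frequency cell wide and
    averaged (bin means, so wide annuli are not over-weighted).  Temporal
    frequencies are in Hz (frame interval converted through tau); negative
    temporal frequencies are averaged onto their positive counterparts.
    """
    T = movie.n_frames
    if T < 64:
        raise ValueError("need at least 64 frames for a spatiotemporal spectrum")
    data = movie.frames.astype(float)
    if detrend_mean:
        data = data - data.mean(axis=0, keepdims=True)
    win = np.hanning(T)[:, None, None]
    spec = np.abs(fftn(data * win, axes=(0, 1, 2)))

    n = data.shape[1]
    dt_s = movie.frame_interval * movie.tau / 1000.0
    w_all = fftfreq(T, d=dt_s)
    kx = fftfreq(n, d=movie.spacing)
    kr = np.hypot(kx[:, None], kx[None, :])
    dk = 1.0 / (n * movie.spacing)
    ring = np.round(kr / dk).astype(int)
    n_rings = ring.max() + 1

    # mean power per (temporal freq, spatial ring)
    counts = np.bincount(ring.ravel(), minlength=n_rings)
    radial = np.empty((n_rings, T))
    flat_ring = ring.ravel()
    for j in range(T):
        sums = np.bincount(flat_ring, weights=spec[j].ravel(), minlength=n_rings)
        radial[:, j] = sums / counts

    # fold negative temporal frequencies onto positive
    pos = w_all >= 0
    w_pos = w_all[pos]
    order = np.argsort(w_pos)
    folded = radial[:, pos][:, order].copy()
    for j, w in enumerate(w_all):
        if w < 0:
            target = np.argmin(np.abs(w_pos[order] + w))
            folded[:, target] += radial[:, j]
            folded[:, target] /= 2.0
    return STSpectrum(
        spatial_freqs=np.arange(n_rings) * dk,
        temporal_freqs=w_pos[order],
        power=folded,
    )


def velocity_power_profile(
    spec: STSpectrum,
    velocities=None,
    n_velocities: int = 100,
    exclude_dc: bool = True,
) -> VelocityPowerProfile:
    """Sum spectral power along lines of constant velocity v = omega / f.

    For each velocity and each temporal frequency omega > 0, the power at
    spatial frequency f = omega / v is linearly interpolated between the two
    straddling radial bins and accumulated.  Velocities outside the
    resolvable band (line leaving the sampled (f, omega) rectangle for every
    omega) contribute nothing and are trimmed.  Default grid: ``n_velocities``
    log-spaced values spanning the resolvable range.
    """
    f_ax = spec.spatial_freqs
    w_ax = spec.temporal_freqs
    wpos = w_ax > 0 if exclude_dc else w_ax >= 0
    w_use = w_ax[wpos]
    P = spec.power[:, wpos]
    if len(w_use) == 0 or len(f_ax) < 2:
        raise ValueError("spectrum too small for a velocity profile")

    if velocities is None:
        v_min = w_use.min() / f_ax[-1]
        v_max = w_use.max() / f_ax[1]
        velocities = np.geomspace(v_min, v_max, n_velocities)
    else:
        velocities = np.asarray(velocities, dtype=float)
        if np.any(velocities <= 0) or np.any(np.diff(velocities) <= 0):
            raise ValueError("velocity grid must be positive and increasing")

    power = np.zeros(len(velocities))
    for i, v in enumerate(velocities):
        fq = w_use / v
        inside = fq <= f_ax[-1]
        if not inside.any():
            continue
        # linear interpolation of each omega row onto its f = omega/v point
        vals = np.array([
            np.interp(fq[j], f_ax, P[:, j]) for j in np.where(inside)[0]
        ])
        power[i] = vals.sum()

    if power.max() <= 0:
        return VelocityPowerProfile(velocities, power, None, None)
    k = int(np.argmax(power))
    return VelocityPowerProfile(
        velocities, power,
        peak_velocity=float(velocities[k]), peak_power=float(power[k]),
    )
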