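"""Time-series statistics for wave kinematics.

Provides the windowed periodogram, the spectral degrees-of-freedom (DoF)
uniformity statistic, approximate entropy (ApEn), detrended fluctuation
analysis (DFA), and reference-noise generators used to calibrate them.

DoF = (sum S)^2 / (N sum S^2) is 1 for a flat spectrum and 1/N for a single
occupied bin.  The DFA exponent alpha is the log-log slope of the RMS
fluctuation of the integrated, per-box linearly detrended signal versus box
size: 0.5 for white noise, 1.0 for 1/f (pink) noise, 1.5 for Brownian
motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

__all__ = [
    "PowerSpectrum",
    "DFAResult",
    "periodogram",
    "spectral_dof",
    "approx_entropy",
    "dfa",
    "make_reference_noise",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum with coefficients normalized to unit sum.

    ``all_zero`` flags a constant input series (spectrum identically zero
    after DC removal)."""

    frequencies: np.ndarray  # Hz
    S: np.ndarray
    all_zero: bool = False

    @property
    def N(self) -> int:
        return len(self.S)


def periodogram(series, dt: float, tau_ms: float = 10.0) -> PowerSpectrum:
    """Hann-windowed one-sided periodogram, coefficients summing to one.

    ``dt`` is the sample interval in rescaled time units; frequencies are
    reported in Hz using the membrane constant ``tau_ms``.  The DC bin is
    dropped (the statistics target fluctuations, not the mean).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 64:
        raise ValueError("need a 1D series of at least 64 samples")
    n = len(x)
    win = np.hanning(n)
    X = rfft((x - x.mean()) * win)
    power = np.abs(X[1:]) ** 2
    dt_s = dt * tau_ms / 1000.0
    freqs = rfftfreq(n, d=dt_s)[1:]
    tot = power.sum()
    # a constant series leaves only floating-point dust after demeaning
    if tot <= 0 or np.ptp(x) == 0:
        return PowerSpectrum(freqs, np.zeros_like(power), all_zero=True)
    return PowerSpectrum(freqs, power / tot)


def spectral_dof(spec: PowerSpectrum | np.ndarray) -> float:
    """Spectral degrees of freedom, (sum S)^2 / (N sum S^2).

    Scale-invariant; equals 1 for a uniform spectrum of any length and 1/N
    when all power sits in one bin.
    """
    S = spec.S if isinstance(spec, PowerSpectrum) else np.asarray(spec, dtype=float)
    if np.any(S < 0):
        raise ValueError("spectrum coefficients must be non-negative")
    s2 = np.sum(S ** 2)
    if s2 <= 0:
        raise ValueError("all-zero spectrum has undefined DoF")
    return float(np.sum(S) ** 2 / (len(S) * s2))


def approx_entropy(series, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r): Phi_m - Phi_{m+1}.

    Template matching uses the Chebyshev distance with self-matches included
    and natural logarithms.  ``r`` defaults to 0.2 times the series standard
    deviation.  Returns 0 for perfectly regular series.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 50:
        raise ValueError("series too short for ApEn (need >= 50 samples)")
    if r is None:
        r = 0.2 * float(np.std(x))
    if not r > 0:
        raise ValueError("tolerance r must be positive (constant series?)")

    def phi(mm):
        n = len(x) - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)  # (n, mm)
        # pairwise Chebyshev distances
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        C = (d <= r).mean(axis=1)
        return np.mean(np.log(C))

    return float(phi(m) - phi(m + 1))


@dataclass(frozen=True)
class DFAResult:
    """Fluctuation function F(n) over box sizes n with the fitted exponent."""

    box_sizes: np.ndarray
    F: np.ndarray
    alpha: float
    fit_range: tuple[int, int]  # indices into box_sizes used for the fit

    def __post_init__(self):
        if np.any(np.diff(self.box_sizes) <= 0):
            raise ValueError("box sizes must be strictly increasing")


def dfa(
    series,
    box_sizes=None,
    n_boxes: int = 20,
    skip_smallest: int = 2,
) -> DFAResult:
    """Detrended fluctuation analysis with first-order (linear) detrending.

    The series is integrated and demeaned, split into non-overlapping boxes
    of each size n (trailing remainder discarded), linearly detrended per
    box, and the RMS fluctuation F(n) computed over all covered points.
    ``alpha`` is the least-squares slope of log F vs log n, excluding the
    ``skip_smallest`` smallest boxes where the linear fit biases F downward.

    Default boxes: ~``n_boxes`` log-spaced sizes from 10 to len(series)/4.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 500:
        raise ValueError("series too short for DFA (need >= 500 samples)")
    y = np.cumsum(x - x.mean())
    N = len(y)
    if box_sizes is None:
        box_sizes = np.unique(
            np.round(np.geomspace(10, N // 4, n_boxes)).astype(int)
        )
    else:
        box_sizes = np.unique(np.asarray(box_sizes, dtype=int))
        if box_sizes.max() > N // 2:
            box_sizes = box_sizes[box_sizes <= N // 2]

    F = np.empty(len(box_sizes), dtype=float)
    for i, n in enumerate(box_sizes):
        k = N // n
        seg = y[: k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        tc = t - t.mean()
        denom = np.sum(tc ** 2)
        slope = seg @ tc / denom
        inter = seg.mean(axis=1)
        detr = seg - (inter[:, None] + slope[:, None] * tc[None, :])
        F[i] = np.sqrt(np.mean(detr ** 2))

    lo = min(skip_smallest, len(box_sizes) - 2)
    fit = slice(lo, len(box_sizes))
    alpha = float(
        np.polyfit(np.log(box_sizes[fit]), np.log(F[fit]), 1)[0]
    )
    return DFAResult(
        box_sizes=box_sizes, F=F, alpha=alpha,
        fit_range=(fit.start, len(box_sizes)),
    )


def make_reference_noise(kind: str, length: int, seed: int) -> np.ndarray:
    """Reference series for statistics calibration.

    ``white``: i.i.d. standard Gaussian.  ``brownian``: cumulative sum of
    white noise.  ``one_over_f``: white spectrum shaped by 1/sqrt(f) and
    inverse-transformed (power spectral density proportional to 1/f).
    """
    if length < 500:
        raise ValueError("length must be >= 500")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(length)
    if kind == "white":
        return white
    if kind == "brownian":
        return np.cumsum(white)
    if kind == "one_over_f":
        X = rfft(white)
        f = rfftfreq(length)
        scale = np.zeros_like(f)
        scale[1:] = 1.0 / np.sqrt(f[1:])
        out = irfft(X * scale, n=length)
        return out / out.std()
    raise ValueError(f"unknown reference-noise kind: {kind!r}")
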