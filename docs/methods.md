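# Methods

## Model and assumptions

The field evolves two occupation probabilities on a periodic square domain:
f (firing) and h (resting deficit / refractoriness), with the refractory pool
eliminated through f + g + h = 1.  Neurons fire when their synaptic input
u = w ∗ f reaches the threshold κ; the Heaviside convention is H(0) = 1.
Time is rescaled by the membrane constant τ (reported in ms only at I/O
boundaries; default τ = 10 ms).  Space is measured in field units of one grid
cell (0.1 mm at the reference resolution).  Default parameters: p = 0.42,
κ = 1, reference kernel W_E = 144.4, W_I = 73.7, σ_E = 1.87, σ_I = 3.24.

The model assumes radially symmetric coupling, sharp (Heaviside) activation,
and spatially homogeneous parameters.  It is a coarse-grained rate-like
description: no conduction delays, no separate inhibitory population, no
external drive except the noise term.

## Kernel and E/I coordinates

`wK(r) = (2/3π)[K₀(r) − K₀(2r)]` is evaluated with the analytic limit
(2/3π)·ln 2 at r = 0.  The Mexican-hat predicate requires w > 0 near the
origin and exactly one sign change on a log-spaced scan out to 20 σ_I.
g₊ and g₋ are adaptive quadratures of 2πr·w(r) split at the sign change r₀
(located by bracketing and Brent's method to 1e−12 relative); the outer
integral is truncated at 20 σ_I, where the exponential Bessel decay puts
|w| far below 1e−12 |w(0)|.

Because (W_E, W_I, σ_E, σ_I) → (g₊, g₋) is many-to-one, the inverse map
`invert_ei` fixes the spatial scales per start (log-uniform draws,
σ_I/σ_E ∈ [1.3, 3]) and solves the well-posed 2×2 problem in the coupling
strengths by Levenberg–Marquardt on the residuals to the target; any
parameter set reproducing the target to 1e−6 is accepted and the achieved
residual reported.  Monte-Carlo kernel sampling draws all four parameters
uniformly on (0, 150) and keeps Mexican hats.

## Bump solutions

The bump interior (p/(1+2p), 1/(1+2p)) is an exact fixed point of the active
dynamics.  The existence condition at the boundary,
f_in·[∬_disc w − 2κ] − κ = 0, is implemented exactly as written, including
the −2κ term; the disc integral at a boundary (or interior) point uses the
closed forms ∫_{|r'|<a} K₀(|r−r'|)dr' = 2π[1 − aK₁(a)I₀(r)] (r ≤ a) and
2πaI₁(a)K₀(r) (r ≥ a) rather than 2D quadrature — the test suite checks the
closed form against brute-force `dblquad`.  Radii come from sign-change
bracketing of the residual on a 400-point log grid on (0, 20 σ_I] and Brent
polishing; at most two roots exist because the boundary input u(ρ) is
unimodal.  The smaller root is unstable, the larger stable to radial
perturbation (both verified by direct simulation in the tests).

Shift (drift) stability is estimated by simulation rather than linearization:
the rasterized bump is displaced by 0.2 cells via a spectral phase ramp,
evolved noise-free, and the growth rate fitted to log COM-displacement over
the window where the displacement grows from 0.01 to 1 cell.  This reproduces
the sign and the E/I-ordering of the drift instability without the
unpublished eigenvalue machinery; runs whose displacement never clears the
floor return an "indistinguishable from zero" flag.  The measurement needs
≤ 0.25 units/cell: on coarser lattices, and for some parameter sets even at
that resolution, marginally unstable bumps pin to the grid and the estimator
honestly reports a rate near zero, so the E/I-ordering of rates is
resolution-fragile at desk scale even though positivity is robust.

## 1D traveling waves

In the co-moving frame the active-region profile solves dF/dx = (2F+H−1)/c,
dH/dx = (pH−F)/c with F(0) = H(0) = 0, giving
F = f_in(1 − e^{αx/c}[cos(βx/c) + A sin(βx/c)]) with α = (2+p)/2,
β = √(p(4−p))/2, A = (2−α+1/p)/β (and similarly H with B).  The sign of the
sine coefficient is fixed by requiring the profile to satisfy this ODE
system; the tests verify it against matrix-exponential integration.  Behind
the active region both fields decay exponentially.

The 1D reduction uses the **transverse-integrated kernel**
w₁(x) = ∫ w(√(x²+y²)) dy, which has the closed exponential form
s·(2/3)[e^{−|x|/s} − e^{−2|x|/s}/2] per Bessel term (from
∫K₀(√(x²+y²))dy = πe^{−|x|}).  This makes the two boundary conditions
u(0) = u(−L) = κ exact for planar fronts of the 2D field, and it is the same
kernel the 1D line simulator uses, so solved waves propagate at their
analytic speed in direct simulation (within ~2% at 0.25 units/cell).  With
the bare radial profile as a 1D kernel the boundary conditions have no
solutions anywhere in the explored E/I range.

`solve_wave1d` minimizes the two squared boundary residuals over (log c,
log L) from a seeded Latin-hypercube (c ∈ (0.01, 50), L ∈ (0.05, 30)),
keeping every distinct minimum below 1e−10 κ² (quadrature: 3001-point
trapezoid on [−L−40c, 0], where the tail has decayed to machine noise).
All minima are returned sorted by (c, L); an unconverged error carries the
best candidate.

## 2D teardrop waves

The boundary is an elliptical front ρ = L_f L_w/√(L_w²cos²θ + L_f²sin²θ) for
θ ≤ π/2 joined at the widest point to the tail
ρ = L_w − L_a[1 − 1/(1 − L_b cos²θ)], 0 < L_b < 1.  Two tail-length labels
are exposed: L_t = L_w + L_a L_b/(1−L_b²) and the boundary's own apex
ρ_tail(π) = L_w + L_a L_b/(1−L_b); they disagree for any L_b > 0, so both are
reported and neither enters the fitting.  Interior (f, h) values follow the
1D profile along propagation-axis chords with local length σ₊(y) − σ₋(y);
rasterization is nearest-grid-point with no anti-aliasing, and the field is
exactly zero outside the boundary.

`fit_wave2d` discretizes the boundary at 64 equally spaced angles (θ = π/2
assigned to the front) and minimizes Σ[u(θᵢ) − κ]² with a compass pattern
search in log/logit coordinates (deterministic multi-start under a seed).
The speed c enters the objective only through the interior fill and is
poorly identified by it; with c free the search can walk into the c → 0
corner of the family, which is a rasterized stationary bump (itself an exact
threshold solution and hence a genuine minimum).  `fit_speed=False` holds c
at the initial value and is the recommended mode for generating wave initial
states.  At scaled-down resolutions no teardrop reaches boundary residuals
below 5% of κ — the family is an approximation, and the released wave
relaxes to the true attractor within the ~50 ms transient.

## Simulator

Classical RK4 on the pair of field equations, with u computed by circular
FFT convolution against the kernel sampled on the lattice at minimal-image
distances and scaled by the cell area (equivalent to the Riemann sum of the
continuum integral; verified against an O(N²) double sum at 1e−10).
Continuous noise enters as μ = f·ξ added to df/dt and subtracted from dh/dt,
with ξ i.i.d. Gaussian per cell, drawn once per step and held through the
four stages; no 1/√dt rescaling is applied, so σ_ξ values are tied to the
step size (dt = 0.01 rescaled time throughout).  After each step f and h are
clamped back to the probability simplex (clamp events are counted and
reported in run metadata).  A single perturbation can be applied either as
an additive i.i.d. Gaussian kick to f (`single_kick` mode) or
multiplicatively, f → f(1 + a·ξ) (`perturb_multiplicative`), the one-shot
analogue of the μ = f·ξ noise that leaves silent regions silent; the regime
and switching studies use the multiplicative form.

Initial-state builders cover bumps, planar wave strips, single teardrops and
n randomly placed/oriented teardrops (rejection-sampled with pairwise margin
2 σ_I, abort after 1000 attempts).  Movies are stored in HDF5 with the full
configuration as attributes; runs are bit-reproducible under a fixed seed.

## Tracking and classification

Patterns are connected components of {f > 0.5 f_in} under 8-connectivity
with periodic wrap (union-find across the edges); components under 4 cells
are dropped.  Centers of mass are f-weighted circular means per axis, exact
for wrapped blobs.  Tracks are matched frame-to-frame by nearest periodic
COM distance (greedy).  Velocities are central differences of the unwrapped
path smoothed by a 10-point moving average; accelerations repeat the
operation on the smoothed velocity.

States are labeled on 20 ms windows with 50% overlap: *bump* if mean v_tot
is below v_eps, *traveling* if moving with mean a_tot below a_eps,
*rotating* if both exceed threshold with near-constant v_tot (relative std
< 25%).  Defaults v_eps = 0.05 cells/ms and a_eps = 0.2 v_eps are stated
choices (the source analyses publish none) and are configurable.  Regimes:
IV if any component covers > 25% of the domain, III if the post-transient
component count grows, else I/II by majority vote of the windowed labels of
the longest-lived pattern; the first 50 ms are skipped as transient.

Switching analysis segments the label series into dwells; runs shorter than
6 windows are absorbed into their neighbors.  That filter is calibrated on
the noise-free control at the transition point, where windowed acceleration
of a deterministic rotating orbit occasionally dips through the threshold for
a few windows — classification flicker, not a physical transition — and the
same filter is applied unchanged to the noisy runs.

## Statistics

* Periodogram: Hann window, one-sided, DC dropped, coefficients normalized
  to unit sum; frequencies in Hz via τ.
* DoF = (ΣS)²/(N ΣS²): equals 1 for a flat spectrum and 1/N for a single
  occupied bin.  (The alternative N-placement would give N² for a flat
  spectrum, contradicting both stated limits.)
* ApEn(m, r): Chebyshev distance, self-matches included, natural logs;
  defaults m = 2, r = 0.2·sd.  The estimate is biased low at small r
  (undersampled templates), so tolerance-monotonicity holds only for
  adequately sampled r.
* DFA: integrate and demean, non-overlapping boxes from the series start
  (trailing remainder discarded), per-box linear detrend, RMS fluctuation;
  ~20 log-spaced box sizes from 10 to N/4; the exponent is the log–log
  slope excluding the two smallest boxes (small-n bias).  Calibration on
  2¹⁴-point references: white 0.50, Brownian 1.49, 1/f 1.00 (20-seed means).
* Reference noise: white (i.i.d. Gaussian), Brownian (cumulative sum),
  1/f (white spectrum shaped by 1/√f, inverse-transformed).

## Spatiotemporal spectra

3D FFT of f(x, y, t) with a temporal Hann window only (the spatial axes are
periodic); modulus taken; the two spatial-frequency axes reduced to annuli
one frequency cell wide by bin *means* (sums would over-weight wide annuli);
negative temporal frequencies folded onto positive.  Velocity-line profiles
sum, for each velocity v, the linear interpolation of the spectrum at
f = ω/v over all ω > 0 (DC excluded — the profile targets propagation, not
mean activity); the default grid is 100 log-spaced velocities spanning the
resolvable band.  A rigidly translating test blob peaks within one velocity
cell of its true speed.

## Scaled-down study conditions

The reference configuration (601² cells, multi-second runs) is retained as
the default `SimConfig`, but the regime and switching studies in the test
suite run at desk scale: 192² cells at 0.125 field units/cell, 300–600 ms
simulated.  Resolution matters physically here: at ≥ 0.25 units/cell slow
waves lock to the grid (the discrete threshold crossing cannot advance), and
the rotating band narrows to a single W_I value; at 0.125 units/cell seeded
1D waves propagate within 2% of their analytic speed and the rotating band
spans several W_I units.  The frozen sweep (W_E = 200, σ's as reference,
p = 0.42) classifies rotating at W_I = 114, traveling at W_I = 105, and
splitting at W_I = 95, with the bistable transition near W_I = 109, where
weak multiplicative noise (σ_ξ = 0.02) produces no state transitions and
σ_ξ = 0.3 drives a single run through both rotating and traveling states.

## What the synthetic fixtures do and do not show

Reference noises and translating-blob movies have exactly known exponents
and speeds, so they calibrate the estimators, not the model.  Passing them
shows the statistics pipeline is correct; it says nothing about cortical
data, where waves deform, collide and change speed.  The scaled-down field
simulations probe the model's qualitative phenomenology (which attractor,
whether splitting or switching occurs), not quantitative speeds or
lifetimes, both of which carry O(grid) discretization bias at desk scale.

## Known limitations

* Attractor selection near regime boundaries is basin-sensitive: slightly
  different initial shapes or perturbation seeds can land a bistable run in
  either state.  The shipped protocols (fixed fitted shape, fixed seeds) are
  chosen for reproducibility, not as measurements of basin volumes.
* The teardrop family does not close the threshold condition exactly; fitted
  shapes are initial conditions, not exact solutions.
* Noise amplitude is dt-coupled (no Euler–Maruyama scaling), so σ_ξ values
  are comparable only at the fixed step size.
* Tracking assumes patterns stay separated by more than their per-frame
  displacement; it does not handle merge events gracefully (splits open new
  tracks).
* No spectral (Evans-function) stability analysis; drift stability is a
  simulation-based estimate.
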