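# Methods

This note documents the models implemented in `cyanopbr`, their
assumptions, the numerical choices behind them, and what the synthetic
test data can and cannot show.

## Light field

A flat plate of width `L` (m) is illuminated on one or two faces with
incident photon flux `I0` (µmol m⁻² s⁻¹ per face). Local intensity
follows Beer–Lambert decay, `I(z) = I0·exp(−a·z)`, with extinction

    a = τc·(1000·X) + 3·αg/db   [m⁻¹]

from cell absorption (τc = 0.126 m² g⁻¹; biomass X converted from
g L⁻¹ to g m⁻³) and bubble scattering (gas hold-up αg = 0.0067, bubble
diameter db = 0.002 m, contributing 10.05 m⁻¹). Two-sided illumination
is the superposition of two independent exponentials, one per face,
with no interfacial reflection. Scattering anisotropy, wavelength
dependence and photoacclimation are outside the model.

The photosynthetic response is the Aiba (substrate-inhibition) form
`k(I) = I/(I + ks + I²/ki)` with ks = 165 and ki = 457 µmol m⁻² s⁻¹ for
growth and ks = 140, ki = 457 for hydrogen production. It peaks at
`I* = √(ks·ki) ≈ 275 µmol m⁻² s⁻¹`; above I* the culture is
photoinhibited.

The dynamics use the depth average `k̄ = (1/L)∫₀ᴸ k(I(z))dz`, evaluated
with the composite trapezoid rule on `n_steps` equal intervals
(weights 1, 2, …, 2, 1 over the interval count). The default is 20
intervals, which stays within 10% of a 10⁴-interval reference even at
12 g L⁻¹ in the 0.025 m laboratory plate (measured deviation ≈3.7%).
An exact cross-check exists for one-sided light: substituting
`u = I(z)` gives `k̄ = (1/(aL))·∫ du/(u + ks + u²/ki)`, used as a
quadrature oracle in the tests.

One subtlety worth recording: `k̄` is *not* universally decreasing in
biomass. For supra-optimal incident light (I0 > I*), self-shading moves
sub-surface layers toward the Aiba optimum and the average can rise
with X. Monotone decrease is guaranteed only when every layer sits on
the rising branch (I0 ≤ I*), and the property-based tests assert it
only there.

## Photo-autotrophic growth and Cmax

Under nutrient sufficiency, `dX/dt = k̄(I;X)·μmax,a·X − μd,a·X²` with
μmax,a = 0.255 h⁻¹ and μd,a = 0.00227 L h⁻¹ g⁻¹, at fixed 35 °C
(temperature effects are not modelled). The maximum sustainable
density Cmax is the nontrivial root of `k̄(I;X)·μmax,a = μd,a·X`, found
by Brent bisection on [10⁻³, 10³] g L⁻¹ with relative tolerance 10⁻⁶;
a missing sign change on the bracket is reported explicitly. Long-horizon
integration of the batch agrees with the root to better than 0.1% and
serves as the consistency check. In the transparent-medium limit
(τc = αg = 0) the system is exactly logistic with carrying capacity
`k(I0)·μmax,a/μd,a`, the analytic reference used in the tests.

For scale-up sweeps over reactor widths up to 0.5 m the quadrature
resolution is raised (default 2000 intervals). At high biomass the
photic zone is a boundary layer of a few millimetres (1/a ≈ 2–3 mm)
at each lit face; a 20-interval rule over a 0.2–0.5 m path places only
one or two nodes inside it, and the resulting quadrature error can even
invert the predicted ordering of designs across incident intensities.
With adequate resolution, Cmax is strictly increasing in I0 and
strictly decreasing in width, as the substitution-integral form
implies.

## Photo-heterotrophic growth and hydrogen production

Six states: biomass X (g L⁻¹), nitrate N (mg L⁻¹), normalized nitrogen
quota q (dimensionless), glycerol C (mmol L⁻¹), oxygen O₂ (model units,
L per L of culture, following the yield units), cumulative hydrogen H₂
(mL L⁻¹). Growth follows Droop kinetics: the rate scales with
`(1 − kq/q)`, so cells keep growing on stored nitrogen after external
nitrate is gone and stop when the quota hits the minimum kq = 0.165.
Nitrate uptake is Monod in N (KN = 50 mg L⁻¹), feeds the quota
(yield Y_q/X = 0.0317 g⁻¹) and drives photosynthetic oxygen evolution
(Y_O/X = 81.02 L g⁻¹). Hydrogen production
`dH₂/dt = Y_H/X·h̄(I)·X·f(N)·f(O₂)` (Y_H/X = 14.20 mL g⁻¹ h⁻¹) is gated
by two smooth switch functions: f(N) vanishes identically above the
100 mg L⁻¹ nitrogenase-inhibition threshold and approaches 1 as N → 0;
f(O₂) = 1 − O₂/√(O₂² + 0.1) is 1 when anaerobic. The smoothing
constants 0.1 are kept verbatim in model units. The fitted glycerol
half-velocity constant is KC = 0: growth is independent of glycerol
level whenever C > 0 (glycerol is always in excess in the underlying
experiments), implemented as the exact limit `C/(C+KC) → 1{C>0}` to
avoid 0/0.

Two small structural choices:

* the glycerol maintenance drain (−Y_C·X) is gated by C > 0, so
  glycerol cannot go negative if a long simulation exhausts it; under
  all shipped scenarios C never falls below ~25 mmol L⁻¹ and the gate
  is inactive;
* states are not clamped. The stiff solver may probe tiny negative
  excursions (≲100·atol); the light field sees max(X, 0), the nitrate
  Monod term is self-correcting, and excursions beyond 100·atol raise
  an error rather than being silently absorbed, since they indicate
  solver misconfiguration.

Integration uses implicit stiff methods (`solve_ivp` BDF by default,
Radau/LSODA selectable) at rtol 10⁻⁸, atol 10⁻¹⁰; explicit Euler-class
methods are unstable on this system, which is why the explicit RK4
integrator shipped here is deliberately a fixed-step *reference*
(Δt = 10⁻³ h) for cross-validation, not a production path. Over a full
240 h nutrient-replete batch the two agree to ~10⁻⁹ relative.

The scale-up hydrogen preset starts a "stationary-phase" culture:
X₀ as specified (3.5 g L⁻¹ for the published-scale sweep, 240 h batch),
N₀ = 0, q₀ = kq, O₂₀ = 0, C₀ = 50 mmol L⁻¹. Hydrogen is produced mainly
in the stationary and decay phases, so the sweep opens both switches at
t = 0; whether residual growth on glycerol (q₀ > kq) should be allowed
is not determinable from the available information, and the preset is
exposed as configuration.

## Parameter estimation

The original laboratory time-series are not tabulated anywhere, so the
estimation machinery is exercised on synthetic data generated by the
model itself: trajectories sampled at design times with independent
multiplicative Gaussian noise per variable (`y·(1 + s·ε)`), seeded and
reproducible. Defaults emulate the laboratory batch: the 0.025 m
one-sided plate at 92 µmol m⁻² s⁻¹, a nutrient-replete start
(X₀ = 0.2 g L⁻¹, N₀ = 500 mg L⁻¹, q₀ = 1, C₀ = 50 mmol L⁻¹, O₂₀ = 0),
observations of X, N, C, O₂ and H₂ at 40 points over 200 h, and 5%
relative noise where noise is wanted. Synthetic data share the model's
structure by construction, so parameter-recovery results demonstrate
identifiability and optimizer correctness — not model adequacy for real
cultures, nor robustness to structural mismatch, autocorrelated errors
or calibration drift.

The loss is a weighted sum of squared residuals with per-variable
weights 1/mean(|observed|), equalizing heterogeneous units. Two
transcriptions of the dynamics feed the same loss and agree to better
than 10⁻⁴ relative on noiseless fixtures:

* **shooting** — the stiff integrator, slightly relaxed during
  optimization (rtol 10⁻⁷) with the optimizer's finite-difference step
  (10⁻⁴ relative) chosen to sit well above the trajectory noise;
* **collocation** — orthogonal collocation on Radau points: each
  interval is split into elements of at most 1 h, the state inside an
  element is a degree-3 polynomial whose derivative matches the ODE at
  the three Radau nodes (5th-order Radau IIA), and the stage equations
  are solved element-wise as nonlinear systems.

Minimization is bounded trust-region-reflective least squares with up
to 5 seeded multistarts (uniform within bounds), stopping early once
the loss reaches numerical zero (10⁻⁹ on the weighted scale, relevant
for noiseless data). Non-convergence and simulation failures (mapped to
a large finite penalty, 10⁶ per residual) are reported on the result.
Standard errors are a Gauss–Newton covariance proxy from the final
Jacobian; they are indicative only and degenerate at active bounds, as
for the glycerol constant, which correctly pins to its lower bound 0
when glycerol never limits.

## Sensitivity analysis

Normalized sensitivity `S_y/x(t) = [y(x(1+δ),t) − y(x(1−δ),t)]/(2δ·y(x,t))`
with δ = 1% by default. S is reported as undefined (and 0) where
|y| < 10⁻⁶ in the output's units — the normalization is singular where
the output vanishes, e.g. hydrogen before the switches open. The
analytic anchor `S(H₂; Y_H/X) ≡ 1` (H₂ is exactly linear in its yield
and feeds back nowhere) holds to 10⁻⁶ and doubles as an integration
check. During growth, S(X; μmax,h) > 0 and S(X; kq) < 0: faster growth
raises biomass, a larger minimum quota shortens the growth phase.

## Mutant transform

For a hypothetical low-chlorophyll mutant with photosystem
cross-section σ reduced by fraction r (default 0.30): both Aiba
constants are inversely proportional to σ, so ks and ki (and the H₂
pair) scale by 1/(1−r); the cellular extinction cross-section τc is
proportional to the chlorophyll mass fraction, so it scales by (1−r).
The equivalent turnover and damage/recovery constants cancel in these
ratios and are not independent knobs. The mutant's depth-averaged
response dominates the wild type's at any biomass in a wide reactor
(less self-shading), giving higher predicted Cmax at 0.2 m; the gains
shrink in thin reactors where attenuation is not limiting.

## Problem sizes and tolerances used in the shipped checks

Batch simulations run 150–240 h. The published-scale sweeps use the
8-configuration design sets; sensitivity uses 150 output points;
recovery fits 4 free parameters (μmax,h, μd,h, kq, Y_N/X) on 40
observation times, with the KC-degeneracy fit adding KC ∈ [0, 5]. The
RK4 cross-check runs the full 240 h at Δt = 10⁻³ h against BDF at
rtol 10⁻¹⁰. These sizes are the package's standard verification
settings and complete in a few minutes on a single core.

## Known limitations

* No gas–liquid mass transfer, pH, temperature dependence, or glycerol
  electron bookkeeping for H₂ (its glycerol consumption is negligible
  against growth and maintenance).
* Dark H₂ production under fast mixing is not modelled; where mixing
  along the light path outpaces the enzymatic rates, the model may
  underestimate the workable biomass ceiling.
* The mutant analysis is a parameter transform on a hypothetical
  strain, not a model of mutant physiology.
* Published large-width predictions could not be reproduced entry-by-
  entry (the generating initial conditions and horizons are not fully
  specified); the package asserts the physically forced orderings and
  the independently verifiable 0.025 m anchor instead.
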