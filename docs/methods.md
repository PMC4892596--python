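# Methods

This note records the models implemented in `chemorace`, the defaults and
their provenance, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## 1. Linear-response theory of gradient climbing (`theory_core`)

A run-and-tumble bacterium swims at speed `u` along a direction that
decorrelates through two channels: tumbles (rate `1/tau_r`, scattering
angle `phi` with mean cosine `<cos phi>`) and rotational diffusion during
runs (`D_rot`). The two rates

    alpha = (1 - <cos phi>) / tau_r,      sigma = 2 D_rot + alpha

govern, respectively, the decorrelation by tumbling alone and the total
direction decorrelation; `sigma` is taken for three-dimensional
orientational decorrelation, consistently with the 1/3 projection factor
below. In a shallow gradient `dc/dx`, the mean up-gradient velocity is
`v = chi * dc/dx` with

    chi = (alpha u^2) / (3 sigma^2) * Integral_0^inf e^(-sigma t) K(t) dt,

where `K(t)` is the impulse response of the run/tumble bias to a unit
concentration impulse. The bilobed form

    K(t) = K0 lam e^(-lam t) [lam t - (1-A)/2 (lam t)^2]

has time integral `K0 * A`, so `A` quantifies the loss of precise
adaptation (`A = 0`: balanced lobes, adapted; serine responses are
measured around `A ~ 0.03` with `lam ~ 1 s^-1`). The Laplace transform is
elementary, giving the closed form

    chi = K0 u^2 alpha / (3 sigma^2) * lam^2 (sigma + A lam) / (sigma + lam)^3.

The memory-rate factor (the "bracket") is maximized at
`lam* = 2 sigma / (1 - 3A)`, defined for `A < 1/3`. The velocity
advantage of imprecise adaptation is quantified as the ratio of the
maximized bracket at `A` to the maximized bracket at `A = 0`; the ratio
is independent of `sigma` and evaluates to +6.3% at `A = 0.03`. The
statement that the advantage is "about 7%" corresponds to this maximized
comparison up to rounding; the comparison at the common memory rate
`lam*(A)` gives +6.6%, so any reasonable convention lands at 6–7%.

The linear-regime response amplitude as a function of the pathway
operating point is

    K0 ∝ a (1-a) h'(y) (1-y) / [h(y)(1-h(y))],     y = a / (a + K),

with `a` the fractional kinase (CheA-P) activity, `y` the fractional
CheY-P level under the quasi-steady-state relation, and `h(y)` the motor
clockwise-bias curve. For a Hill curve `h = [1 + (y/y0)^-H]^-1` the
expression collapses to `H K (1 - a)` (maximal at zero activity); for an
allosteric curve `h = 1/[1 + C((1+y/K1)/(1+y/K2))^n]` with `K1 > K2` the
amplitude peaks at an interior activity `0 < a* < 1/2`. The two shapes
differ qualitatively at `y = 0` (the Hill bias vanishes, the allosteric
bias has a basal level `1/(1+C)`), which is why the optimum moves. The
proportionality constant is fixed to 1: this amplitude is used only for
shape and argmax statements and is never mixed with the
micromolar-calibrated `K0` of the response kernel.

Numerics: kernel quadratures use adaptive Gauss–Kronrod with an upper
limit of `40 / min(lam, sigma)` and absolute tolerance 1e-12, with an
extra panel boundary at t = 1 s so that narrow early features are
resolved; `amplitude_argmax` prescans a 512-point grid and refines with
bounded scalar minimization (the Hill case returns the boundary 0
exactly). Endpoint amplitudes are evaluated at `a = 1e-9` and
`1 - 1e-9`.

## 2. Agent-based simulator (`rt_simulator`)

Agents carry position, a unit direction, a per-agent speed, a tumble
clock and the response state. One step applies, in order: tumble
decision at rate

    r = clip( (1 - Q) / (tau_r * m(c)), 0, 10/tau_r ),

reorientation with the persistent scattering law, rotational diffusion
of runners, advection `u dt`, and the response-filter update.

*Response state.* `Q(t) = Integral K(s) s_in(t-s) ds` is carried exactly
by a three-state exponential filter (the kernel is a polynomial in `t`
times `e^(-lam t)`): with deviations from the local equilibrium
`(c, c, 2c)` the one-step update is the closed-form matrix exponential
of the moment chain, so no history buffer or convolution is needed. At
rest in concentration `c` the output settles to `Q = K0_eff * A * c`.

*Sensing modes.* `absolute` applies the kernel amplitude to raw
concentration; `weber` rescales the amplitude by the local background,
`K0_eff = K0 * c_ref / (c + c_eps)` (defaults `c_ref = 100 uM`,
`c_eps = 1 uM`), which makes the gradient response scale like
`grad(c)/c` — the fold-change sensitivity of the pathway. The functional
form is a package choice; only its qualitative property (sensitivity
falls along the linear gradient) is relied upon.

*Run-time modulation.* The measured steady-state effect of non-adapted
attractant backgrounds is imposed directly as `tau_loc = tau_r * m(c)`,
with `m` interpolated log-linearly between measured anchors
(serine: 1.0 at 1 uM to 2.1 at 3 mM; aspartate over a 30 uM serine
background: 1.7 at 1 uM to 2.1 at 100 uM aspartate, flooring at the
serine-curve value 1.467 at 30 uM as the aspartate concentration
vanishes). Because `m(c)` already encodes the steady-state consequence
of the unbalanced kernel, the race presets keep the *dynamic* kernel
balanced (`A = 0`); carrying both would double-count the steady shift
and, at Weber amplitudes, clip the tumble rate to zero outright.
Kernels with `A > 0` are exercised in the theory-validation
configuration (absolute sensing, `m = 1`, shallow gradient, small
`K0 A c`), where the closed form applies.

*Scattering law.* `cos phi` is drawn from the linear-tilt density
`p(x) = 1/2 + b x` on [-1, 1] with `b = 3<cos phi>/2` — the simplest
one-parameter family consistent with the measured mean cosine 0.3 (the
full distribution is not constrained by the data we model). Rotational
diffusion uses the tangent-plane step with renormalization, giving
`<d(t)·d(0)> = e^(-2 D_rot t)`.

*Race geometry.* The lateral channel is 4000 x 725 x 300 um with
reflecting side walls. The injection channel maintains a fixed density
at the entry: each step the first 100 um of the channel is topped up to
the target line density with fresh agents, and agents crossing `x < 0`
return to the injection channel and are removed. This realizes the same
Dirichlet condition the continuum model uses. The reservoir at
`x = L` absorbs. The physical injection density (4e7 bacteria/ml, i.e.
8.7 per um of channel) is scaled by `density_scale = 0.125` by default
(~1.1 agents/um, peaking near 7000 concurrent agents per replicate);
rank-k front positions are rank statistics and shift only logarithmically
with density, and no quantitative front speed is asserted anywhere.

*Stability.* `dt <= 0.02 * min(tau_r, 1/lam)` is enforced. A fused
numba kernel accelerates the common case (no pitch constraint); the
numpy implementation is the reference path and covers all cases.
Randomness is pre-drawn from a seeded numpy Generator either way, so
identical configurations and seeds reproduce bit-identical outputs
within a path.

*Validation against the closed form.* `validate_against_theory` measures
the ensemble drift of independent agents in an unbounded linear profile
and compares with `chi * grad(c)`. Standard configurations use 5000
agents for 400 s. Power analysis: with `D = u^2/(3 sigma) ~ 93 um^2/s`,
the drift SE is `sqrt(2D/(T n)) ~ 0.01 um/s`, against predicted drifts
of 0.02–0.06 um/s for the configured gradients; gradients are kept
shallow enough that `K0 A c <~ 0.1` and the signal fluctuation scale
`K0_eff u |grad c| / lam <~ 0.1`. Known second-order effects (the
steady run-time shift at `A > 0` and the `grad D` transient of an
ensemble released at a point) contribute below one SE at these settings
and are absorbed by the 3-SE criterion.

## 3. Continuum model (`continuum_model`)

The channel density (bacteria per um) obeys
`d rho/dt = d/dx(D d rho/dx) - d/dx(v rho)` with `D = u^2/(3 sigma)` and
`v = chi dc/dx`, both optionally x-dependent through `m(c(x))` and the
Weber amplitude (`TransportCoeffs.from_theory` builds them from the same
presets the agent model uses). Boundary conditions: `rho(0) = rho0`
(maintained injection density), `rho(L) = 0` (absorbing reservoir).

The solver is a conservative node-centred finite-volume scheme with
central face fluxes (second order in dx) and implicit Euler time
stepping (first order in dt, unconditionally stable); the tridiagonal
systems are solved with banded LU. If the grid Peclet number
`|v| dx / D` reaches 2 the grid is refined automatically with a warning.
Mass bookkeeping uses the scheme's own boundary face fluxes, so the
discrete balance `d/dt Integral rho = J_in - J_out` holds to rounding.

The stationary profile solves the same operator directly; for constant
coefficients it matches `rho = (J/v)(1 - e^(v(x-L)/D))` with
`J = v rho0 / (1 - e^(-vL/D))`. Saturation of the rank-k fronts — the
plateau of `x_k(t)` solving `N(x_k, t) = k` for the tail-cumulative
`N(x,t) = Integral_x^L rho dx'` — follows once influx and outflux
balance; the plateau position decreases with `k`.

Consumption estimate: steady uptake `D_attr c'' = q rho_b` with pinned
end concentrations gives, for uniform cell density, a parabolic sag with
midpoint `q rho_b L^2 / (8 D_attr)`; the module reports the maximum
deviation relative to the midpoint of the linear profile and flags
regimes that would drive `c < 0`. Consumption is never coupled back
into the transport solve (the estimate justifies neglecting it at the
experimental densities).

## 4. Tracking-assay analysis (`track_analysis`)

Tumble filtering at 10 Hz with 0.3 um localization noise is genuinely
hard, and the estimators encode the standard counter-measures:

* **Span smoothing.** Speeds and headings are computed over a centred
  3-frame span. Raw frame speeds carry a noise scale of ~4 um/s
  (Rayleigh), which would produce ~1 false tumble per second; the span
  reduces it threefold.
* **Tumble label.** A frame is a tumble frame when its span speed falls
  below `max(0.5 * track median, 2.35 * noise scale)` or the heading
  change between adjacent spans exceeds 1.0 rad. The absolute floor
  makes stationary, noise-dominated stretches label as tumble even
  though the relative criterion alone cannot (the track median itself is
  then at noise level).
* **Run-time estimator.** Censored first/last runs are excluded; half a
  frame per detected boundary is added back (the conservative filter
  drops every tumble-contaminated frame, eating on average half a frame
  of run at each end). Two further instrument corrections matter in the
  short-run regime: a tumble segment much longer than one resolved
  tumble (`frames_per_tumble`, default 3 for the smeared detector) is a
  *pileup* of several tumbles separated by unresolvably short runs and
  is counted with its multiplicity, and the segment extent beyond those
  resolved tumbles is returned to the run-time exposure. With both, the
  estimator is unbiased within sampling error down to mean run times of
  0.5 s at 10 Hz. Tracks whose median span speed is below 6x the noise
  scale are excluded from run-time estimation (run/tumble discrimination
  is noise-limited there; run time does not depend on swimming speed, so
  the exclusion is unbiased).
* **Run-speed estimator.** Per bacterium, the RMS raw frame speed over
  interior run frames (two frames clear of every boundary), debiased for
  localization noise in quadrature, then corrected for projection:
  2-D tracks from the near-surface acquisition (see below) are rescaled
  by `1/sqrt(1 - pitch_max^2/3)`; isotropic 3-D projections by
  `sqrt(3/2)`; 3-D tracks need no correction. Population mean and SD
  are taken over per-bacterium values, matching the convention in which
  speed error bars are population SDs.
* **Turn angles.** Headings two frames clear of each run-flanked tumble
  are compared; the raw cosine is attenuated multiplicatively by noise
  and by rotational diffusion across the tumble gap, so it is divided by
  the within-run heading autocorrelation at the same span/lag structure,
  measured from the same tracks. Both attenuations cancel because the
  reference pairs carry them identically.

## 5. Synthetic data (`synthetic_data`)

Defaults are the study conditions: running speed 15 um/s (population SD
5 um/s, truncated at 3), baseline run time 1.15 s, `D_rot = 0.1 rad^2/s`,
`<cos phi> = 0.3`, kernel memory rate 1/s, gradients 0 to 1 mM over
4 mm, 30 uM serine background in the combined condition, snapshots every
5 min, five replicates, 2 h races, 10 Hz tracking with 0.3 um noise.
The per-attractant response amplitudes are not printed anywhere and are
package defaults: `K0 = 1.0 /uM` for aspartate (sized so aspartate
fronts advance at order 1 um/s) and `K0 = 2.0 /uM` for serine (the
strain is more sensitive to serine; with matched kernels and the
measured modulation curves, an amplitude difference is also the only
mechanism that can order serine fronts ahead of the
aspartate-plus-background condition, whose run-time boost is pointwise
at least as large). `default_parameters()` tags every value as
`measured` or `package-default` with a one-line note.

Tracking assays render tumbles as 0.2 s stationary dwells (within the
measured range of tumble durations) so a 10 Hz assay can resolve them,
and constrain the swimming pitch to `|d_z| <= 0.5`: 2-D video microscopy
of E. coli observes cells swimming near the chamber surface, not an
isotropic 3-D ensemble, and under full isotropy 16% of runs point within
23 degrees of the optical axis and are indistinguishable from tumbles in
projection — no estimator can undo that. Azimuth-only resampling keeps
the scattering-angle marginal exact under the pitch constraint. Race
and validation simulations keep full 3-D isotropy.

What passing tests therefore do and do not show: the pipeline recovers
run times, speeds and turn statistics from data with the noise,
projection, discretization and pileup pathologies of real tracking
assays, under an acquisition model (near-surface swimming, fixed dwell,
Gaussian noise) that is idealized; they do not certify performance on
imaging artefacts the generator omits (motion blur across 200 ms
exposures, cell-cell occlusion, duplicated detections across stitched
sub-images, track-linking errors).

## 6. Sizes used by the test suite

Tests scale the simulations to what the conclusions need: tracking
closures use 150–500 tracks of 40–80 s; drift validation 5000 agents
for 400 s per parameter point; races 5 replicates of 30 min at
`density_scale = 0.125` (the 2 h default covers saturation, which the
continuum model probes more cheaply). The front-speed assertion is an
ordering with replicate SEs, not a quantitative slope: the measured
slopes depend on the unprinted response amplitudes.

## 7. Known limitations

* The rate law `r = (1 - Q)/tau_loc` with zero-clipping is one
  consistent microscopic realization of the linear-response kernel;
  deep in the clipped regime (entry of the Weber-scaled channel, where
  the effective amplitude is large) the model is outside the linear
  theory by construction.
* Tumble duration is zero in races (instantaneous reorientation),
  consistent with `alpha` carrying no tumble-time correction; the
  tracking generator overrides it to make tumbles observable.
* The continuum and agent models agree on transport coefficients by
  construction (`TransportCoeffs.from_theory`), but the agent model's
  clipped nonlinear zone near the channel entry has no continuum
  counterpart; comparisons are made at matched constant coefficients.
* Attractant consumption, hydrodynamic interactions, growth and
  motor-remodeling adaptation are not modelled; consumption is bounded
  by the steady-state estimate only.
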