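# Methods

`thermotrap` models a thermogravitational trap: a thin, vertical,
water-filled chamber (gap `w`, height `H`, depth `d`) whose two faces are
held at different temperatures.  Two transport processes driven by the same
heat flow combine to concentrate dissolved biomolecules at the chamber
bottom, to confine them there against a flushing flow at the open top, and
to exchange feed and waste molecules with that flow.

## Transport model

Each solute obeys an advection-diffusion-thermophoresis equation in the
2-D chamber cross-section (x across the gap, z along the height):

    dc/dt = -div j,    j = -D grad c + (u + v_T) c

* **Thermophoresis.** The temperature field is linear across the gap and
  uniform along the height (sapphire plates impose near-uniform wall
  temperatures; end effects are negligible at aspect ratio H/w ~ 200).
  The thermophoretic drift is `v_T = -D S_T grad T`; for a positive Soret
  coefficient `S_T` it points toward the cold wall.  Without flow it alone
  would produce the cross-gap Soret equilibrium `c ~ exp(-S_T (T - T_cold))`
  — a modest factor `exp(S_T dT)` ~ 1.1 for a protein.
* **Convection.** The density difference between the warm and cold sides
  drives a single laminar roll.  Away from the ends it is the fully
  developed Boussinesq slot profile

      u(x~) = -(g beta dT w^2 / (12 nu)) x~ (1 - x~)(1 - 2 x~),  x~ = x/w,

  positive upward, sinking on the cold side.  (A second-order finite
  difference solve of the slot momentum balance is kept as an independent
  test oracle; it fixes the 1/12 prefactor.)  The roll must close inside
  the chamber, so the 2-D field is built from the streamfunction
  `psi(x, z) = G(x) s(z)`, with `G` the integral of the slot profile and
  `s` a smoothstep ramp from 0 at each end cap to 1 over one turning
  length (default: one gap width).  Face velocities are taken from corner
  values of `psi`, making the discrete field divergence-free to machine
  precision and the normal velocity zero on every wall.  Without the end
  closure, solute carried up the hot side piles up against the top wall
  (it can only return by cross-gap diffusion), which distorts the top
  boundary layer and, in flow scenarios, inflates the leak into the
  channel several-fold.
* **Interaction.** Thermophoresis segregates solute toward the cold,
  downward-moving stream; the roll then transports it to the bottom.  The
  steady vertical profile is exponential, `c(z) ~ exp(-q z)`, with an
  exponent `q` far larger than the bare Soret factor — the
  thermogravitational amplification.

Fluid properties (`nu`, `beta`, `rho`, `eta`) come from a built-in table
for liquid water, evaluated at the mean chamber temperature, with a
dimensionless viscosity factor `f_visc` (default 1.3 for the
transcription-translation mix) multiplying the viscosity and — via
Stokes-Einstein — dividing every radius-derived diffusion coefficient.
Between scenario temperatures, diffusion coefficients rescale as
`T/eta(T)`.

## Discretization

Finite volumes on a uniform cell-centered grid (default 34 x 350 for the
170 um x 35 mm chamber), conservative by construction: the only mass terms
are face fluxes, so a closed trap conserves total solute to linear-solver
precision.

Face fluxes use a two-point weighting `F = (A D / h)(B(-Pe) c_a - B(Pe) c_b)`
with `Pe = v h / D`.  The default scheme (`sg-central`) combines:

* **Cross-gap faces:** Scharfetter-Gummel exponential fitting,
  `B(x) = x / (e^x - 1)` — exact for the constant thermophoretic drift, so
  the Soret equilibrium is reproduced to <0.5% on a 64-cell slice.
* **Vertical faces:** central differencing, `B(x) = 1 - x/2`.  The vertical
  cell Peclet number is ~5-10 for a protein; an upwinded flux there would
  add false diffusion `~u dz/2` of several hundred um^2/s — several times
  the molecular diffusivity — and visibly suppress the accumulation
  exponent (the steady bottom/top ratio drifted from 25 to 40 under grid
  refinement in our experiments with a fully upwinded scheme).  The
  vertical profile varies on the millimetre scale, so the second-order
  central flux is both accurate and, in practice, positivity-clean; with
  it, the steady ratio changes by <0.01% from 34x350 to 68x700.

Pure `sg` and `upwind` schemes remain available (and are the ones with a
positivity guarantee).  Any face Peclet number above 20 is reported via a
warning rather than silently accepted.

Time integration is backward Euler with sparse LU factorizations cached per
step size; the step ramps geometrically from 10 s to 30 min (2 h for
diffusion-only runs), so six-month horizons integrate in about a minute.
Mass accounting of channel inflow/outflow uses the implicit end-of-step
values, making the discrete balance exact.  Stationary states are obtained
by a direct sparse solve; in the closed trap the operator's nullspace is
normalized by replacing one row with the volume-weighted mass constraint.

## Open top and channel coupling

The open top is a well-mixed channel compartment (default: a 1 mm diameter
channel spanning the chamber depth, ~7.9 ul) flushed at `Q` = 11 ul/h.  It
exchanges with the top cell row by a diffusive conductance
`g = D A / (dz/2 + R_ch)` per top cell (`A` the cell's top face area,
`R_ch` = 0.5 mm), i.e. the well-mixed channel concentration notionally
lives at the channel center, which keeps the conductance grid-convergent.
There is no advective trap-channel exchange: the convection roll closes
inside the trap, so the fluid velocity through the top boundary is zero.

This coupling is the model's largest structural uncertainty, and it is
deliberately simple.  For the standard trap it gives a total conductance of
~1 ul/h against the 11 ul/h flush.  Consequences (all reproduced by the
acceptance script): short-term retention of an accumulated protein is
~97% after 9 h of flow, but the quasi-steady leak `lambda ~ Q_eff c_top / M`
~ 1.7e-3/h empties the trap on a ~month scale, and the initial phosphate
charge in the feed/waste scenario washes out with a ~100 h time constant.
Reported long-term figures for comparable devices imply an effective
junction conductance roughly fifty times smaller; reproducing them would
require resolving the actual inlet/outlet junction geometry, which this
model does not attempt.

## Species parameters

* **Reporter protein (sfGFP).** Diffusion from Stokes-Einstein with
  hydrodynamic radius 2.4 nm at the mean temperature, divided by
  `f_visc` = 1.3 → D ~ 97 um^2/s at 33.5 degC.  The Soret coefficient is
  *calibrated*: a bracketed root search sets `S_T` so the closed-trap
  steady state shows a 25-fold bottom/top point-sample ratio (the observed
  relative accumulation), giving `S_T` ~ 5.8e-3 1/K.  Everything else the
  model predicts for this species follows from those two anchors.  A
  caveat worth stating: the reported ~3,000 h isothermal relaxation time
  implies an effective protein diffusivity of ~35 um^2/s in the reaction
  mix; with the Stokes-Einstein value the slowest diffusive mode of the
  35 mm column (tau = H^2/(pi^2 D) ~ 420 h at 27 degC) caps the
  time-to-5%-uniformity at ~1,540 h for *any* non-negative profile, and
  the model yields ~1,100 h.  The same difference makes the simulated
  accumulation onset (~53 h to 95% of steady) slower than the observed
  ~24 h: a smaller molecular D strengthens convective (Taylor-type)
  dispersion and speeds the column up while slowing bare diffusion down.
* **Orthophosphate.** Printed literature coefficients, used as-is:
  D = 959 um^2/s, S_T = 0.7e-3 1/K.
* **ATP.** Phosphate-like, rescaled by the Stokes-Einstein size ratio: the
  printed phosphate D implies r ~ 0.32 nm; with r_ATP ~ 0.71 nm,
  D_ATP ~ 330 um^2/s and S_T ~ 1.6e-3 1/K (package fixture).
* **Feed mix (activation scenario).** Amino-acid/tRNA-like: D = 300
  um^2/s, S_T = 2e-3 1/K (fixture).

## Reactions

The feed/waste scenario converts ATP to phosphate at a spatially uniform
Michaelis-Menten rate `V_max c / (K_M + c)`.  The rate law's parameters are
package fixtures chosen once on biochemical grounds (K_M = 100 uM, the
NTP-Km range of T7 RNA polymerase; V_max = 1e-3 uM/s, a dilute
transcription-scale turnover; initial phosphate 1 mM).  The split reaction
step is the backward-Euler update of the rate law, which reduces to a
quadratic with a closed-form positive root — unconditionally stable,
positivity-preserving at any dt, and exactly stoichiometric cell by cell.
The "stable state" of the phosphate pool is declared at the first time
after which |d(total phosphate)/dt| stays below 1% of the reference
production rate (the MM rate at the 1 mM feed concentration integrated
over the trap); with the fixtures above this occurs at ~475 h, and the
pool is flat to 0.1% of the reference by ~800 h.

The feeding-activation scenario is explicitly qualitative.  Reporter
synthesis follows a Hill switch (threshold 0.3 uM, exponent 4) in the fed
limiting component, scaled by a transported "machinery" tracer with
protein-like coefficients and a finite synthesis capacity (5 uM product
per uM machinery).  The capacity term represents batch expression
lifetime; without it, bulk machinery resupplies the top region
indefinitely and the isothermal top signal never declines.  With it the
model reproduces the observed shapes: isothermally the signal rises near
the feed inlet and is then flushed away, while under the gradient the
bottom signal grows monotonically and dominates.

## Measurement statistics

Two sampling conventions, both implemented because real experiments use
both: gap-averaged *point samples* in a 0.5 mm window, 0.5 mm from each
end (real-time imaging; the "25-fold relative / 3-fold absolute"
convention), and *thirds fractions* — volume-weighted means over exact
height thirds, emulating freeze extraction.  Thirds averaging attenuates
the extremes: the same profile that shows a 25-fold point ratio shows
~9-fold between bottom and top thirds (the ideal unit-mean exponential
with k = ln 25 gives 2.06 / 0.70 / 0.24 and an 8.5-fold ratio, used as an
analytic test oracle).  Retention is the trap-region amount (channel
excluded) over its initial value.  "Six months" is read as 183 days.

## Synthetic data and calibration

The synthetic generator evaluates the forward model at chosen
positions/times and applies multiplicative log-normal noise (unit mean,
configurable CV, default 5%) plus an additive Gaussian floor (sd = 1% of
the initial signal); ground truth is always written to a sidecar.  It
emulates relative fluorescence kinetics only — no photophysics
(maturation, bleaching), no optics, and no biological variability — so
recovery tests validate the estimator, not the realism of fluorescence
imaging.

Fitting profiles out one multiplicative scale per position (fluorescence
is relative) and minimizes residuals weighted by `1/(model + 0.1 max)` — a
mixed error model matching the generator's multiplicative-plus-floor
structure; unweighted residuals bias the Soret estimate low when the top
signal decays to the floor.  Parameters are log-transformed, bounded, and
optimized with deterministic multi-starts; confidence half-widths come
from the Gauss-Newton curvature.  A single position, or a single steady
profile with D and S_T jointly free, is rejected as non-identifiable
(the stationary profile constrains only their ratio).

## Scenario horizons and problem sizes

Default grid 34 x 350 (about 12,000 unknowns; all headline numbers change
by <3% under 2x refinement in each direction, <0.01% for the steady fold).
Horizons: accumulation 120 h, retention 16 h pre-run + 4,392 h of flow,
relaxation up to 10,000 h (terminates at the uniformity criterion),
feed/waste 1,500 h, thickness scan 11 gaps x 16 h, activation 72 h.  The
full scenario suite runs in about three minutes on one core.

## Known limitations

* 2-D per unit depth; no depth-wise structure, no tilted geometries.
* The analytic thermal and flow fields ignore plate conduction detail and
  entrance effects beyond the smoothstep end closure.
* The channel junction is a single well-mixed compartment (see above);
  long-horizon retention and washout figures are coupling-limited and
  should be read as order-of-magnitude under this geometry.
* Temperature dependence of S_T is not modeled; `f_visc` is a single
  scalar for the whole mix.
* Expression kinetics are a qualitative stand-in, not a mechanistic
  transcription-translation model.
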