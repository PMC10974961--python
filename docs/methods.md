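# Methods

This note records the modeling choices, default parameters and known
limitations of the package; it is the place where design decisions that were
genuinely open are argued.

## Process model

The stress-energy description of stirred media milling factorizes the
specific energy input to the product into the energy scale of a single
bead–bead stressing event (SE) and the number of such events (SN):
`E_M = SE · SN`.  Neither factor is directly measurable on a production
mill, so the package computes their measurable surrogates from the sensor
channels of a recirculation-mode mill:

- **Shaft power** `P = F · r · 2π · n` from the load-cell force `F`, the
  load-cell lever radius `r` and shaft speed `n` (rev/s).  A pre-run no-load
  measurement gives `P0`; net power `P − P0` is the mechanical input to the
  chamber contents.  The no-load model is constant when the observed speed
  varies by < 1% in the no-load segment, otherwise affine in speed.
- **Mass-specific energy** is the running rectangle-rule sum
  `E_M,i = E_M,i−1 + (P_i − P0,i)(t_i − t_{i−1})/M` in kJ/kg.  The
  discretization follows the plant recursion exactly (sample value times the
  preceding interval) rather than a trapezoid; the test suite bounds the
  discretization error against a 1000×-finer brute-force integration
  (< 0.2% on smooth profiles at 1 s sampling).  Negative instantaneous net
  power (sensor noise dipping below the no-load model) is retained, not
  clamped, and logged, because the recursion has no clamp.
- **Average stress energy** `SE̅ = κ · mean(v_t²)` in μNm, with
  `v_t = π·D·n` the tip speed.  Physically `κ = ρ_GM · d_GM³` (bead density
  times diameter cubed); bead properties and rotor diameter are proprietary
  equipment data, so by default κ is **calibrated** to a reference operating
  point, 0.88 μNm at 1050 rpm, which preserves every ratio the quadratic
  speed law implies (e.g. 875 rpm → 0.88·(875/1050)² = 0.61 μNm).  Explicit
  bead descriptors override the calibration when available.
- **Turnover cycles** `N_i = N_{i−1} + ṁ_i (t_i − t_{i−1})/M`: transported
  mass over batch mass.  Mass flow falls back to volume flow times the
  suspension density (default 1.1 kg/L) when the mass-flow channel is
  absent.

The stress number itself is proportional to `n · N_GM · Τ` with an
unspecified proportionality constant and an ideal residence time that is
never evaluated; following the model's use in practice, N serves as the SN
surrogate and SN is never computed absolutely.  `N_GM` and the bead fields
are housed in the configuration but unused by default.

## Energy balance

The chamber balance `Q̇_S,out − Q̇_S,in = (Q̇_C,in − Q̇_C,out) + Q̇_Agi − Q̇_Atm`
is quasi-steady per sample: no thermal hold-up of the chamber contents, no
bearing heat.  Component terms are linear in their flow and temperature
difference.  The atmospheric term is lumped into a single loss coefficient
α·A in W/K, **default 0** (no surface/coefficient data exists for the
equipment, and the remaining terms dominate); when enabled, the unmeasured
surface temperature is approximated by the suspension outlet temperature,
which keeps the rearranged balance linear and solvable in closed form.  The
algebraic sign conventions follow the balance as stated above verbatim; the
suite checks, on random inputs, that the outlet-temperature predictor is the
exact root of the closure residual.  Heat capacities default to
cp_S = 3900 J/(kg·K) (concentrated aqueous suspension) and
cp_C = 4180 J/(kg·K) (water); both are configurable and every shipped check
is either ratio-based or a generator round-trip, hence insensitive to them.

## Size–energy correlation

Mean particle size against specific energy is fitted as a power law,
ln x on ln E_M by ordinary least squares — the data span no grinding-limit
plateau, and the closed-form inverse is what maps a size window onto an
energy window.  An asymptotic variant `x = x_lim + a·E^b` is available
behind a flag (bounded nonlinear least squares seeded by the power fit).
On the packaged 22-batch reference table the fit gives
x = 784.3·E_M^−0.2366 nm with rms residual 2.5% and max residual 5.6% (the
2400 kJ/kg batches sit slightly above the 2134 kJ/kg cluster, a local
non-monotonicity no monotone law can thread exactly).  Predictions and
inversions outside the fitted range warn; targets more than 25% beyond the
fitted size span raise, a guard chosen because the canonical acceptance
window (120–180 nm) itself slightly exceeds the fitted span (111–174 nm)
and must remain usable while gross extrapolation must not.

PdI is modeled only as a plateau statistic (0.11 above ~200 kJ/kg); the
input drug size x_90,3 is range-checked but excluded as a predictor — both
show no effect on milled size within the demonstrated ranges.  All
dispersion statistics use the sample (n−1) standard deviation;
RSD = 100·sd/mean; groups with fewer than two members are excluded.

## Design space

The design space is a polygon in (E_M, N).  Its E_M edges are the inverted
size law at the window edges; its N edges the operationally demonstrated
turnover span (35–232 for the reference table).  Because no batch was ever
run in the low-E_M/high-N and high-E_M/low-N corners, those corners are
beveled: each cut is the tightest 45° supporting line — in edge-normalized
coordinates — of the in-window batches, so every compliant batch stays
inside by construction and the region claims nothing beyond coverage.  This
yields six vertices by default.  Whether the registered geometry derives
from stress-energy limits, flow limits or coverage is not fixed by the data,
so an explicit vertex list overrides the construction verbatim when fidelity
to a registered shape is required.  Membership is boundary-inclusive (a
batch on the edge of the demonstrated region is demonstrated), with a
1e-9-relative distance tolerance absorbing floating-point fuzz for points
exactly on an edge.  The size surface over (E_M, N) is piecewise-linear on
the Delaunay triangulation of the measured batches: exact at supports,
overshoot-free, undefined (NaN) outside the convex hull.

## Control strategy

The packaged strategy mirrors the plant's criticality designations: E_M and
N are the CPPs (controlled jointly via the design space), mean particle size
the CQA (in-process control window 120–180 nm), and the remaining parameters
non-critical with document- or range-based controls (coolant inlet 8–13 °C,
speed 875–1215 rpm, flow 5–20 L/min, batch mass 62–175 kg, outlet
temperature 18–27 °C, SE̅ 0.61–1.17 μNm, x_90,3 ≤ 7.6 μm).  The source
tables disagree on the speed cap (1215 vs 1225 rpm, most likely a typo);
the default uses 1215 and emits a loud warning for batches in between, with
the alternate bound one switch away.  All checks are boundary-inclusive.
Disposition: any fail → reject; warnings only (e.g. unchecked values —
never a silent pass) → review; otherwise accept.

## Synthetic runs

The generator emulates the batch protocol: a no-load segment at set speed
with zero flow, processing from 5 L/min, a linear ramp (default 60 s) to the
set flow once three turnover cycles are reached, then constant flow until
the target E_M.  Net shaft power is a scenario setpoint (default 2200 W,
optionally scaled with speed cubed as stirred-media power draw roughly is)
— the plant's true power draw and its torque dynamics (viscosity rise as
particles shrink) are not public, so the constant-setpoint stand-in is
flagged in the series metadata.  Any positive power profile exercises the
cumulative integrators identically, which is all the downstream quantities
depend on.  Temperature channels are constructed to close the energy balance
exactly in noiseless mode: a configurable fraction (default 0.7) of the net
power leaves through the jacket coolant, the rest heats the suspension
stream.  Sensor noise is multiplicative Gaussian, default 1% RSD per
channel; in-process size and PdI measurements use the validated analytical
precisions (0.9% and 7.4% RSD).  All randomness flows from explicit seeds;
a seed is mandatory whenever noise is enabled, and identical
(scenario, seed, config) reproduce identical bytes.

Fault injection covers the three residual risks the in-process control
exists for: a mis-weighed batch mass (recorded mass scales E_M and N by the
inverse factor exactly), a biased no-load measurement (lowers reported E_M),
and a mass-flow sensor dropout (lowers reported N).

What the generator does **not** emulate: torque/viscosity dynamics, pump
pulsation, thermal transients at segment boundaries, drifting no-load power,
or any breakage kinetics beyond the fitted size–energy law.  Passing tests
therefore demonstrate the internal consistency of the pipeline and its
statistical behavior under the stated noise model — not the fidelity of the
generator to any particular plant.

## Problem sizes and numerics

Campaign-scale simulations widen the time step per scenario so a run stays
below ~4000 processing samples (default 1 s for single runs); at these
resolutions the rectangle-rule discretization error is orders of magnitude
below the 1 kJ/kg reporting precision.  The exponent-recovery check of the
end-to-end pipeline uses the mean over six independently seeded 22-run
campaigns: a single campaign at the 0.9% analytical size precision has a
recovered-exponent sampling sd of ~1.4%, so averaging separates the
pipeline's (un)biasedness from the sampling noise of one draw.  Batch
summaries round to the batch-table reporting precision (integer kJ/kg, two
decimals for SE̅) but never round a positive quantity to zero.

## Known limitations

- The energy balance is steady-flow; start-up and segment-boundary
  transients violate it briefly on real data.
- The atmospheric-loss term follows the stated sign convention of the
  balance verbatim; with a surface hotter than the atmosphere it adds heat
  to the suspension side, so enabling a nonzero loss coefficient should be
  done with that convention in mind (default keeps it off).
- The power-law correlation is scale- and formulation-specific; the fitted
  constants carry no transferability claim.
- The design-space bevel rule is one defensible reading of "bounded by
  experimental coverage"; regulatory use should supply explicit vertices.
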