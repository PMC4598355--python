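# Methods note

This note records the modelling conventions, parameter provenance and
numerical choices in `finwalk`, in enough detail to re-derive every
packaged constant.

## 1. Kinematic conventions

- A trajectory is a uniformly sampled planar track `t, x, y, vx, vy`
  (s, cm, cm/s), origin at the tank centre. Sampling uniformity is
  enforced to a relative tolerance of 1e-9; the reference rate is 5 Hz
  (`Δt = 0.2 s`).
- Speed `u = ||v||`. Signed turning speed
  `ω_k = atan2(v_k × v_{k+1}, v_k · v_{k+1}) / Δt`, **anticlockwise (left)
  positive**. Two consequences:
  - `|ω| ≤ π/Δt = 5π ≈ 15.71 rad/s`, the maximum turn resolvable between
    consecutive samples;
  - exactly antiparallel velocity pairs have no intrinsic sign; the sign
    of the last non-zero turn is reused (+ at the start of a series).
  Zero-speed samples and the padded final sample are flagged in
  `omega_mask` and excluded from fitting.
- Heading is the velocity angle wrapped to `[-π, π)`; at zero-speed
  samples it is carried forward from the last moving sample.

## 2. Swim-bout segmentation

Raw tracks mix swimming with drifting/resting. The segmentation rule:

1. smooth the speed with a centred 3-sample moving average (shrunken at
   the edges);
2. mark samples with smoothed speed strictly above `u_min = 1 BL/s`
   (body length 3 cm → 3 cm/s) as swimming;
3. join bouts separated by gaps strictly shorter than `τ_s = 2 s`;
4. cut each bout into consecutive windows of `round(τ_l/Δt) = 300`
   samples (`τ_l = 60 s`), discarding the remainder.

Segments carry the *unsmoothed* data; smoothing only drives the
thresholding decision.

## 3. Arena geometry

The tank is a rounded square: side `L = 120 cm`, corner radius
`R_c = 10 cm` (a Minkowski sum of a square and a disc, hence convex — a
ray from any interior point crosses the boundary exactly once, which the
test-suite oracle exploits). For a walker at `(x, y)` with heading `φ`:

- `d_W` is the distance along the heading ray to the boundary (four flat
  wall segments plus four corner arcs; closed-form intersections);
- `t_W = d_W / u` is the projected time to collision;
- `φ_W = atan2(m × r, m · r)` where `m` is the outward boundary normal at
  the hit point and `r` the ray direction. Head-on approach gives
  `φ_W = 0`; `φ_W > 0` means a left turn steers away from the wall.
- Wall-corrected turning `ω_c` equals `|ω|` signed + if `sgn(ω) = sgn(φ_W)`
  (turning away) and − otherwise; head-on (`φ_W = 0`) counts as toward.

## 4. Calibration

### O-U maximum likelihood

Sampling an O-U process at a fixed step gives an exact AR(1) with
Gaussian transitions, so the conditional MLE has a closed form in the
pairwise sums of the series (no numerical optimizer). Degenerate inputs —
fewer than 10 samples, constant series, or an estimated AR coefficient
outside (0, 1) (non-mean-reverting) — raise errors rather than return
garbage. Recovery on exact synthetic series at `n = 2×10⁵`, `Δt = 0.2 s`
is well within 2% for `μ_u`, `θ_u`, `σ_u` and 5% for `θ_ω` (tested over
fixed and scanned seeds).

### Parameter averaging

Per-fish parameters are unweighted means over that fish's segments;
global parameters weight each fish by its segment count. With the
packaged per-fish table and counts `(4, 3, 4, 4, 4, 4, 1, 4)` this yields
the global set `μ_u = 14.02`, `θ_u = 0.59`, `σ_u = 4.21`, `μ_ω = −0.02`,
`θ_ω = 2.74`, `σ_ω = 2.85`.

Two quirks of the source calibration are preserved *as defaults* and
logged by `finwalk.params.warn_default_quirks()`:

1. **Speed-parameter ordering.** One printed form of the global speed
   triple swaps `θ_u` and `σ_u` (4.21 vs 0.59). The package uses
   `θ_u = 0.59 s⁻¹`: it is the ordering consistent with the per-fish
   table semantics and with the observed speed-autocorrelation half-life
   (~1.2 s; `θ_u = 4.21` would give ~0.16 s).
2. **Two values of `θ_ω`.** The global average is 2.74 s⁻¹ but the
   saturation level σ0 is derived with 2.81 s⁻¹ (a different averaging
   pass). Both are kept: 2.74 as the simulation default, 2.81 inside the
   σ0 derivation, reproducing σ0 ≈ 12 exactly.

### Turning-noise saturation

`σ0 = max(ω) √(2 θ_ω) / 2` places the largest observed turning speed at
the 2-sigma boundary of the stationary turning distribution of an O-U
process with amplitude σ0. With `max(ω) = 10 rad/s` and `θ_ω = 2.81 s⁻¹`:
σ0 = 11.853 → rounded to 12.

### Wall-response fit

Pairs `(d_W, ω_c)` (or `(t_W, ω_c)` in time mode) are pooled, LOESS-
smoothed (locally linear, via `statsmodels`), interpolated onto a
100-point grid and fitted with `A·exp(B·z)` by nonlinear least squares
(log-linear initial guess). **Deviation from the obvious default:** the
LOESS span is 0.2 rather than the common 0.5. Measured over 30 synthetic
seeds (A = 2.25, B = −0.11, noise sd 1.0, n = 2000), span 0.5
over-smooths the ~9 cm decay scale and biases A low (mean 1.98, worst
error 0.44 — outside the ±0.3 recovery band), while span 0.2 is nearly
unbiased (mean A 2.26, worst error 0.24; mean B −0.106, worst error
0.018). The span is configurable (`calibration.loess_span`).

The reference fitted constants are `A = 2.25 rad/s`, `B = −0.11 cm⁻¹`
(distance mode) and `A = 2.25`, `B = −1.68 s⁻¹` (time mode). The
*simulation* default amplitude is `3A = 6.75`: the fitted amplitude is a
mean response over all incidence angles, and the amplified value is what
keeps simulated walkers off the wall at realistic rates.

## 5. Simulation

Euler–Maruyama with `Δt = 0.2 s`, per step (in order):

1. project the wall collision from the current state; compute `f_W`;
2. update `U` (explicit Euler + noise), floor at 0 (speed is a norm);
3. update `Ω` with equilibrium `μ_ω + f_W` and noise amplitude `f_c`
   evaluated at the *pre-update* speed; clamp to ±15 rad/s (the detector
   bound; configurable, may be ∞);
4. advance heading by `Ω Δt` (wrapped), then position along the new
   heading;
5. if the new position leaves the arena, the collision is fully
   inelastic: position and heading revert, `U := 0`, `Ω` is kept.

One seeded generator drives the run (two standard-normal draws per step,
speed first), so runs are bit-reproducible. Initial state: `U = μ_u`,
`Ω = 0`, position/heading uniform in the arena (or fixed). The
trajectory's velocity channel is the backwards difference of position, so
round-tripping through the kinematics module recovers the latent speed
and heading exactly away from collision steps.

Discretization checks: at `Δt = 0.2` the explicit-Euler AR(1) stationary
variance is `σ²/(θ(2 − θΔt))` (about 5% above the continuous-time
`σ²/2θ` for the turning parameters), matched by simulation; at
`Δt = 10⁻³` the integrator is distributionally indistinguishable from the
exact sampler (two-sample KS test).

## 6. Validation statistics

- Lag-1 autocorrelation `r1` with the asymmetric normalization
  (covariance sum over n−1 pairs divided by the full sum of squares);
  correlation time `τ = −Δt/ln r1`, half-life `τ ln 2`.
- Full ACF via FFT (`statsmodels`), with the fitted exponential envelope
  `exp(−t/τ)`.
- Joint speed–turning density on a 2-D histogram in `log10(count + 1)`;
  the coupled model shows the characteristic funnel (conditional spread
  of `Ω` shrinking with `U`).
- Spatial occupancy maps (fraction of time per bin); out-of-grid points
  are clipped to edge bins with a warning.
- Thigmotaxis: the ratio `σ_ω/θ_ω` predicts wall-following. Packaged
  per-fish parameter sets with ratio < 1 (F6, F7, F10) sit measurably
  closer to the boundary in simulation than those with ratio > 1
  (F1, F2, F5), with no attraction term in the model.

## 7. Synthetic data

`gen_ou_exact` samples the discrete O-U chain from its exact Gaussian
transition (stationary initial draw by default) and serves as the ground
truth for both the MLE and the integrator. `gen_wall_response` produces
noisy exponential scatter for fit-recovery studies. Problem sizes used in
the tests and the acceptance script (2×10⁵ O-U samples, 2 000 wall
points, simulations of 10³–2×10⁴ s) are the package's own choices,
balancing statistical power against a ~10 s suite runtime on one CPU.

## 8. Known limitations

- The plain O-U likelihood ignores the speed–turn coupling and the wall
  term, so recalibrating from simulated (or real) arena data biases
  `θ_u`, `θ_ω` upward by tens of percent (demonstrated in the README
  worked example). Matching the generating values requires free-space,
  uncoupled data.
- The inelastic boundary is a modelling shortcut; real fish glance off
  walls. Collision steps are flagged so analyses can exclude them.
- `f_W` depends only on the first projected collision; concave
  obstacles or multiple walls in close range are out of scope (the
  rounded square is convex).
- The turning-speed estimator aliases turns beyond `π` per sample;
  the simulation clamp at 15 rad/s keeps the model inside the detector's
  measurable range by construction.
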