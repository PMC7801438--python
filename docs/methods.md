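# Methods

## Models

### Deformed Arrhenius law

Rate constants k(T) or self-diffusion coefficients D(T) are modelled on
the log scale as a polynomial in x = 1/(RT), R = 8.314 J K⁻¹ mol⁻¹:

    ln v(T) = ln_pre + B·x + C·x²

All energies are J/mol internally; kJ/mol appears only at the reporting
boundary (a single ÷1000).  The temperature-dependent activation energy
is the negative logarithmic derivative, Eₐ(T) = −B − 2C/(RT); it is
strictly decreasing in T iff C < 0.  Fits are *unweighted* ordinary
least squares on ln v (a `weights` hook exists on the internal solver
but is off by default); the design matrix is column-normalized before
solving because the raw columns {1, x, x²} span nine orders of
magnitude.  R² is computed on the ln scale.  With exactly three points
the quadratic interpolates (R² = 1, zero covariance).  Parameter
covariance is s²(XᵀX)⁻¹ with s² = RSS/(n−p).

Sign convention: **C < 0 ⇒ super-Arrhenius** (Eₐ decreasing with T,
the convention consistent with published channel-water fits where every
super-Arrhenius row has C < 0).  The classifier's default tolerance is
the fitted standard error of C; judging a *series* to be linear uses
3·se(C) (99.7% nominal), since |C| < 1·se(C) holds only ~68% of the
time even for exactly Arrhenius data.

Model comparison (`compare_models`) prefers the quadratic only when its
adjusted R² exceeds the linear fit's; exact ties (both models exact)
resolve to the simpler law.

### Mean-squared displacement and diffusion

The ensemble MSD at lag ℓ averages |x(t₀+ℓ) − x(t₀)|² over all
particles in the selection and, by default, all valid time origins t₀
(the standard variance-reduction choice in single-particle tracking; a
`single_origin` mode reproduces the literal t₀ = 0 definition).  The
multiple-origin average uses the exact FFT decomposition
MSD(m) = S1(m) − 2·S2(m) (autocorrelation by FFT, prefix sums for S1),
O(F log F) per particle-dimension; it agrees with the naive O(F²)
double loop to ~1e−13 Å².  |MSD| values below 1e−9 Å² are snapped to
exact zero — three orders of magnitude below the 1e−3 Å precision of
the on-disk formats — so round-off from the FFT path never masquerades
as signal.

Channel-resident (masked) MSD restricts origin/endpoint pairs to the
same contiguous residence interval; intervals shorter than 3 frames are
discarded (shorter spans cannot contribute a windowed fit point and are
dominated by entry/exit transients).  This path uses the direct loop.

The directed-motion fit is least squares of MSD(t) = f·D·t + (V·t)² over
a lag window, with f = 4 (`paper_4Dt`, the single-particle-tracking
convention, kept as the default for fidelity with common practice) or
f = 2·n_dim (`dim_2nDt`; 6Dt in 3-D, used by all physically grounded
recovery studies here — the two differ only by a constant factor 2/3 in
D in 3-D, and every report names its mode).  Defaults: window =
[10%, 50%] of the maximum lag (excluding the short-time ballistic
regime; the upper half of the lags is noisy because few origins remain),
max lag = half the trajectory duration.  A negative quadratic
coefficient refits with V = 0 (a drift speed cannot be imaginary); a
negative slope clamps D to 0 with a `clamped` flag instead of erroring.
Unit conversion is exact: 1 Å²/ps = 1e−8 m²/s.

`fit_msd`'s standard error is the naive OLS value and is documented as
such: MSD values at neighbouring lags are strongly correlated, so OLS
understates the uncertainty.  `estimate_diffusion` therefore computes
the honest replicate-level error by splitting particles into 10 blocks
(independent for non-interacting tracers), fitting D per block, and
taking sd/√10.  The 3σ coverage of this estimator is verified at
98–100/100 replicates in the calibration study.

Periodic-boundary unwrapping applies the minimum-image convention to
every consecutive-frame displacement (each component mapped into
(−L/2, +L/2]); it is the definition of the reconstruction, not a
heuristic, so super-L/2 physical jumps are folded silently — callers
must sample densely enough, as with any MD post-processing.

### Channel hydration

A channel is an ordered centerline polyline with optional per-point
radii and lining residues.  "Within the channel" means minimum
*point-to-segment* distance to the polyline ≤ cutoff (default 3 Å),
boundary inclusive — i.e. waters are counted along the whole channel,
not around a single center point.  The bottleneck is the minimum local
radius (first index on ties); reported "width" is the diameter 2r.
Hydropathy is Kyte–Doolittle divided by 4.5, mapping the scale onto
[−1, 1] (ILE = +1, ARG = −1); lining residues carry no coordinates in
this representation, so they are assigned to centerline segments in
order, split as evenly as possible.  Water-count statistics use the
sample SD (n−1) over strided frames; the default stride targets frames
~100 ps apart and keeps the last ~10 such frames (the equilibrated tail
of a run).

## Synthetic generators

The generators emulate the *study conditions* of channel-water MD at
desk scale; they make no attempt to reproduce explicit-water physics
(no hydrogen bonding, no protein flexibility, no TIP4P-class force
field), so passing tests demonstrate estimator correctness and
mechanism signs, not absolute MD numbers.

* **Bulk Brownian** (`simulate_bulk_brownian`): independent Gaussian
  steps per axis, variance 2·D(T)·dt, wrapped into a periodic cubic
  box.  D may be a constant (default 0.2 Å²/ps = 2e−9 m²/s) or an
  Arrhenius/deformed law evaluated at the run temperature.  Defaults
  500 particles × 2000 frames at dt = 1 ps.
* **Channel hopping** (`simulate_channel_hopping`): axial site hopping
  with spacing a = 3 Å (one water diameter) and per-step *total* hop
  probability p = k₀·exp(−Eb/RT)·dt split evenly between ±a, so the
  axial diffusion coefficient is exactly a²·k_hop/2 (the 1-D
  random-walk value used as the oracle).  p > 0.5 raises a
  timestep-too-large error.  Defaults Eb = 25 kJ/mol and k₀ = 500 ps⁻¹
  (an *effective* prefactor chosen so D(300 K) ≈ 1e−9 m²/s, the
  channel-water scale; it subsumes the attempt frequency and entropic
  factors and is not a molecular vibration rate).  Radial coordinates
  are a stationary AR(1) with correlation time 5 ps and sd 0.3 Å —
  tight single-file confinement.  The radial plateau adds a constant
  ~4σ² to the 3-D MSD; at σ = 0.3 Å this bias is bounded well below
  the fit tolerances (at larger σ it shows up as spurious positive
  curvature in the no-intercept fit, which is why the default is
  small).
* **Occupancy release**: with `occupancy_decay` > 0, a fraction
  f(T) = clip(occupancy_decay·((T−260 K)/80 K)², 0, 1) of tracers is
  released (per particle, at t = 0) to free 3-D Brownian motion at
  D_free = 0.5 Å²/ps.  This implements population thinning — the
  constrained water population shrinks with T faster than its own
  mobility grows.  The quadratic ramp is a package modeling choice (no
  quantitative law exists for it); what matters, and what the studies
  assert, is the resulting sign: the trapped/free mixture makes ln D
  vs 1/RT concave with fitted C ≈ −1e8 J²/mol² and Eₐ(290) > Eₐ(310),
  the published ordering.  A ramp that grows too fast at the cold end
  would instead let the free term dominate everywhere and flatten the
  cold side (sub-Arrhenius curvature); the quadratic shape keeps the
  cold end barrier-dominated.
* **Rate series / channel fixtures**: exp(ln_pre + Bx + Cx² + ε) with
  ε ~ N(0, σ²) on the log scale; centerline fixtures are
  equal-step random polylines of *exact* requested arc length, with
  waters placed at controlled perpendicular offsets whose true
  centerline distances are recomputed by an independent plain-Python
  exhaustive check, offsets within 2% of the cutoff redrawn so in/out
  labels are unambiguous.

All generators draw from one `numpy` Generator seeded per call; no
global state, bit-identical repeats.

## Study conditions and problem sizes

Replicate studies (`hydrokin.studies`) use: 100 seeded replicates for
rate refits (8 temperatures 270–340 K, 2% lognormal noise,
transient-channel truth), 100 Brownian replicates at 500 × 2000, one
200 × 1500 hopping sweep for barrier recovery, and 100 sweeps at
120 × 1000 for the release-mechanism classification — sizes at which
each effect is resolved with wide margin while the full chain runs in
minutes on one CPU.

## Known limitations

* Absolute MD-derived quantities — bulk and channel D ranges of real
  TIP4P-class water, per-channel water counts (11±4 / 17±3 / 15±9),
  the true geometry and hydropathy of the PFK-1 channels — require the
  original trajectories and channel-detection runs; this package
  covers them qualitatively (orderings, signs, invariants) and treats
  published fit parameters as *inputs* for worked examples.
* Channel detection itself (Voronoi/shortest-path tools) is out of
  scope; `ChannelPath` is an input contract.
* The 4Dt default is a 2-D convention often applied to 3-D tracking
  data; D values from the two modes differ by 2/3 and are never mixed
  within a report.
* The respiration-rate fit row of the published comparison is excluded
  from exact checks: its stated kJ-based units do not reproduce the
  printed Eₐ values under either unit reading to better than
  ~1 kJ/mol.
* No velocity-autocorrelation (Green–Kubo) route, no anomalous-exponent
  fitting, no trajectory superposition/alignment.
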