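# Methods

This note documents the models, parameter choices, numerical details
and known limitations of `gatedose`. Coordinates are patient-fixed:
x = LR (+left), y = CC (+cranial), z = AP (+anterior). Exhale
corresponds to the maximal CC coordinate (the liver rides cranially at
exhale) and to the maximum of the external surrogate signal; modules
that depend on this sign expose a flip flag.

## Breathing and ground-truth coupling

The external surrogate is generated cycle by cycle as

    ext(t) = baseline − a_i · sin^(2n)(π t_loc / T_i) + drift(t) + noise

with per-cycle period `T_i ~ N(period_s, period_sd)` and amplitude
factor `a_i ~ N(1, amp_sd_frac)`; the waveform equals the baseline at
cycle boundaries, so amplitude jitter never introduces discontinuities.
The exponent 2n (default n = 2) concentrates time near exhale: for
n = 2 the signal spends ≈31% of each cycle within the top 5% of its
range, emulating the extended exhale dwell of real breathing.

Defaults describe free-breathing liver motion: 4 s ± 0.3 s period,
peak-to-trough amplitudes (3, 20, 10) mm in (LR, CC, AP), 10% amplitude
jitter, and a slow baseline drift of (0, +0.10, −0.05) mm/min so a
~15 min fraction accrues the ~1 mm cranial / −0.7 mm posterior exhale
drift typical of a session. The surrogate amplitude is taken from the
CC component (the dominant respiratory axis); which axis drives the
surrogate is configurable.

Internal tumor motion is *derived* from the surrogate through a known
instance of the correlation model (below), never generated separately —
this makes the model fit exactly recoverable and gives every synthetic
experiment a closed-form truth. For times earlier than the delay τ the
lagged signal clamps to the first sample; the rule affects less than
one breathing cycle at the start of a recording. Fiducial markers are
rigid translates of the tumor centroid; the returned centroid is the
input motion translated by the mean marker offset (identical to the
input when the offsets sum to zero).

## Cone-beam projection model

The gantry rotates about the CC axis at constant speed; at angle 0 the
source is anterior at SAD = 2700 mm and the centered flat panel sits at
SID = 3700 mm with `u` horizontal in the gantry frame and `v` parallel
to CC. A point at depth w from the source projects to
`(u, v) = (ξ, η) · SID / w` — magnification SID/SAD = 1.370 in the
isocenter plane. Marker segmentation is modelled as truth + Gaussian
pixel noise (0.388 mm/px) + Bernoulli dropout; image rendering is out
of scope. Scan duration (60 s), arc (360°) and projection count
(default 1000; 300 in the simulation scenarios for speed) are
configurable.

## Probability-based 3D trajectory estimation

One projection constrains a marker to the source–detection ray. The
position over the scan is modelled as a single 3D Gaussian N(μ, Σ).
For each ray with orthonormal transverse basis E (3×2), the marginal
likelihood of the observation is the 2D Gaussian
N(Eᵀμ, EᵀΣE) evaluated at Eᵀo (o = any ray point); μ and Σ are fitted
by maximizing the product over projections. Numerics: Σ is
parameterized by its Cholesky factor with log-scaled diagonal (clipped
at e^±20, which lets the covariance collapse gracefully for static
markers); L-BFGS-B from a least-squares ray-intersection start plus
optional perturbed restarts (3 by default; the objective history is
retained and is non-increasing over accepted iterates). Only Gaussian
densities are supported — conditioning is then closed-form.

Each projection's 3D estimate is the mean of the fitted Gaussian
restricted to its exact backprojected ray: for p(s) = o + s·d the
restricted density is Gaussian in s with mean
s* = dᵀΣ⁻¹(μ−o)/(dᵀΣ⁻¹d). The estimate therefore lies on the ray and
reprojects onto the observed panel position to machine precision; if Σ
is singular along the ray the nearest ray point to μ is used and
flagged. Undetected projections stay as gaps. The marker-group
centroid serves as the tumor surrogate; with detection dropout the
pipeline uses only timestamps where *all* markers are detected, because
a partial mean is biased by half the missing marker's offset.

Measured accuracy under the default conditions (300 projections, 0.5 px
detection noise): median CC RMS trajectory error ≈ 0.15 mm across 20
seeded scans, far below the 1.5 mm contract.

## External–internal correlation model

INT_d(t) = A_d·EXT(t) + B_d·EXT(t−τ) + C_d per direction, the delayed
term absorbing hysteresis. A, B, C are ordinary least squares per
direction after interpolating the surrogate onto the internal
timestamps; τ is shared across directions and selected on a grid
(default 0–1.0 s in 0.04 s steps, the gating-log resolution): a grid
search plus OLS is exactly reproducible, unlike a continuous joint
optimization of a non-convex delay.
Ties go to the smallest τ — relevant when B = 0, where all delays fit
equally well. A constant surrogate is rejected by name as a degenerate
regressor; at τ = 0 the two regressors coincide and the minimum-norm
least-squares solution is used (predictions are unaffected). The model
of the day is built from the post-treatment scan pairing and applied
retrospectively to the whole fraction; building it from the setup scan
is not supported by default because couch corrections between setup and
delivery would invalidate the pairing.

Because the synthetic coupling is exactly linear, fit residuals on
noiseless data recover A, B, C to 1e-6 and τ exactly, and residuals on
estimated trajectories stay well below the millimeter scale —
real-patient residuals (breathing irregularity, coupling drift) are
larger, and passing these tests shows correctness of the estimator, not
clinical accuracy.

## Gating and delivery

The gating window upper bound sits at the exhale-side extreme of the
surrogate (100th percentile by default, configurable); the lower bound
is bisected so the fraction of samples inside the window matches the
duty-cycle target (±2%). Gate-on intervals [a, b] become gate-open
[a + 240 ms, b + 80 ms], snapped to the 40 ms grid and dropped if
empty; a window crossing shorter than 160 ms therefore yields no beam
permission.

Delivery walks the spot list in order: spot duration = MU / rate
(default 300 MU/s, chosen so even the heaviest optimizer-assigned spot
fits inside a typical gate-open interval), 1.0 s energy switches,
0.02 s/mm pauses for lateral moves beyond 5 mm, and gate-off waits
whenever the remaining open time cannot hold the next spot. Pause
durations carry 10 ms Gaussian jitter — real switches are not exactly
reproducible — which also keeps the UDP rounding errors of repeated
identical pauses from accumulating into a systematic clock drift. Spot
timestamps for dose purposes are interval midpoints (spots are short
against the 40 ms log resolution).

The emitted machine log reproduces the real logs' information content:
exact spot durations, beam-off gaps only as UDP message counts
(nominal 2 ms per message) whose true message interval differs by an
unknown factor (drawn within ±3%), and an unknown clock offset.
Synchronization reconstructs beam-on intervals as
`offset + Σ durations + scale · Σ (udp_count · udp_dt)` and maximizes
their overlap with the gate-open intervals, minus a penalty for unused
gate-open time before the first spot of each active gate. The penalty
removes the plateau of the pure-overlap objective: at the true
alignment the beam resumes exactly at gate-open starts, so the penalty
vanishes there and the optimum is a sharp corner. Because offset and
scale trade off along δoffset ≈ −δscale × (mid-treatment cumulative
gap), refinement runs on a 2D grid in ridge-aligned coordinates after a
coarse (0.2 s, 0.002) global grid. Recovery over 50 seeded trials:
median |offset error| ≈ 2 ms (max 11 ms), median |scale error| ≈
4×10⁻⁵ — within the 40 ms / 0.5% contract in all trials. A timeline
without gate-off pauses is rejected: without gating's unique pause
pattern the alignment is unidentifiable.

The gating log is aligned with the CBCT clock by normalized
cross-correlation of the surrogate with the AP component of a tungsten
sphere riding on the marker block, with parabolic sub-sample peak
refinement. Quasi-periodic breathing makes distant lags near-ambiguous,
so the search can be restricted around the coarsely known clock
relation (±30 s in the pipeline).

## Dose engine, planning, and motion encoding

The engine computes dose on a uniform water box as
MU · D(z; E) · G(r; σ):

* Range–energy: Bragg–Kleeman R = 0.0022·E^1.77 cm, inverted in closed
  form; machine limits 71–153 MeV.
* Depth dose D(z; E): Gaussian peak at R plus a sigmoid entrance
  plateau (~30% of peak), normalized numerically to unit peak. The
  peak width σ_R = 1.0 + 0.035·R mm is wider than physical range
  straggling so that energy layers at the default 5 mm spacing stack
  into a smooth spread-out peak on a 2.5 mm grid; all dosimetric
  statements are relative (planned vs reconstructed with the same
  engine), so the widening does not bias any reported comparison.
* Lateral σ: in-air σ linear from 6 mm at 71 MeV to 4 mm at 153 MeV,
  with a small in-depth broadening (0.01·z) in quadrature; the profile
  is a normalized 2D Gaussian truncated at 4.5 σ.

The default phantom is a 120 mm water cube (2.5 mm voxels) with a
12 mm-radius spherical CTV inside an ellipsoidal liver. Toy SFUD-like
plans place energy layers across the CTV depth extent and spots on a
rectangular BEV grid covering each layer's CTV cross-section plus a
6 mm margin, for three equally spaced gantry angles. Per-field spot
MUs solve a non-negative least-squares problem targeting a uniform
per-field share of the fraction dose on the CTV; optimizer-disabled
spots are pruned. The resulting static plan is homogeneous (CTV
HI ≈ 3%, coefficient of variation < 1%) with per-field spot counts and
total MU within the clinically reported ranges.

Motion encoding decomposes each spot's tumor displacement (patient
frame, at the spot's delivery mid-time) per field into BEV-lateral and
in-depth components. Spots shift by the *negative* lateral component;
the energy is changed so the new range equals the old range plus the
in-depth component (a tumor moving away from the source needs a longer
range — verified against the distal-falloff shift of the engine rather
than assumed). Zero components pass through bit-exactly, making the
zero-motion reconstruction identical to the planned dose. Energies are
clipped to machine limits with a counter, never silently.

DVH metrics use the top-x% convention with linear interpolation
between order statistics: Dx is the dose received by at least x% of
the structure (D98 = 2nd percentile of voxel doses), and
HI% = (D2 − D98)/D50 × 100.

## Simulation scenario (pipeline defaults)

One fraction runs: setup CBCT (60 s, starting at 5 s) → online
registration with a configurable human-error perturbation
((0.4, 0.8, −0.4) mm by default, matching the sub-millimeter scale of
manual matches) and couch correction → gated delivery of the toy plan
→ post-treatment CBCT → retrospective analysis. The CBCT clock runs
7.5 s behind the gating log and the machine clock 13.37 s ahead; both
offsets are recovered, not assumed. Problem sizes (300 projections per
scan, ~260 spots, ~15–20 min of surrogate signal) keep a full fraction
simulation + analysis at a few seconds while preserving every
structural feature of the chain.

## What the synthetic tests do and do not show

The generator provides exactly linear external–internal coupling,
stationary quasi-periodic breathing, rigid marker geometry, Gaussian
detection noise and a uniform water patient. Passing tests therefore
demonstrates that each estimator recovers the truth its model assumes
and that the chain's bookkeeping (clocks, frames, signs) is correct.
They do not demonstrate robustness to coupling drift, irregular or
pathological breathing, marker migration, deformable anatomy,
heterogeneous stopping power, or segmentation artifacts — the synthetic
error levels (e.g. sub-0.1 mm correlation-model residuals) are
correspondingly optimistic relative to clinical recordings.

## Known limitations

* Gaussian-only position density in the trajectory estimator.
* Rigid-translation tumor surrogate; no rotation or deformation.
* Analytic water-box dose engine; no heterogeneity, RBE variation, or
  robust-optimization planning. Absolute doses are not clinical.
* Synchronization requires gated delivery and reasonable coarse clock
  knowledge for the CBCT alignment.
* The delivery timing constants are plausible defaults, not vendor
  measurements; contracts that depend on them are tested as
  inequalities or round-trips, never as absolute times.
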