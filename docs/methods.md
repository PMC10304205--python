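# Methods

This note records the models implemented by the package, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open. Units are SI throughout the library (tesla,
metres, amperes); nT/mm/mA appear only at I/O boundaries.

## Coordinate frame and geometry

Right-handed frame with the origin at the midpoint between the two coil
planes and z along the inter-plane axis. The two participants face each
other across the x axis (head centres at ±separation/2; 0.65 m for the
touch task, 0.80 m for the ball game), with +y "up" in each helmet
frame. Source analysis is done in the helmet frame, whose origin is the
head-sphere centre; this is exact because head and helmet move as one
rigid body, so the dipole–sensor geometry is motion-invariant.

## Matrix coil and driver electronics

Each plane carries a 4×4 grid of 38 cm square ten-turn coils tiled
edge-to-edge (pitch = side length) plus a 3×3 grid offset by half a
pitch with its central coil omitted — 24 coils per plane, 48 in total,
planes 150 cm apart. The pitch is a design choice: no inter-coil gap is
modelled, and the overlapping half-pitch offset is the standard
overlapping-loop layout. Wires are infinitely thin filaments with the
ten turns co-located; the winding cross-section is unspecified in
practice and its effect is second order at helmet distances. Coil
resistance/inductance are metadata only — the controller operates at DC
and no electrical transients are modelled.

Segment fields use the exact finite-wire Biot–Savart closed form
B = (μ0 I/4π)(a×b)(|a|+|b|)/(|a||b|(|a||b|+a·b)), validated against a
10⁵-point line quadrature and the textbook square-loop centre field
(2√2 μ0 I/πa, to 10 significant figures).

Driver defaults: ±10 V full scale, 16-bit DAC (lsb voltage
20 V/2¹⁶ = 0.305 mV), 1.2 kΩ series resistance — hence ±8.33 mA maximum
current and a 0.254 µA lsb current, always derived from voltage and
resistance rather than stored. Per-coil current noise is 10 nA/√Hz.
Field-noise propagation combines the 48 per-coil projections in
quadrature (independent sources); because an OPM measures a single
field component, `coil_noise_at_point` reports the noise density in a
measured component (worst case over components, or along a supplied
axis). At the plane midpoint this is 17.4 fT/√Hz (x/y components:
11.2), below the 15 fT/√Hz-class sensor floor's order of magnitude and
under the 20 fT/√Hz design bound; the full 3-vector magnitude (23.6)
is not the measured quantity.

## OPM sensing model

Sensors are radial single-axis magnetometers in measurement mode
(±5 nT range, 0.33× gain) and dual-axis DC sensors in field-zeroing
mode (±50 nT). The second (tangential) axis is the projection of the
helmet x axis orthogonal to the radial axis — a deterministic
convention, since only "two orthogonal directions" is physically
constrained. Readings clip silently at ±range with a per-sample
saturation mask. Sensor noise is white at 15 fT/√Hz, independent per
channel. Gain errors and cross-axis projection errors are *not*
modelled — a known limitation; real OPMs moved far from their zero
point show both.

Helmets are synthetic: 16 sensors on a spherical-Fibonacci spiral over
the upper 75° cap at 10.5 cm from the head centre, 10 of them (spread
through the ordering) flagged as nulling inputs, giving N = 40 dual-axis
nulling measurements across the two helmets. Pose interpolation between
120 Hz tracking samples is piecewise-linear in translation and slerp in
rotation; motion bandwidth (≤ a few Hz) is far below the 1200 Hz data
rate.

## Field nulling

Calibration pulses each coil in turn (default 5 V/1.2 kΩ = 4.17 mA,
100 ms) and estimates each column of A as (pulse-plateau mean −
equal-length pre-pulse baseline mean)/current; the estimator is a
choice, as is the convergence criterion below. The regularised solution
x = −Aᵀ(AAᵀ+αI)⁻¹b is the unique dimensionally consistent reading of
the controller equations for N ≠ M and equals the minimiser of
‖Ax+b‖² + α‖x‖² (verified against a numerical optimiser);
α = 0.01·σ_max(AAᵀ) per calibration. The feed-forward loop (G = 0.1,
dt = 0.1 s) quantises and clips currents each step, stops when the mean
|b| changes by <10⁻³ relatively for 5 consecutive steps (max 600
steps), and raises an instability error if the residual grows for 10
consecutive steps or exceeds 3× its starting level — the gain-too-large
failure mode; clipping can bound the divergence into a sustained
oscillation, which the 3× check catches. With exact calibration and a
static field the residual is non-increasing up to the DAC quantization
floor (~0.1 pT per step in practice).

On the default synthetic remnant the controller reduces the mean
nulling-sensor |field| by factors of ~50–75 for both layouts, with the
wider ball-game layout consistently worse than the touch layout —
heads sit closer to the plane edges where fewer coils couple
effectively. These synthetic factors exceed the measured factors
reported for the real system (≈7–9.5 and ≈2.4–2.9), as they should:
the simulation has a perfectly affine remnant field, exact calibration
and no sensor calibration error, so its residual is limited only by
regularisation and quantization.

## Remnant field and drift

Uniform 2 nT vector (fixed direction) plus a symmetric traceless
gradient tensor of ~2 nT/m Frobenius norm (consistency with a
source-free static field), plus a spatially uniform seeded random-walk
drift scaled to 200 pT RMS over 10 min. The drift is deliberately slow
and spatially uniform; eddy-current or wall-interaction dynamics are
out of scope.

## Synthetic sessions

Per channel: projected dipole field + movement artefact + drift +
white noise, clipped at the measurement range.

*Carriers.* Beta sources are amplitude-modulated band-limited Gaussian
noise (13–30 Hz), not sinusoids, because the Hilbert-envelope analyses
assume broadband-in-band signals. Baseline source strength is 20–30
nA·m territory (default 30 nA·m), a typical sensorimotor magnitude
that yields clearly visible task modulation at the 15 fT/√Hz sensor
floor. The Hilbert envelope of a Gaussian carrier fluctuates with
σ/μ ≈ 0.52 (Rayleigh) regardless of bandwidth; trial averaging is the
only mechanism that suppresses it, which sets how deep the latent
modulation must be to be resolvable (next paragraphs).

*Touch task.* 60 (or fewer) 5 s trials, alternating active participant.
ERD is a raised-cosine-edged multiplicative suppression of depth 0.55:
active participant over 0.3–2.7 s post-cue, passive participant 0.3 s
later in onset and 0.5 s earlier in offset — the active-earlier/longer
asymmetry with exact timings chosen here, since only the asymmetry is
qualitatively constrained.

*Ball game.* 25 trials of 5 s rally + 7 s rest, trials 8 and 17 dropped
(analysis-side exclusion). Each participant's envelope carries a
common suppression (depth 0.55) spanning ~0.1–6.8 s — sustained
slightly past the rally so that its recovery ramp falls outside the
3–6.5 s correlation window, where a shared ramp would add a spurious
common component — plus rebound bumps (raised cosine, 0.7 s wide,
amplitude 0.6 at peak) 0.25 s after each of that player's strikes.
Participant 1 strikes roughly every 1.5 s with a deterministic ±12–18%
pace jitter; participant 2's strikes lag participant 1's by exactly the
configured inter-brain lag (default 0.6 s). Two structural choices are
load-bearing for lag identifiability: (i) a perfectly periodic rally
makes the unbiased estimator's alignment at lag ± (lag+period) exactly
as strong as the true-lag alignment — the pace jitter breaks this
degeneracy; (ii) rebound amplitude follows a build-and-fade intensity
profile (raised cosine centred 4.2 s, width 5 s), concentrating
envelope energy mid-window so that large-lag alignments pair strong
bumps with weak ones. Without these, the 1/(T−|k|) scaling — whose
variance diverges as the overlap shrinks — lets near-full-lag noise
dominate the extremum.

*Motion and artefacts.* Band-limited 6-DoF trajectories rescaled so
the maximum excursion equals the stated bound exactly (touch: 20 mm /
5°, smooth; ball: 60 mm / 17°, faster). The movement artefact is each
sensor's trajectory through the post-nulling residual field, evaluated
at the 120 Hz tracking rate and linearly interpolated to 1200 Hz; it is
quasi-DC and largely removed by beta-band filtering, as in practice.
Cross-helmet neural pickup (~10⁻⁴ of own-helmet signal at these
separations) is neglected.

*What passing tests do and do not show.* The generator's remnant is
perfectly affine, its sources are single dipoles in an ideal sphere,
and sensors are perfectly calibrated. Passing recovery tests therefore
demonstrates the correctness and internal consistency of the analysis
chain — not that real two-person data would yield these effect sizes;
real nulling factors, localization errors and envelope SNR will all be
worse.

## Beamformer

Weights use the whole-recording band-limited covariance, regularised
by μ = 0.01·σ_max(C); active/control covariances come from the stated
window lists. Filtering is zero-phase forward–backward 4th-order
Butterworth (the effective noise bandwidth of the squared response is
~0.9× nominal — relevant when predicting noise power). The source
lattice is every 4 mm grid point inside the 9 cm head sphere,
excluding a 1 cm core where all orientations are radial and hence
silent. Per voxel the tangential orientation extremising the pseudo-T
is found in closed form: with the unit-gain weight substituted, Ŧ(u)
is a generalized Rayleigh quotient of two 2×2 matrices on the
tangential lead-field pair, solved by a vectorised symmetric
eigendecomposition — equivalent to, and exactly as optimal as, a 1-D
angle search. A fixed-orientation mode is also provided. Virtual
electrodes use broadband (1–150 Hz) covariance weights.

Degenerate inputs: zero lead fields raise (silent source), zero
control-window power raises, overlapping active/control windows
raise, covariance windows shorter than three filter time-constants
warn.

## Envelope correlation

"Normalised, unbiased" is implemented as r(k) = [1/(T−|k|)]·Σ ẽ1 ẽ2 /
(s1 s2) with whole-segment mean removal and standard deviations, so
lag-0 autocorrelations are exactly 1 while extreme-lag values may
exceed [−1, 1]. Positive lag means the second envelope is delayed;
at the full ±3.5 s lag range the shift is clamped to T−1 samples since
no samples overlap at exactly the segment duration. The
trial-averaged-envelope mode is the default (a per-trial mode is
available); the 13-band overlapping BandSet treats the one
inconsistent entry in its half-overlap progression as 25–35 Hz, with
arbitrary band lists available via configuration.

## Problem sizes and tolerances

Demo and test problem sizes are the package's own defaults: 20-trial
touch sessions and full 25-trial ball sessions at 1200 Hz, 16 sensors
per helmet, 4 mm lattices (~45 000 voxels), 50-seed localization
batches at 16 s per session. Oracle agreement thresholds: 10⁻⁶
relative for Biot–Savart vs quadrature and for the current solver vs
optimiser; ~1% for the Sarvas field vs a 5120-element boundary-element
solve (the BEM uses vertex collocation with the auto-solid-angle
diagonal and deflation of the constant nullspace); machine precision
for the correlation estimator vs explicit loops.
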