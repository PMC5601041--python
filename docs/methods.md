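# Methods

This note documents the models, numerical choices and known limitations of
`restcm`. It is written for a reader who wants to know exactly what is
computed and what passing the test suite does and does not establish.

## Head model and forward solution

The volume conductor is three concentric spherical shells — brain, skull,
scalp — with normalized radii (0.87, 0.92, 1.0) and conductivity ratios
(1.0, 0.0125, 1.0); the sphere center is the coordinate origin, x toward the
right ear, y toward the nasion, z toward the vertex. The potential of a
current dipole at eccentricity `b < 0.87` observed on the scalp is the
classic Legendre / associated-Legendre series: for each degree `n` the
infinite-medium coefficient is multiplied by a shell-transfer factor `f_n`
obtained by solving the five boundary conditions (potential and radial
current continuity at both interfaces; zero radial current at the scalp) as
a per-degree 5×5 linear system. For equal conductivities `f_n` reduces
analytically to the bounded-homogeneous-sphere factor `(2n+1)/n`, and the
whole series then matches the closed-form homogeneous-sphere dipole
potential — the independent oracle used in the tests (agreement ≤ 1e-6
relative over random source/electrode pairs).

**Truncation.** The resistive skull damps high degrees, but at the grid's
maximum eccentricity (0.86, only 0.01 under the brain radius) convergence is
slow: the tail beyond degree 60 is still ~4e-4 relative. The series is
therefore truncated at degree 160 by default, where doubling the degree
changes the most eccentric dipole's gain by < 1e-8 relative to the map peak.
The vectorized lead-field path evaluates all degrees for all
electrode–dipole pairs at once, so the high degree costs well under a second
for 61 × 5982 gains. The scalar entry point additionally stops early once a
term's relative contribution falls below 1e-10 and raises if the tail bound
at the maximum degree exceeds 1e-6.

## Source grid

Dipole locations are the origin-anchored cubic lattice `(i·d, j·d, k·d)` with
spacing `d = 0.0905`, kept when `x² + y² + z² ≤ 0.86²` and `z ≥ 0` (both
inclusive); enumeration is lexicographic in (k, i, j). This yields exactly
1994 upper-hemisphere points (3695 on the full ball, 293 on the z = 0
plane). Origin anchoring and inclusive bounds are what make the count land
on 1994; both were verified by independent brute-force enumeration.

## Electrode fixture

The packaged cap is an idealized extended 10/20 construction on the unit
sphere: midline electrodes at 18° steps along the nasion–inion arc, the
outer 10% ring at polar angle 72°, interior electrodes by great-circle
interpolation between the midline and ring electrode of each coronal row,
and an inferior row (FT9/FT10, TP9/TP10, PO9/PO10) on the equator — as real
63-channel extended 10/20 caps have. 61 scalp channels plus VEOG/HEOG
placeholders (non-scalp, nominal periocular positions) make the 63-channel
fixture; dropping EOG and the mastoids leaves the 59-electrode CM montage.
The montage is exactly left–right symmetric by construction. It is a
geometric idealization, not digitized ground truth; consequences are noted
under *Limitations*.

## Referencing and REST

AR subtracts the mean of the scalp channels (EOG excluded), LM the mean of
TP9/TP10, CZ (or any named electrode, e.g. a recorded FCz that is not a data
channel — its lead-field row is computed at the ideal position) that
channel's potential. The REST operator is `U = G G_ref⁺` with the
pseudoinverse computed by SVD, truncating singular values below 1e-4 of the
largest (exposed as `sv_cutoff`); referencing removes one dimension, so the
retained rank is 60 of 61. Every transform validates and updates the
recording's reference tag, so applying an operator to data under the wrong
reference fails loudly rather than silently compounding.

Two properties worth knowing: (i) the REST output is numerically identical
whichever common reference the operator is built for (the row space of
`G_ref` does not depend on the reference), so the CZ-path and AR-path
operators agree to machine precision on forward-model data; (ii) REST's
accuracy is coverage-limited — with this montage the minimum-norm step
rebuilds infinity-referenced potentials of random grid dipoles with ~4%
median relative error, and the inferior electrode row is what brings it
under 5%.

## Center of mass, velocity, and the CM error

The positive CM uses strictly positive voltages (`m_i(t) > 0`; zeros
excluded); a sample with no positive channel is *undefined*, a flagged and
legal outcome rather than an error. The CM is a convex combination of
electrode positions, so its norm never exceeds 1. Velocity scales the
normalized coordinates to a 10 cm sphere radius and divides consecutive
displacements by the sample interval (m/s); steps touching an undefined CM
are NaN. The CM error is `‖CM_ref − CM_ir‖ / ‖CM_ir‖`; a zero-norm standard
CM makes it undefined (excluded from aggregates with a logged count).

The simulation evaluates the error **at the waveform's positive peak**
(`argmax h`). The error definition carries no time index, and a per-sample
time average would mix in the burst's negative phase, where the "positive
CM" of the sign-flipped map lies near the coordinate origin and the relative
error becomes unbounded — those outliers would dominate the z-orientation
means. The per-sample time average remains available
(`cm_aggregation="time-mean"`) as a sensitivity check, and the vectorized
rank-1 implementation is tested against a literal per-sample trajectory
computation.

In the simulation the CM is 3-D (the error uses all coordinates); the ERP
application uses the 2-D (X, Y) CM to keep the trajectory on the scalp.
Both are exposed.

## Simulation study

Each grid dipole, oriented along x, y, z in turn, drives the damped-Gaussian
(Gabor) burst `h(t) = exp(−(2πf(t−t₀)/γ)²) cos(2πf(t−t₀)+α)` with f = 10 Hz,
γ = 5, α = π/2, t₀ = 35·dt on a 250 Hz, 100-sample base (the Gabor reading is
the only dimensionally consistent parenthesization with γ dimensionless).
The forward result is exact infinity-referenced data; AR/LM/CZ are row
operations on it, and REST is applied to the CZ-referenced version via the
transfer matrix built from the same montage and grid. The whole path is
noiseless and deterministic. Reference comparisons over dipoles use one-way
Tukey HSD with per-dipole errors as observations (the repeated-measures
error term is not meaningful for a deterministic grid).

With the symmetric fixture montage the error maps are mirror-symmetric
across x = 0 to machine precision for y- and z-oriented dipoles; for
x-oriented dipoles the mirror image corresponds to the sign-flipped map, so
exact symmetry holds only for sign-symmetric aggregations.

## ERP pipeline

Zero-phase 4th-order Butterworth low-pass at 6 Hz (forward–backward, so
latencies are preserved), then decimation to 250 Hz by sample picking (the
6 Hz cut is far below the new Nyquist, so no separate anti-alias stage is
needed). Epochs are cut on the half-open [−200, 800) ms; the baseline is the
mean over [−200, 0) ms per channel; rejection is strictly `|v| > 75 µV` on
the 59 CM-analysis channels (EOG and mastoids do not veto), applied after
down-sampling. P300 amplitude and latency are the positive peak within
250–500 ms averaged over Cz, CPz, Pz. Stage statistics compare references on
subject-level stage means (n = 12 → F(2, 22), matching the repeated-measures
design) of the CM's anterior–posterior coordinate and of the mean speed,
with Greenhouse–Geisser correction and Tukey HSD. Cross-condition velocity
correlations pair the group-mean curves: target 250–350 ms against standard
210–310 ms in S1 (40 ms lag), identical windows in S2/S3; window endpoints
snap to the nearest trajectory sample (inclusive), giving 26 paired samples
for the 100 ms windows.

## Statistical kernel

One-way repeated-measures ANOVA: `F = MS_condition / MS_(condition×subject)`
with sums of squares computed on subject-centered data — this keeps tables
with identical condition columns at exactly F = 0 instead of a ratio of
floating-point residue. Greenhouse–Geisser ε is
`(tr C)² / ((k−1) tr C²)` for the double-centered condition covariance `C`,
clipped to [1/(k−1), 1]; a vanishing `C` (compound symmetry with no
interaction variance) is treated as ε = 1. Both the uncorrected and
GG-corrected p are always returned; the headline p uses the correction when
ε < 0.75. Tukey HSD uses `q = |Δmean| / √(MS_err/n)` with studentized-range
probabilities from scipy's numerically integrated distribution (no lookup
tables); the test suite checks the critical value against an independent
double-quadrature CDF and calibrates the GG-corrected type-I error
(0.035–0.065 at α = 0.05 under a seeded spherical null, k = 3, n = 12,
2000 replicates).

## Synthetic cohort generator

The generator emulates the oddball protocol the pipeline expects: 12
subjects × 3 sessions × 150 trials, an exact 30/120 target/standard split
per session (shuffled), 500 Hz, trial timing cue 250 ms → fixation 500 ms →
stimulus 500 ms, recordings referenced to FCz (the reference electrode's
potential is simulated and subtracted, then dropped).

Components are lumped equivalent dipoles on the midline with damped-Gaussian
(slow-carrier Gabor, α = 0) time courses; each is calibrated so its
projected scalp map peaks at a stated µV value:

| name | position (x,y,z)  | peak  | env. τ | target / standard µV |
|------|-------------------|-------|--------|----------------------|
| P200 | (0, 0.45, 0.45)   | 200 ms| 35 ms  | 6 / 6                |
| P250 | (0, 0.20, 0.60)   | 250 ms| 45 ms  | 4 / 7                |
| P300 | (0, −0.15, 0.30)  | 360 ms| 90 ms  | 10 / 0 (at Pz)       |
| LFP  | (0, 0.45, 0.45)   | 600 ms| 110 ms | 4 / 4                |

The P300 dipole is deliberately deep so its map is the broad centro-parietal
positivity of a real P300 (Cz/CPz/Pz at 0.81/1.00/0.99 of peak) rather than
a narrow focal bump. The late frontal positivity (LFP) is part of the
default set because the recovery stage — the CM's return to frontal sites in
S3 — cannot exist without late frontal positive activity; it stands for the
post-response positivity real oddball data show. Across subjects, component
amplitudes are jittered lognormally (σ = 0.2) and latencies normally
(σ = 20 ms). Background activity comes from 20 random deep dipoles
(|r| < 0.6) with 20 Hz-low-passed Gaussian time courses scaled to 7 µV
sensor RMS — spatially correlated, like real EEG — plus 3 µV white sensor
noise; ~8% of trials receive a ±150 µV slow frontal deflection so the
rejection stage has realistic work (≈90% of epochs survive, as in typical
recordings). Everything is reproducible bit-for-bit from (config, seed),
and ground-truth parameters are stored alongside the data.

**What the generator does not emulate:** genuine trial-to-trial latency
jitter and amplitude habituation, ocular artifacts with realistic
topography, inter-trial-interval jitter, volume-conduction differences
between subjects (all subjects share one head model and montage), and any
fitting to real waveforms. Passing the end-to-end tests therefore shows the
*pipeline* recovers what the generator put in under realistic noise — not
that real cortical dynamics follow the three-stage pattern.

## Design choices where the design was open

- **Simulation montage**: forward modelling and re-referencing use the
  61-channel scalp montage (LM needs the mastoids), the CM uses the
  59-electrode subset — mirroring the real-data pipeline.
- **REST input reference in the simulation**: CZ (the derivation's
  formulation); immaterial in exact arithmetic, see above.
- **Error aggregation**: at-peak by default (see *Center of mass*).
- **Rejection boundary**: strictly greater than 75 µV rejects; exactly 75 µV
  is retained.
- **Intervals**: epochs and trajectory windows are half-open [start, end);
  stage means and correlation windows are endpoint-inclusive; stimulus onset
  is t = 0; all times in seconds internally.
- **P300 search window**: 250–500 ms positive peak, configurable.
- **I/O**: delimited text matrices with JSON sidecars (sampling rate,
  reference tag); montages as .sfp. No binary formats.

## Known limitations

- The exactly symmetric idealized montage makes the average reference
  unrealistically good for x-oriented (left–right tangential) dipoles: its
  offset nearly cancels by symmetry, so AR's mean CM error in the x
  orientation (~0.003) undercuts REST's (~0.025, floored by the minimum-norm
  offset-recovery error). With digitized, slightly asymmetric electrode
  positions this advantage should shrink; the package reports the measured
  ordering rather than forcing the expected one.
- Group-mean CM speeds on the default cohort sit in 0.1–3 m/s for ~94% of
  samples rather than ≥95%: the standard condition's averaged topography is
  nearly static in the quiet stretch after P250 (no P300 follows), so the CM
  barely moves there. The target-condition curve is entirely in band.
- Spherical geometry throughout: no realistic (BEM/FEM) head models, no
  individual anatomy.
- Threshold rejection only; no ocular regression or ICA.
- Positive-potential CM only; negative and spectral-power CM variants are
  out of scope.
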