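# Methods

This note records the models, conventions and numerical choices behind
`opmpipe`, and what the synthetic study conditions do and do not show
about real recordings.

## Coordinate frames and pose convention

Room and head frames share the axis convention X right–left, Y down–up,
Z back–forward; the head frame is centred on the conductor sphere and
coincides with the room axes at the start pose. Rotations are intrinsic
Tait–Bryan angles applied yaw (about Y) → pitch (about X) → roll (about
Z), stored in degrees and unwrapped over time; all internal math uses
rotation matrices. The convention is a package choice — optical trackers
and MEG toolboxes disagree on it — and is applied consistently by the
simulator, the rigid-body solver and the regression stage, so no result
depends on it.

## Synthetic study conditions

The generator emulates a three-condition auditory experiment: sitting
still at the room centre, standing still with the head 0.7 m above the
centre, and standing while moving continuously. All three share the same
neural ground truth.

* **Sensors.** 45 dual-axis magnetometers (90 channels) on a Fibonacci
  lattice over the upper scalp (polar angle ≤ 115°) at 9.65 cm from the
  sphere centre; per sensor one radial and one tangential sensitive axis,
  the tangential azimuth randomised per seed. White noise 15 fT/√Hz;
  hardware clipping at ±5.56 nT available but off by default (range
  exceedance is data loss, not a modelling target).
* **Remnant room field.** Affine: `B(p) = B0 + G (p − origin)` with
  |B0| ≈ 1.4 nT at the room centre and a gradient tensor of ~10 nT/m
  scale for the standing presets (~1 nT/m near the centre for sitting).
  A real MSR field is nonlinear; the affine model is the minimal one that
  (i) produces motion artefacts of the observed several-hundred-pT
  per-trial scale, (ii) leaves motion regression only partially effective
  when rotations are large (the artefact is nonlinear in the pose through
  the rotation matrices), and (iii) gives HFC a non-trivial job (the
  uniform part of the field is exactly removable, the across-array
  gradient part is not). The standing-preset gradient was set so that the
  moving condition produces raw mean per-trial maximal field changes of
  the several-hundred-pT-to-nT order while the residual interference
  stays in the regime where the beamformer's adaptivity is what restores
  the source-level spectrum — the regime the three-condition comparison
  is about.
* **Motion.** Each pose degree of freedom is Gaussian noise low-passed at
  0.15 Hz (zero phase, 4th order), rescaled so the realised range equals
  the requested range — defaults (1.0, 0.5, 1.15) m and (110, 150, 180)°
  for the moving preset — and shifted to start at the identity. The
  0.15 Hz smoothness makes the mean per-trial (0.5 s) displacement
  ~4–5 cm, the scale continuously moving participants produce. Still
  presets use millimetre/degree ranges.
* **Stimuli and sources.** 70 ms tones at a fixed 0.5 s ISI (~570 in a
  300 s run). Two mirror-symmetric tangential dipoles at (±54, 0, 5) mm
  carry an identical trial-locked waveform: Gaussian deflections at 50,
  100 and 200 ms with alternating sign and the 100 ms one largest, scaled
  (7 nA·m peak) so the strongest sensor-level deflection is in the
  50–150 fT range. Identical waveforms make the pair fully correlated —
  the hard case for single-dipole beamformers.
* **Line interference.** 50 Hz mains and harmonics plus 120 Hz and 83 Hz
  camera lines, each a spatially uniform oscillating field with a fixed
  random direction projected onto the channel axes (how such interference
  actually couples to a dual-axis array — and why HFC attenuates it).
* **Markers.** Six markers rigid to the head; occlusion gaps drawn per
  marker with exponential durations (mean 29 ms, clipped at 1.24 s) until
  the requested occluded fraction (8.9 % moving, 0.86 % still) is
  reached.

What the generator does **not** emulate: nonlinear room-field structure,
sensor calibration drift and cross-axis errors, cable-motion and muscle
artefacts, brain noise (1/f background sources), or inter-individual
anatomy. Passing tests therefore demonstrate that the pipeline's stages
do what they claim under the stated physics — not that real data of any
particular lab will reach the same numbers.

## Motion processing

Gap filling runs in three passes: pattern-based completion wherever ≥ 3
markers of the rigid body are visible (partial Procrustes against the
layout template, occluded markers placed from the solved pose), cubic
splines per marker for remaining interior gaps of ≤ 100 samples (fitted
to 24 flanking samples per side, hence exact at the gap edges), then
pattern-based again. Gaps touching the record boundary are reported, not
extrapolated. Marker trajectories are low-passed at 2 Hz (4th-order
Butterworth, forward–backward) *before* rigid-body solving, which uses
the Kabsch/orthogonal-Procrustes solution with proper rotations enforced.
Per-trial movement is the maximal Euclidean displacement of the
translation relative to the trial's first sample — still data scores
exactly zero.

## Interference suppression

* **Motion regression** fits each channel on [intercept, X, Y, Z, pitch,
  yaw, roll] in 10 s windows at 50 % overlap, recombined with a
  Hann cross-fade normalised to unit weight; a window whose regressors
  are (numerically) constant keeps zero motion betas, so still runs are
  not injected with tracking noise. The stage is switchable per
  condition and off in the still presets, where it is known to do more
  harm than good.
* **HFC** solves, per sample, `min_u ‖y − A u‖` with A the 90 × 3 matrix
  of channel unit axes, and subtracts `A u`. It removes ~100 % of any
  spatially uniform interference and, on this array geometry, only
  ~8–12 % of a dipolar source's energy.
* **Spectral interpolation** replaces the rFFT amplitude within ±0.5 Hz
  of each target line by the mean amplitude of the ±(0.5–1.5) Hz flanks,
  keeping phases — no notch-filter ringing.
* **Artefact rejection** automates the visual screen: a 5 s chunk is bad
  if any channel changes by > 100 pT, if a channel's 100 Hz–Nyquist
  envelope is a > 5 robust-z outlier, or if the cross-channel median
  absolute step is a > 5 robust-z outlier. Flagged chunks are excluded
  from epoching *and* from all PSD diagnostics.

## Forward model and beamformer

The conductor is the analytic homogeneous sphere (radius 9 cm); its
closed-form dipole field is validated in the tests against an independent
numerical gradient of the magnetic scalar potential (< 1e-6 relative) and
shares the spherical model's structural properties (radial moments are
silent; the sphere centre is fully silent). The source grid is a 5 mm
lattice through the sphere centre clipped at 0.9 × radius, so every point
has an exact mirror partner across x = 0; scanning uses the concatenated
pair lead field [L(i) | L(mirror i)], rank-2 reduced per dipole (the
near-silent radial column would otherwise dominate the unit-gain filter
norms — the standard MEG "reduce rank" convention).

Numerical choices that matter:

* **Rank-truncated covariance inverse.** HFC leaves the covariance with
  exactly 3 empty spatial dimensions; a plain inverse lets the
  minimum-variance filter hide in them and corrupts every power estimate.
  Eigendirections below 1e-4 of the largest eigenvalue are excluded, and
  the projected-noise floor σ₀² is the smallest retained eigenvalue.
* **NAI window power from the trial average.** Weights use the
  unaveraged single-trial covariance (0–0.5 s, per-trial demeaned); the
  mapped quantity is the second moment of the trial-averaged,
  baseline-corrected response in 0.08–0.12 s. Demeaning within a 40 ms
  window would subtract most of the M100 itself, and unaveraged window
  power lets non-trial-locked residual artefact pose as deep sources;
  averaging attenuates it by 1/n_trials.
* **Dominant-orientation NAI.** Per point the orientations are collapsed
  by the largest generalised eigenvalue of (W C_win Wᵀ, σ₀² W Wᵀ) rather
  than the trace ratio: at realistic single-trial SNR the trace is
  diluted by the weak moment orientations and biases the peak ~3 cm
  deep, while the dominant-orientation index localises the simulated
  bilateral pair to within one or two grid steps. The trace form remains
  available (`combine="trace"`).
* **Virtual channel.** All ROI pair filters are stacked into F, the
  principal eigenvector v of F C Fᵀ defines w = vᵀF (the F·C reading is
  switchable), polarity is fixed so the average peaks positive in the
  M100 window, and the average is scaled to unit M100 peak — a pure
  reporting convention (t statistics and correlations are invariant)
  that makes amplitudes and PSDs comparable across conditions, since the
  eigenvector scale is otherwise arbitrary. No NAI normalisation is
  applied to ROI series.
* **ROI.** A 12 mm sphere around the left simulated source (its pair
  filters span both hemispheres). With no anatomy in the model, a
  geometric ROI replaces an atlas parcel.

## Degenerate inputs and tie-breaks

A magnetically silent grid point (the sphere centre) yields W = 0 and
NAI 0 rather than an error. A Gram matrix with condition number > 1e12
falls back to the pseudo-inverse and is flagged. Rigid-body frames whose
visible marker set is near-collinear are flagged ill-conditioned.
Reflection-optimal Procrustes solutions are corrected to the nearest
proper rotation. Zero-variance samples in the t series report signed
infinity with a flag.

## Problem sizes

Default desk-scale runs are 60 s per condition (~115 trials); the
full protocol scale used by `scripts/acceptance.py` and the acceptance
tests is 300 s (~600 tones, ~525+ good trials) per condition, 90
channels at 1000 Hz, and a 5 mm grid (~17,800 points / ~8,900 scanned
pairs). A full three-condition run with source maps takes a few minutes
on one CPU within ~2 GB of memory; result objects drop raw-data and
ground-truth channel arrays by default to keep several full-length
conditions resident.

## Known limitations

The affine room field makes motion regression *more* linear than
reality below ~0.5 Hz and the artefact's high-frequency tail depends
on the large-angle rotation products, so the precise stage-wise
reduction factors are condition-dependent (their ordering is not). The
simulated line interference is perfectly uniform, so spectral
interpolation is nearly redundant after HFC here, while on real data it
is not. The homogeneous-sphere conductor cannot represent the ~10 %
lead-field error a realistic single-shell model corrects; localisation
statements are therefore about grid-step accuracy under the model's own
forward physics. Sensor-level t values and NAI magnitudes depend on the
synthetic noise model and should not be read as predictions for any
particular hardware.
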