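# opmpipe

Recovery of auditory evoked fields (AEFs) from wearable optically pumped
magnetometer (OPM) magnetoencephalography recorded while the participant
makes large, continuous head movements inside a magnetically shielded room
(MSR).

Wearable OPM arrays move with the head, so recording during natural
movement is possible in principle — but any motion through the MSR's
remnant static field (≈1.5 nT at the room centre, with gradients that
steepen away from it) turns into field artefacts hundreds of picotesla
strong, while the neural signals of interest are of order 100 fT.
`opmpipe` implements, end to end, the processing chain that makes the
evoked response recoverable anyway:

1. **Motion capture** (120 Hz, six retro-reflective markers): occlusion-gap
   filling (pattern-based rigid-body completion, then cubic splines for
   gaps ≤ 100 samples), 2 Hz zero-phase low-pass, per-frame orthogonal
   Procrustes rigid-body solving, and synchronisation with the
   magnetometer data.
2. **Sensor-level interference suppression**: windowed multiple linear
   regression of the 90-channel data on the six rigid-body pose regressors
   (10 s windows, 50 % overlap); homogeneous field correction (HFC) — per-
   sample removal of the best-fitting spatially uniform field using the
   channel orientations; spectral interpolation of mains harmonics and
   camera lines (50 Hz harmonics, 120 Hz, 83 Hz); zero-phase Butterworth
   band limiting (2 Hz high-pass, order 5; 40 Hz low-pass, order 6);
   automated artefact-segment rejection (100 pT per 5 s chunk, plus
   high-frequency and step rules); epoching to (−0.2, 0.5) s with a
   (−0.1, 0) s baseline.
3. **Source analysis**: analytic spherical-conductor lead fields on a 5 mm
   grid with exact mid-sagittal mirror pairing, an LCMV beamformer that
   scans **symmetric dipole pairs** (the unit-gain constraint spans both
   hemispheres, so the strongly correlated bilateral auditory responses
   are not self-cancelled), a neural-activity-index (NAI) map for the
   M100 window (0.08–0.12 s), a PCA-combined auditory-cortex virtual
   channel, and a pointwise one-sample t series.

Because no recordings are distributed, the package ships a first-class
synthetic-data generator (`opmpipe.synthetic`) that emulates the study:
45 dual-axis OPMs (90 channels, 15 fT/√Hz), an affine remnant-field model,
6-DOF band-limited head motion up to ~1 m translation and ~180°
rotation, marker occlusion statistics, bilateral auditory dipoles with
M50/M100/M200 deflections of 50–150 fT at the sensors, and line
interference. Every analysis stage is tested against this ground truth.

## The beamformer in brief

For a source (pair) with lead field `L` (channels × k) and sensor
covariance `C` from unaveraged single-trial data (0–0.5 s post-stimulus),
the spatial filter is

    W = (Lᵀ C_r⁻¹ L)⁻¹ Lᵀ C_r⁻¹ ,   C_r = C + (λ/100)·(tr C / N)·I ,

with λ = 0.1 % by default and a rank-truncated inverse (HFC leaves `C`
rank-deficient). The NAI at each grid point is the dominant-orientation
ratio of beamformer-projected evoked power (0.08–0.12 s, trial average)
to projected sensor noise `σ₀² tr(W Wᵀ)`, which cancels the depth bias of
raw beamformer power.

## Worked example

```python
import numpy as np
from opmpipe import pipeline

res = pipeline.run_condition(pipeline.preset_config("standing_moving",
                                                    duration=60.0))
print(res.stage_field_change.to_string(index=False))
times, truth = pipeline.ground_truth_epoch_waveform(res)
r = pipeline.waveform_correlation(times, res.virtual_channel.average, truth)
peak = res.source_map.peak_point() * 1000
print(f"ROI/truth correlation: {r:.3f}")
print(f"NAI peak at ({peak[0]:.0f}, {peak[1]:.0f}, {peak[2]:.0f}) mm")
```

prints (60 s desk-scale moving run, default seeds):

```
            stage  mean_trial_max_pT  max_trial_max_pT
              raw        1348.287241       7741.205119
motion_regression         304.270956       4660.504599
              hfc          17.785502        321.100424
         highpass           2.512876          3.253124
ROI/truth correlation: 0.986
NAI peak at (-50, -5, 5) mm
```

Reading: raw per-trial field changes of ~1.3 nT (the head is moving
through a ~10 nT/m gradient) fall to ~0.3 nT after motion regression, to
~18 pT after HFC, and to ~3 pT after the 2 Hz high-pass; the auditory
virtual channel then reproduces the true evoked waveform (r = 0.99) and
the M100 map peaks one grid step from the simulated left auditory source
at (−54, 0, 5) mm (its mirror partner receives the same value by
construction).

The same pipeline is scriptable from the shell:

```bash
opmpipe run --duration 60 --out scratch/report     # all three conditions
opmpipe preprocess --preset standing_moving --no-hfc --out scratch/ablate
```

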