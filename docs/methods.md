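# Methods note

This note records the model, the numerical choices, and the deliberate
deviations behind `usbonereg`, a desk-scale virtualization of a
tracked-ultrasound (iUS) bone-surface registration pipeline for
image-guided bone-tumor surgery.

## Problem model

A preoperative bone model (CT-derived mesh, frame `ct`) must be rigidly
registered to the patient's reference frame (`reference`, the optical
reference body fixed to the bone). The intraoperative measurement is a
tracked ultrasound sweep: a sequence of 2D B-mode frames, each with a
probe pose (`probe` → `reference`) and a fixed image calibration
(`image` → `probe`, plus pixel spacings in mm/px). The pipeline is:

1. **Calibration** — pivot calibration of tracked pointers (joint linear
   least squares of `R_i p_tip + t_i = p_pivot`) and needle calibration
   of the image plane (paired-point rigid fit of in-plane mm points to
   probe-frame points, optionally alternating with a linear 2-parameter
   spacing fit).
2. **Segmentation** — per-frame bone-surface detection. The default
   classical backend scores each pixel as the per-frame min-max-normalized
   product of smoothed intensity, an axial ridge response (negative second
   axial derivative of the smoothed image, clipped at zero), and an
   acoustic-shadow factor (1 − mean normalized intensity of all deeper
   pixels in the scanline), then keeps the deepest strong local maximum
   per column and the largest 8-connected component. An optional trainable
   encoder–decoder backend with skip connections is included (BCE + Dice
   loss, Adam, blur/flip augmentation); it is implemented in plain numpy
   with manual backpropagation so the package stays CPU-only with no deep
   learning dependency.
3. **Reconstruction** — every masked pixel is mapped through
   `pose ∘ image_to_probe` applied to `(u·spacing_lateral,
   v·spacing_axial, 0)`, giving a reference-frame point cloud; the cloud
   is binned into an occupancy voxel grid and detached blobs are removed
   by 26-connected component analysis.
4. **Registration** — coarse paired-landmark initialization followed by
   trimmed ICP between the (subsampled) CT surface and the ultrasound
   cloud; accuracy is the target registration error (TRE) at 10 surface
   targets, success is mean TRE strictly below 5 mm.

## Centered ridge response

A positive axial first derivative peaks at the *upper edge* of a bright
band, biasing detections ~1.5–2 px shallow. The implemented ridge term is
the negative second axial derivative of the Gaussian-smoothed image
(σ = 1.5 px, clipped at zero), which peaks at the band center. Measured
mean surface distance on simulator frames is 0.04–0.1 mm at speckle SNR
3–6 (axial spacing 0.3 mm), well inside the 2×spacing acceptance bound.

## ICP correspondence direction

Correspondences run **from the ultrasound cloud into the CT surface**:
every cloud point genuinely lies on the CT surface, whereas the reverse
direction manufactures matches for CT points the sweep never imaged. With
CT→cloud correspondences and a 10 mm gate, far-side CT points acquired
spurious matches and dragged the solution on roughly a fifth of
zero-noise runs (TREs of 5–35 mm); with cloud→CT correspondences all
zero-noise runs land at 0.15–0.37 mm TRE. Trimming (default 20 % of the
largest residuals) and the correspondence gate (default 10 mm) are kept
for robustness to outlier frames and segmentation spillover.

## Speed of sound

A scanner converting echo time to depth with an assumed sound speed
`c_assumed` while the medium's true speed is `c_true` scales every depth
by `c_true/c_assumed`. The package models this as a scale on the
*recorded axial spacing* (frames unchanged), and the same operator
corrects it. Because injection and correction act on the same scalar, a
correction with the true ratio restores the uncorrupted reconstruction
essentially exactly; the acceptance criterion allows 0.2 mm.

## Simulator

`phantom_sim` virtualizes a cadaver-style validation: a watertight
tibia-like loft (tapered, slightly bowed shaft with a sigmoid proximal
flare; 180 mm long, 12 mm shaft radius), 10 farthest-point-sampled
surface targets, a 15 mm tumor sphere in the proximal metaphysis, 9
surface landmarks (screw/K-wire analogues), and a random ground-truth
CT→reference transform (rotation 5–30°, translation 10–50 mm). A linear
probe slides along the bone axis imaging transverse planes; per frame the
visible bone curve is the *shallowest* plane–mesh intersection per image
column (everything deeper is in the acoustic shadow), rendered as a
Gaussian bright band (σ 2 px, peak 220) over Rayleigh speckle, with all
intensities below the surface attenuated to 20 %. Pose jitter is applied
on the probe side (a world-frame rotation would have an arbitrary,
placement-dependent lever arm); outlier frames displace the pose by a
fixed magnitude in a random direction, modeling transient tracking
interference.

What the simulator does **not** emulate: wave propagation, refraction,
soft-tissue deformation, curvilinear scan conversion, tracking latency,
or multi-marker line-of-sight geometry.

### Noise conventions

All translational noise magnitudes (`pose_trans_sd_mm`,
`outlier_trans_mm`, `landmark_pick_sd_mm`) are **total 3-D RMS
magnitudes** of the error vector (per-axis σ/√3). Rotational jitter is a
rotation-vector draw with the given per-axis SD in degrees. Speckle SNR
is the band peak over the mean speckle intensity.

## Key parameters (units, defaults, rationale)

| Parameter | Default | Rationale |
|---|---|---|
| frame size / pixel spacing | 128×128 px, 0.3 mm/px | desk-scale linear probe field of view (~38 mm) |
| frames per sweep | 200 | see frame-spacing constraint below |
| segmentation threshold / min score | 0.3 / 0.1 | local-max acceptance on the normalized score map |
| reconstruction voxel | 1.0 mm | component-filter granularity |
| ICP | 100 iters, tol 1e-4 mm, trim 0.2, gate 10 mm, subsample 5000 | partial overlap requires trimming; gate bounds outlier influence |
| success threshold | 5.0 mm, strict `<` | clinical surgical-margin rule |
| phantom count | 8 | study design |
| training recipe | batch 4, Adam 1e-4, BCE+Dice, blur σ 1.1 + flip each on a random 25 % of the training split, 80:20 split, 20 epochs | standard medical-segmentation recipe at desk scale |

### Frame-spacing / voxel constraint

The largest-component filter uses 26-connectivity on the occupancy grid,
so the inter-frame spacing must not exceed the voxel size: at 60 frames
the 2.3 mm spacing shreds the cloud into many components at 1 mm voxels
and registration degrades badly; at the 200-frame default the 0.7 mm
spacing keeps the reconstructed surface a single component.

## Experiment orchestration

`run_experiment` simulates N phantoms and registers each. The master seed
spawns per-phantom seeds as `phantom_seed = master_seed·1000 + k`, and
stage sub-seeds as `phantom_seed·10 + {1,2,3}` (sweep, gold-standard
picks, coarse picks), so any phantom reproduces in isolation. Per-phantom
failures are recorded, not raised; overall statistics are mean ± sample
SD over the completed phantoms. The TRE reference is configurable: the
landmark gold standard (as in a cadaver study) or the simulator's exact
transform.

The default preoperative surface is sampled directly from the phantom
mesh; a synthetic-CT path (`voxelize_and_threshold`: rasterize at 1 mm,
add optional Gaussian intensity noise, midpoint threshold, keep the
largest component, take boundary voxel centers) is available via
`ct_source: ct_voxel`.

## Definitions fixed by this package

- **Coverage** (per frame): percentage of truth-mask columns for which
  the prediction has any detection. **Mean surface distance**: mean, over
  covered columns, of the axial offset between the deepest predicted and
  deepest truth pixel, times the axial spacing. One-sided, column-wise
  definitions; other conventions exist.
- **Gold-standard registration**: closed-form paired-point (Kabsch/SVD
  with the determinant fix) on the landmark pairs, although clinical
  descriptions sometimes call this "point ICP"; with known
  correspondences the closed form is exact.
- **Coarse registration**: paired landmarks with independent pick noise
  (how coarse corresponding points are produced intraoperatively is
  underdetermined; paired landmarks are the simplest defensible choice).

## Limitations

- Accuracy figures from the simulator characterize the *algorithms*, not
  clinical performance; real B-mode bone appearance is far richer than
  the band/shadow/speckle model.
- The rigid model ignores soft-tissue pressure deformation and bone
  segmentation bias from beam width.
- The trainable backend is a deliberately small CPU network for
  protocol-shape verification, not a competitive segmenter.
- Timing is logged but never asserted; wall-clock performance is
  hardware-dependent.
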