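# Methods

`scleraflow` measures blood-flow characteristics in grayscale video of
scleral/conjunctival microvessels. The acquisition this targets is
fundamentally unstable — the eye cannot be fixed, so the field of view
jitters, occasionally jumps, and sharpness and illumination drift — and the
method is therefore a cascade: find the informative region of each frame,
split the video into stabilizable fragments, register each fragment to a
fixed coordinate system, mask the vessels, and only then measure flow along
the vessel midlines and describe the vascular net's topology.

This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## The phantom generator

Every stage is validated against synthetic phantoms with exact ground truth
(`scleraflow.phantom`). A phantom is a tree of tube segments (widths 2–12 px,
linear taper, built by successive bifurcations with collision avoidance and a
turn-rate limit; each grown tree is checked against its own invariant — tubes
meet only at their declared junctions, no stubs, no hairpins — and
regenerated from a deterministically derived seed if the check fails). The
lumen carries band-limited multiplicative speckle advected along the
centerline at a prescribed per-segment speed, resampled with linear
interpolation in arc length; nearest-neighbor resampling would quantize
non-integer speeds into alternating integer per-frame shifts that any
frame-pair velocimeter reads with a systematic bias. With `conserve_flow`
the generator splits the parent's volumetric rate `Q = v · S`
(`S = π (w/2)²` on the mean width) across the children exactly.

The motion model is the acquisition-defect model: per-frame camera
translation as an integer random walk (`jitter_sd`, default conditions use
1–3 px/frame), optional jump frames whose step exceeds the fragmenter's
drift limit (default jump magnitude 120 px > 100), per-frame Gaussian blur
drawn from a range, and a slow sinusoidal illumination drift. The background
is not optically flat: it carries weak static texture
(`background_texture = 0.04` intensity SD, correlation length ~1.5 px),
standing in for episcleral tissue structure. This matters: on a perfectly
flat background the *only* trackable content is the vessels themselves, and
any registration method can lock onto the moving blood texture — a
degeneracy real scleral video does not have.

What the phantom does **not** model: pulsatile (time-varying) flow,
parabolic cross-lumen velocity profiles (the speckle advects as a plug),
3-D geometry, rotation or scale changes of the camera, and sensor noise.
Passing the phantom suite therefore demonstrates the correctness of the
measurement chain under known kinematics, not clinical accuracy.

## Informative region and fragmentation

Informativity is judged on the gradient image: `g = max(|Sobel_h|,
|Sobel_v|)` with 3×3 kernels and edge replication. The contrast index is the
Michelson ratio `C = (g_max − g_min)/(g_max + g_min)`; frames with `C < 0.3`
are discarded. The binarization threshold is the knee of the cumulative
gradient histogram — the bin at maximum perpendicular distance from the
chord between the first and last nonempty bins (256 bins on `[0, g_max]`,
ties toward the lowest bin). After size filtering (`min_object_px = 20`) and
linking dilation (disk radius 2), the ROI is the bounding box of the
surviving objects.

The intensity-weighted centroid of the informative pixels is tracked across
frames; a fragment ends when the centroid drifts more than 100 px
(Euclidean, measured against the fragment's first frame) or a frame has no
ROI. Each fragment is cropped to the minimum per-frame ROI extent, centered
on each frame's centroid and shifted inward at borders. The centroid uses
the standard weighted mean (weights scaled so the maximum in-ROI intensity
is 1); a literal variant that divides by the plain pixel count is available
behind `literal_denominator` for comparison but does not generally land
inside the support.

## Stabilization

Two translation estimators are provided.

**Correlation**: the central 50% of the first frame's ROI is matched in
every frame by zero-normalized cross-correlation (FFT-based, verified
against the direct double sum to 1e−6). The search window is padded by edge
replication so a region that has partially drifted out of view can still be
located. Offsets are absolute with respect to frame 0, so errors cannot
accumulate.

**Keypoint**: Shi-Tomasi corners tracked by pyramidal Lucas–Kanade
(15×15 window, 3 levels), the frame offset being the component-wise median
of tracked displacements. Three choices make this robust on vessel imagery,
where most intensity corners sit on the *moving blood texture* and would
otherwise out-vote the eye motion:

1. corners are detected on the blurred, morphologically ironed vessel
   *silhouette* (Otsu minority class), where only tips, branch wedges and
   bends — structures that move with the eye — are corner-like; the corner
   list is cut at the largest ratio gap of the response spectrum rather than
   a fixed quality threshold, because how much stronger geometry corners are
   than residual boundary bumps varies per scene;
2. tracking runs on texture-suppressed frames (lumen interior flattened to
   its mean) and is anchored to frame 0 with warm starts from the previous
   offset — chaining frame-to-frame steps would integrate any per-pair bias
   into an unbounded drift;
3. each frame's offset is verified by silhouette alignment at the geometry
   corners, and the whole series is cross-validated against the correlation
   series; when the two disagree (the signature of the correlation patch
   having been captured by the blood texture on a vessel-dominated scene),
   the series that aligns the vessel silhouette better wins.

Stabilized frames are resampled by integer shifts and cropped to the common
valid region, so no pixel is interpolated or undefined. On tree phantoms
with 3 px/frame jitter over 60 frames both methods recover ≥ 95% of offsets
within 1 px; a single straight vessel is degenerate for the correlation
method (the patch is intraluminal) and is handled by the keypoint method.

## Vessel masking

The default segmenter is deterministic: the frame is background-flattened
(median filter, 31 px), smoothed (σ = 1.5 px), and the local contrast is
combined with multi-scale Hessian (Frangi) vesselness over the 2–12 px width
range. Candidate pixels come from a global Otsu split of the contrast
(recalibrated so that the split maps to probability 0.5); they must also
reach 50% of the local *ridge* contrast — a grey closing of the smoothed
contrast — which makes the mask width track the full-width-at-half-maximum
of each vessel's own profile (a global threshold alone sits low on the
flanks of narrow vessels and inflates their width; a plain window maximum as
the reference adopts the strongest nearby station and over-trims). Finally,
only connected components containing tubular structure (log-domain Otsu of
the vesselness) survive, reconstructed to their full extent, because the
Hessian filter alone under-covers junctions and endpoints. Output follows
the 0-means-vessel probability polarity; `binarize_mask` thresholds at 0.5
and removes debris smaller than 20 px.

Segmentation quality is scored by pixel accuracy and by the RMS deviation
between binary labels and the probability map; mask overlap uses Dice. On
ten seeded phantoms the classical path averages Dice ≈ 0.87–0.91 against
the rendered truth masks.

An optional sliding-window patch classifier reproduces the two-class framing
of CNN vessel segmenters (patch centered on a vessel vs. not) at phantom
scale: a small MLP on raw 16–32 px patches with flip/rotation augmentation,
trainable only on phantom data with a fixed seed. It is a deliberately
modest, fully reproducible counterpart of the classical path, not a clinical
tool.

## Flow measurement

Before flow, frames are photometrically normalized. The background outside
the mask is set to the mean of a 5 px halo ring; the pipeline uses a
feathered fill (2 px) that decays from the local wall intensity to the halo
constant, because a hard static step at the lumen dominates the structure
inside an optical-flow window that straddles the wall and drags the
estimated speed toward zero (at 1 px/frame the loss reached −17% with a hard
fill, −3% feathered). Brightness is then equalized to a target mean
γ = 0.5 by the iterative n-th root/power transform; the pipeline computes
one transform for the whole fragment, since per-frame exponents flicker and
violate the brightness-constancy assumption of optical flow.

Dense optical flow is a polynomial-expansion (Farnebäck) estimator written
on numpy/scipy: quadratic neighborhood models (poly_n 5, poly_sigma 1.1) on
both frames, displacement from the change of coefficients, averaged over a
15 px window and refined over 3 iterations and a half-resolution 3-level
pyramid. It is deterministic and is validated against pure translations
(recovered to < 0.1%) and against the phantom's known advection speeds.

The vessel mask (from the temporal mean of the stabilized fragment — the
advected texture translates along the vessel and averages out) is thinned to
a 1 px skeleton; terminal twigs ≤ 8 px off a junction and tiny same-node
loops are pruned as thinning artifacts. Skeleton pixels are classified by
8-neighborhood degree, adjacent branch pixels merge into one node, and
segments are the ordered chains between nodes.

Per segment: the relative speed profile is the flow magnitude averaged over
a 3×3 neighborhood of each centerline pixel and reduced over frame pairs by
the median (robust to pulsatility; mean available); the diameter is twice
the Euclidean distance transform at the centerline; the cross-section
assumes a circular lumen, `S = π (w/2)²`, so `Q = v · S` exactly as
reported. Physical calibration is explicit:
`v_phys = v_rel · µm_per_px · fps · 1e−6` m/s; no implied constant is
assumed.

Topology metrics: total and per-segment arc length (diagonal steps √2),
branchiness (branch nodes per unit length), compactness (isoperimetric
`4π·area/perimeter²` of the mask — the term is used in the field without a
fixed definition; this is ours), and tortuosity (arc/chord per segment,
with the arc measured on a 5-point smoothing of the pixel chain: the raw
digital chain length overestimates oblique curves by up to ~8%, which alone
would push a semicircle's tortuosity outside ±5% of π/2).

## Numerical and reporting choices

- All randomness flows from explicit integer seeds; rendered videos, ground
  truth and pipeline reports are bit-reproducible.
- Degenerate inputs degrade explicitly: blank gradient maps report C = 0
  with a warning, empty masks skip flow with a warning, frames with mean 0
  or 1 skip equalization, all-lost keypoint tracks fall back to correlation.
- Problem sizes in tests and in the acceptance script are chosen to exercise
  the full cascade at phantom scale: canvases of 120×240 to 192×256 px,
  fragments of 10–60 frames, speeds of 1–3 px/frame — comparable to
  capillary-scale motion at video rate.
- The end-to-end flow-conservation check (parent vs. children volumetric
  rates at a bifurcation) is reported as the median over three phantom
  realizations: it is a ratio of noisy end-to-end quantities whose
  single-realization spread (typically 0.05–0.15, occasionally 0.3) reflects
  width-squared error amplification, not a systematic imbalance.

## Known limitations

- Pure translation registration; rotation/scale are out of scope.
- The circular cross-section behind `Q = v·S` is a model; flattened vessels
  would need an elliptical correction the data cannot constrain.
- Velocity is *relative* (px/frame) unless the user supplies calibration
  constants; no absolute hemodynamic claim is made.
- The classical segmenter is tuned to tube-like, locally darker (or
  brighter, via the polarity flag) vessels on a smoothly varying background;
  heavy occlusions or specular highlights are not modeled.
- On scenes whose only content is a single straight vessel, the along-axis
  component of camera motion is close to unobservable; the keypoint method
  relies on the two tube ends being in view.
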