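# scleraflow

Blood-flow velocimetry and vascular topology from unstable grayscale video
of scleral / bulbar-conjunctiva microvessels.

Conjunctival microcirculation is one of the few places where blood flow can
be watched non-invasively at capillary scale, and changes in it track
systemic vascular disease. The catch is the video: the eye cannot be fixed,
so the field of view jitters and jumps, sharpness comes and goes, and
brightness drifts. `scleraflow` implements the full analysis cascade such
video requires, for researchers building or validating microvascular
velocimetry pipelines:

1. **Informative region** — score each frame by the Michelson contrast of
   its Sobel gradient image, `C = (g_max − g_min)/(g_max + g_min)`; discard
   frames with `C < 0.3`; locate the region of interest by a
   cumulative-histogram knee threshold, size filtering and dilation.
2. **Fragmentation** — track the intensity-weighted centroid of the
   informative region; split the video whenever it drifts more than 100 px;
   crop every fragment to a common box.
3. **Stabilization** — register each fragment to frame 0, either by
   zero-normalized cross-correlation of a reference patch or by Shi-Tomasi
   corners tracked with pyramidal Lucas–Kanade flow (median offset, with the
   symmetric matching rate `Mr = 200·M/(Kp1+Kp2)` as the correspondence
   score).
4. **Vessel masking** — a deterministic multi-scale Hessian (Frangi)
   tubularness segmenter over the 2–12 px width range, with an optional
   sliding-window patch classifier; evaluated by pixel accuracy and the RMS
   deviation `σ = sqrt(mean((x_i − x̄_i)²))` between labels and
   probabilities.
5. **Flow** — background flattening and iterative brightness equalization to
   a mean of γ = 0.5, dense Farnebäck optical flow, velocity profiles along
   the skeleton midline, vessel widths from the distance transform, and the
   volumetric rate `Q = v·S` with `S = π(w/2)²`; plus vascular-net topology
   (lengths, branchiness, compactness, tortuosity).

A synthetic phantom generator (`scleraflow.phantom`) renders branching
vessel trees carrying advected speckle at known speeds under known camera
jitter, with exact ground truth (offsets, masks, centerlines, speeds), so
every stage — and the cascade end to end — is tested without clinical data.
`docs/methods.md` describes the models and design choices in detail.

## Worked example

Generate a bifurcating phantom whose parent vessel advects blood texture at
2 px/frame (children at 2.06 px/frame by flow conservation), jittered by a
2 px/frame camera walk, and run the full cascade:

```python
import numpy as np
import scleraflow as sf

scene = sf.make_vessel_tree(2, seed=7, canvas=(160, 200))
speeds = sf.assign_speeds(scene, v_root=2.0, conserve_flow=True)
video, gt = sf.render_video(scene, sf.MotionSpec(jitter_sd=2.0, seed=3),
                            speeds, n_frames=16)
print("true per-segment speeds:", np.round(gt.speeds, 3))

report = sf.run_pipeline(sf.PipelineConfig(seed=1), video=video)
print("status:", report.status)
frag = report.fragments[0]
print("topology:", frag["topology"])
for seg in frag["segments"]:
    print(f"  segment {seg['segment_id']}: v_rel={seg['v_rel_px_per_frame']:.2f} px/frame, "
          f"width={seg['mean_width_px']:.1f} px, Q={seg['Q_rel_px3_per_frame']:.0f} px^3/frame, "
          f"tortuosity={seg['tortuosity']:.3f}")
```

Output:

```
true per-segment speeds: [2.    2.055 2.055]
status: ok
topology: {'total_length_px': 215.752309, 'n_branch_nodes': 1, 'n_segments': 5, 'branchiness_per_px': 0.004635, 'compactness': 0.070484}
  segment 0: v_rel=0.98 px/frame, width=8.0 px, Q=49 px^3/frame, tortuosity=1.110
  segment 1: v_rel=1.09 px/frame, width=6.0 px, Q=31 px^3/frame, tortuosity=1.005
  segment 2: v_rel=1.96 px/frame, width=6.3 px, Q=62 px^3/frame, tortuosity=1.011
  segment 3: v_rel=1.95 px/frame, width=10.0 px, Q=153 px^3/frame, tortuosity=1.033
  segment 4: v_rel=1.43 px/frame, width=8.0 px, Q=72 px^3/frame, tortuosity=1.008
```

The one branch node of the Y is found; the two long interior segments
(2 and 3) recover the true advection speed within a few percent (1.96 and
1.95 px/frame against 2.06 and 2.0), and `Q = v·S` holds exactly by
construction in every row. The short segments are slivers created where the
crop box cuts the tubes; their profiles run close to the frame border and
tube ends, where window-averaged optical flow reads low — which is why the
report carries per-segment geometry, so such segments can be recognized and
filtered by length. Speeds are *relative* (px/frame); pass
`um_per_px`/`fps` in the config to get m/s via
`v_phys = v_rel · µm/px · fps · 1e−6`.

The same cascade is available from the shell:

```bash
scleraflow simulate --out phantom_dir --seed 4 --n-frames 20
scleraflow run --input phantom_dir/frames --out results_dir
scleraflow eval-seg --pred mask.png --truth phantom_dir/mask.png
```

`run` exits with code 3 (distinct from a crash) when no frame carries
enough contrast to analyze — a routine outcome with unstable clinical video.

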