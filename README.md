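# sheetflow

Quantifying single-cell and collective cellular motion in timelapse
microscopy — without tracking single cells.

`sheetflow` is aimed at labs running long (days-scale) two-colour epithelial
migration assays: two dyed cell populations seeded either side of a gap
migrate toward each other, meet, and either merge, form a stable boundary,
or one population pushes the other back. At one frame per hour over 96+
hours, individual-cell tracking is fragile; `sheetflow` instead partitions
the first frame into a regular grid of ~1000 *superpixels* (near-square
tiles, ~37 px across on a 1344×1024 frame), estimates dense optical flow
between consecutive frames, and advects each superpixel centroid by the
mean flow over the image area it covers. Concatenating positions gives
long-time tracks `r_i(t)` that are guaranteed continuous and cheap to store
(a few MB per video).

## The statistics

Local context comes from two graphs over the superpixels:

- the **static mesh**: `i ~ j` iff `‖r_i(0) − r_j(0)‖ ≤ 1.2·w` (with `w`
  the average superpixel width), frozen for the whole video;
- the **radius-neighbour graph**: rebuilt each frame from current
  positions with a larger cutoff (`5·w`), so node degree tracks where
  motion concentrates.

From these, per video:

- **mesh strain curve** ε(t) = mean over i of
  `(1/|N_i|) Σ_{j∈N_i} |d_ij(t) − d_ij(0)|` — mean absolute change of
  neighbour distances (an L1 statistic, robust to occasional flow errors);
  normalized by its maximum over a common time window it is the video's
  *motion signature*;
- **mesh stability index** = 1 − end gradient of the normalized strain
  curve on time rescaled to [0, 1]; 1 means the mesh has plateaued (a
  stable configuration), ≤ 0 means it is still distorting linearly;
- **mesh order** — the polar order parameter `ψ = ‖⟨v̂_i⟩‖` applied to
  resultant mesh-strain vectors instead of instantaneous velocities;
- **MSD/RMSD** with power-law exponent α (α = 1 diffusive, α = 2
  ballistic), **spatial velocity correlation** with exponential-decay fit
  `a·e^(−r/b)`, and the **normalized velocity cross-correlation (VCC)**
  `max_m |C(m)| ∈ [0, 1]` between track pairs over all time lags;
- **motion saliency map** — per frame, each superpixel's radius-graph
  degree written at its position, averaged over time and over the frame-0
  partition; boundaries act as motion sinks and show up as ridges;
- **boundary formation index** — Otsu-split signal-to-noise of the
  saliency map, `(mean(high) − mean(low)) / mean(high) ∈ [0, 1]`: 0 for
  uniform motion, 1 for motion concentrated on a single line.

The boundary module segments each channel (k-means or entropy-based),
extracts migrating fronts with a sweepline, detects the **gap-closure
frame** from the front-to-front distance curve (asymmetric-least-squares
baseline + smoothing spline), and summarises the interface by displacement,
infiltration, shape (arc length / chord) and intermixing. The phenotyping
module turns motion signatures into 2-D **motion maps** (PCA over a
cohort) and clusters superpixel tracks into motion groups (Gaussian
mixtures, BIC-selected k).

A synthetic module renders two-channel gap-closure videos with scripted
outcomes (`coalesce` / `stable_boundary` / `push_through`) and known ground
truth, plus Brownian/ballistic point-process tracks — so the full pipeline
is testable without any external data.

## Worked example

Render a stabilising-boundary video and a push-through video, track both,
and compare:

```python
import numpy as np
import sheetflow as sf

for scen in ("stable_boundary", "push_through"):
    spec = sf.ScenarioSpec(scenario=scen, shape=(160, 224), gap_width=84,
                           speed_left=3.0, speed_right=3.0, n_frames=42, seed=0)
    video, truth = sf.render_two_sheet_video(spec)
    bundle = sf.track_video(video, n_superpixels=150, seed=0,
                            flow_params={"radius": 7, "num_warp": 3})
    report = sf.analyse_bundle(bundle, stability_tail=10)
    masks = [np.stack([sf.segment_sheet_frame(video.channel(c)[t], avg_width=13)
                       for t in range(video.n_frames)]) for c in (0, 1)]
    closure = sf.gap_closure_frame(sf.gap_distance_curve(masks[0], masks[1]))
    print(f"{scen:16s} closure det/true {closure}/{truth.closure_frame} "
          f"stability {report['mesh_stability_index']:.3f} "
          f"BFI {report['boundary_formation_index']:.3f}")
```

prints

```
stable_boundary  closure det/true 14/14 stability 1.000 BFI 0.696
push_through     closure det/true 14/14 stability -1.013 BFI 0.645
```

Both scenarios close the 84 px gap at the predicted frame (84 / (3+3) =
14). After contact the stabilising boundary freezes the mesh — the strain
curve plateaus and the stability index hits 1 — while the push-through
mesh keeps distorting (index < 0). Motion also concentrates more sharply
on the contact line in the stable case (higher boundary formation index).

The same stages are scriptable from the shell:

```bash
sheetflow simulate --scenario stable_boundary --seed 0 --out sim.tif --truth truth.json
sheetflow track --input sim.tif --n-superpixels 1000 --out bundle.h5
sheetflow measure bundle.h5 --out report.json
sheetflow boundary --video sim.tif --out boundary.json
```

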