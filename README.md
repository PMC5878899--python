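# femurshift

Analysis of femur motion in B-mode ultrasound during isometric knee
extension.  When a subject ramps knee-extension torque up to ~0.9 MVC and
back down, the femur — imaged through the quadriceps with a fixed probe —
does not drift smoothly: it *dwells* at a few discrete positions and hops
between them, a "gear shifting" pattern reminiscent of a car gearbox.
This package provides a tested, reusable pipeline to quantify that
pattern from an ultrasound frame sequence plus a synchronized torque
trace, and a synthetic trial generator with full ground truth so every
stage can be validated without clinical recordings.

The pipeline stages:

1. **Guided filter** — edge-preserving speckle smoothing.  In each
   window ω the filtered output is the averaged local linear model
   `q = ā I + b̄` with `a = cov(I, p) / (var(I) + ε)`, `b = p̄ − a Ī`
   (defaults r = 8, ε = 0.4² on [0, 1]-rescaled intensities).
2. **LBF level set** — femur segmentation by implicit active contours
   driven by local binary fitting energy.  Two spatially varying
   intensity fits f₁ (interior) and f₂ (exterior), each estimated through
   a Gaussian kernel G_σ, drive the evolution

   ∂φ/∂t = δ_ε(φ)(λ₁e₁ − λ₂e₂) + ν δ_ε(φ) κ + μ(∇²φ − κ),

   with eᵢ(x) = ∫ G_σ(x−y)|I(x) − fᵢ(y)|² dy, κ the level-line
   curvature, and interior = {φ < 0}
   (defaults λ₁ = 1, λ₂ = 2, ν = 0.001·255·225, μ = 1, σ = 10, Δt = 0.1).
3. **Tracking** — per-frame mask centroids in mm, dwell-time occupancy
   maps, interpolation of short gaps.
4. **Gear-shift statistics** — the trial is split by the torque trace
   into contraction / relaxation / rest (peak splits the working stages;
   rest begins when torque < 0.05 MVC), each working stage is cut into
   k = 3 phases by exact dynamic-programming change-point segmentation
   (globally minimal within-segment sum of squares), and the phases
   (#A, #B, #C, then #C′, #B′, #A′) get scalar positional variances,
   Small/Medium/Large ranks, and Euclidean distances between the
   torque-matched pairs #A–#A′, #B–#B′, #C–#C′.

## Worked example

```python
from femurshift import (TrialDesign, generate_torque_trace,
                        generate_gear_trajectory, analyze_trial)

design = TrialDesign(seed=1)           # 240 frames @ 25 fps, 0.9 MVC peak
torque = generate_torque_trace(design)
track, truth = generate_gear_trajectory(design)
report = analyze_trial(track, torque)

print("true     :", truth.true_change_points)
print("recovered:", report.change_points)
print(report.variance_table().to_string(index=False))
print(report.distance_table().to_string(index=False))
```

prints

```
true     : {'contraction': [32, 67], 'relaxation': [131, 164]}
recovered: {'contraction': [32, 67], 'relaxation': [130, 164]}
cluster       stage  variance_mm2   rank
     #A contraction      0.164789 Medium
     #B contraction      0.193002  Large
     #C contraction      0.091103  Small
    #C'  relaxation      0.113928 Medium
    #B'  relaxation      0.506494  Large
    #A'  relaxation      0.107531  Small
  pair  euclidean_distance_mm
#A-#A'               1.935624
#B-#B'               0.129995
#C-#C'               0.022101
```

The gear transitions are recovered to within one frame; the relaxation
middle phase #B′, generated with the largest positional jitter, is ranked
Large; and the #A–#A′ distance recovers the configured 2 mm offset
between the contraction start and relaxation end positions (incomplete
return of the muscle to its initial configuration), while the other two
pairs return essentially to zero.

For image-based runs, the CLI orchestrates the full chain:

```bash
femurshift synth --out fixture --seed 1        # synthetic trial + ground truth
femurshift run --frames fixture/frames --torque fixture/torque.csv \
    --out results --roi 14 8 96 124 --init-rect 20 20 70 100
```

which writes per-frame masks, the centroid track CSV, a dwell map, the
gear report JSON, per-cluster variance and pair-distance tables, an
overlay plot and a reproducibility manifest.

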