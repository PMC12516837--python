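# blurmoe

Sharpness-gated mixture of experts (MoE) for tile-based whole-slide-image
(WSI) classification under heterogeneous blur.

Digital pathology slides are rarely uniformly sharp: scanner defocus
leaves regions blurred, and a classifier trained on sharp tiles degrades
on them.  Instead of discarding low-quality tiles, `blurmoe` keeps every
tile and routes it by measured sharpness to a model trained for its blur
regime:

1. tile sharpness is estimated as the **variance of the Laplacian (LV)**
   — low LV means blur;
2. a deterministic **gate** compares LV against calibrated thresholds
   τ₁ > τ₂ > … > τ_{m−1} and assigns the tile to one of *m* experts,
   each trained on tiles blurred at a fixed Gaussian σ;
3. expert outputs are combined into a slide-level probability — either
   the 75th percentile of pooled tile probabilities (tile-classifier
   track) or the tile-fraction-weighted average
   p̂ = Σᵢ wᵢ p̂ᵢ with wᵢ = nᵢ/n_tot (attention track).

The thresholds come from two measurements the package automates: a
σ→LV calibration curve (median LV of a tile sample blurred at each σ on
a grid) and a cross-blur AUC matrix (every expert evaluated on
validation sets blurred at every grid σ); each boundary between adjacent
expert bands becomes the average of the median LVs of the two
consecutive boundary sigmas.

The package is a complete desk-scale laboratory for the method: a
seeded synthetic-cohort generator whose class signal is carried by
high-spatial-frequency texture (so Gaussian blur progressively destroys
separability), a blur/scenario simulator, LV quality control, threshold
calibration, two reference expert implementations (logistic tile
classifier and gated-attention multiple-instance head over handcrafted
features — real backbones plug in behind the same contract), and a
benchmark harness.  See `docs/methods.md` for the model and design
choices.

## Worked example

```python
import numpy as np
from blurmoe.synthetic import SyntheticConfig, generate_cohort, make_cv_splits
from blurmoe.experts import train_tile_expert
from blurmoe.calibration import (calibrate_sigma_to_lv, select_expert_ranges,
                                 derive_lv_thresholds)
from blurmoe.benchmark import blur_sensitivity_sweep, scenario_benchmark

cohort = generate_cohort(SyntheticConfig(n_patients=120, tiles_per_slide=24, seed=42))
train_ids, val_ids = make_cv_splits(cohort.patient_ids, cohort.labels, k=2, seed=0)[0]
train, val = cohort.subset(train_ids).bags, cohort.subset(val_ids).bags

sigmas = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
experts = {f"E{s:g}": train_tile_expert(train, sigma=s, seed=100) for s in sigmas}
matrix = blur_sensitivity_sweep([experts], [val],
                                [0, 1, 2, 3, 4, 5, 6, 8, 10])
calib = calibrate_sigma_to_lv([t.image for b in train for t in b.tiles],
                              n_sample=150, seed=1)
ranges = select_expert_ranges(matrix.table, {f"E{s:g}": s for s in sigmas})
gating = derive_lv_thresholds(calib, ranges)
print("expert bands:", ranges.entries)
print("LV thresholds:", np.round(gating.thresholds, 1))

report = scenario_benchmark([experts["E0"]], [experts], [gating], [val],
                            scenario_ids=(1, 3, 11), seed=7).summary()
print(report.round(3))
```

Output (seeds as above):

```
expert bands: [('E0', [0.0, 1.0, 2.0]), ('E2', [3.0]), ('E3', [4.0, 5.0]), ('E4', [6.0]), ('E5', [8.0, 10.0])]
LV thresholds: [7.4 2.9 1.8 1.7]
             auc_baseline  auc_moe  delta
scenario_id
1                   0.975    0.975  0.000
3                   0.405    0.654  0.249
11                  0.461    0.662  0.201
```

Reading this: the sharp-trained baseline keeps the band up to σ≈2 and
blur specialists take over beyond it; the LV thresholds are the gate.
In scenario 1 (all tiles essentially sharp) MoE and baseline are on par;
in scenarios 3 and 11 (tiles dominated by heavy blur, σ ∈ [5, 10]) the
baseline collapses toward chance while the gated mixture recovers a
large part of the discrimination — the headline behaviour of the
method.  The two-fold benchmark in the test suite runs all 12 scenarios.

A CLI wraps the same stages (`blurmoe make-synthetic | sharpness |
simulate-blur | calibrate | train-experts | sweep | derive-gates |
infer | benchmark | run-all`); `blurmoe run-all --out run/ --seed 5`
executes the whole pipeline and writes every artifact (calibration
table, experts, gates, sensitivity matrix, scenario report) with the
seed and config hash embedded.

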