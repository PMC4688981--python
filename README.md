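# morphatlas

Morphometric atlas selection for multi-atlas brachial-plexus (BP)
autosegmentation — a reusable evaluation pipeline.

## The problem

The brachial plexus is an organ at risk in head-and-neck, breast and lung
radiotherapy, but it is nearly invisible on planning CT, which makes manual
delineation unreliable and atlas-based autosegmentation attractive.  In
multi-atlas segmentation, several pre-delineated reference datasets
(atlases) are deformably registered to the patient, their BP contours are
propagated, and the propagated contours are fused into one consensus.
Registration quality — and hence contour quality — depends on how
anatomically similar each atlas is to the patient.  For the BP, shoulder
posture is the dominant factor, summarised by the **protraction distance**
*D*: the anterior–posterior offset between the anterior tubercle of C5 and
the infraglenoid tubercle of the scapula.

This package implements and evaluates the resulting selection strategy:
given a database of atlases with known protraction distances, pick the *k*
atlases closest to the patient's *D*, propagate and fuse them, and compare
the accuracy against fusing *k* randomly chosen atlases.

## What is inside

| stage | module | method |
| --- | --- | --- |
| phantom atlas database | `morphatlas.synthetic` | BP-like tubular masks, landmark pairs encoding *D*, and a simulated registration whose label-transfer error has RMS `a + b·|ΔD|` mm |
| morphometry | `morphatlas.morphometry` | `protraction_distance`, ranking and top-*k* selection |
| label fusion | `morphatlas.fusion` | STAPLE EM (per-rater sensitivity *p<sub>j</sub>* and specificity *q<sub>j</sub>*, voxelwise posterior *W<sub>i</sub>*), majority-vote baseline |
| scoring | `morphatlas.metrics` | DSC = 2\|A∩B\|/(\|A\|+\|B\|), JI = \|A∩B\|/\|A∪B\|, INI = \|A∩B\|/\|A\| |
| experiment | `morphatlas.experiment` | leave-one-out selected-vs-random arms (k = 2..8), Welch t-tests, equivalence trial (two-sided 90 % CI within a 10 % margin), power-based sample size |
| I/O + CLI | `morphatlas.io`, `morphatlas.cli` | NIfTI masks, landmark JSON, manifest CSV, YAML config; `morphatlas` console script |

Real cadaver CT atlases and commercial registration engines are not
redistributable, so every stage is exercised on synthetic phantoms whose
statistical structure matches the clinical setting; the registration
interface is pluggable so a real engine can be substituted.

## Worked example

```python
import numpy as np
from morphatlas import (
    SyntheticConfig, generate_database, rank_atlases, select_top_k,
    simulate_registration, staple, score_pair,
)

config = SyntheticConfig(seed=42)          # 12 phantoms, 48^3 grid, 2 mm voxels
db = [p.atlas for p in generate_database(config)]

patient, pool = db[0], db[1:]
print(f"patient protraction: {patient.protraction_mm:.1f} mm")

ranked = rank_atlases(patient.protraction_mm, pool)
chosen = select_top_k(ranked, 6)
print("selected atlases:",
      [(a.id, round(a.protraction_mm, 1)) for a in chosen])

propagated = [simulate_registration(a, patient, config, seed=i)
              for i, a in enumerate(chosen)]
fused = staple(propagated)
print(f"STAPLE converged after {fused.n_iterations} iterations; "
      f"rater sensitivities {np.round(fused.sensitivities, 3)}")

scores = score_pair(patient.gold_mask, fused.consensus)
print(f"DSC={scores.dsc:.3f}  JI={scores.ji:.3f}  INI={scores.ini:.3f}")
```

prints

```
patient protraction: 58.7 mm
selected atlases: [('atlas_07', 59.3), ('atlas_06', 58.1), ('atlas_03', 54.9), ('atlas_02', 62.9), ('atlas_11', 66.3), ('atlas_05', 68.8)]
STAPLE converged after 13 iterations; rater sensitivities [0.633 0.529 0.562 0.522 0.611 0.548]
DSC=0.752  JI=0.603  INI=0.885
```

The patient's six nearest atlases by protraction are fused; each rater's
estimated sensitivity (~0.5–0.6) reflects the simulated registration error,
and the fused consensus recovers the gold standard with DSC 0.75 — far
better than any single propagated contour.  The inclusion index (0.885) is
higher than the DSC because it does not penalise false-positive voxels.

The same pipeline is available from the shell:

```sh
morphatlas simulate --n 12 --seed 1 --out atlases/
morphatlas measure --manifest atlases/manifest.csv
morphatlas evaluate --config config.yaml     # full leave-one-out experiment
```

`evaluate` writes `runs.csv` (one row per fused combination: patient, k,
strategy, combination, dsc, ji, ini), `summary.csv` (per-arm, per-k means
and SDs) and `statistics.json` (per-k Welch t-tests and the equivalence
ladder around the best-performing atlas count).

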