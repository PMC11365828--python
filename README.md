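# osteoplan

3D preoperative planning for high tibial osteotomy (HTO) normally requires a
CT scan, acquired supine and at a high dose, even though the clinically
decisive deformity measurements describe the *standing*, weight-bearing leg.
Calibrated biplanar radiography (EOS-style systems) acquires simultaneous
frontal and sagittal standing images at a fraction of the dose — but gives
only two projections, and the full-leg field of view superimposes the two
legs in the sagittal image.

`osteoplan` implements a complete desk-scale pipeline that closes this gap:

1. **Phantom cohort** — synthetic two-leg lower-limb "patients"
   (femur/tibia surrogates with a tilted articular plateau and a soft-tissue
   envelope) with analytically known hip/knee/ankle joint centers
   ($H_C$, $K_C$, $A_C$), varus deformity and tibial slope, replacing a
   patient CT cohort so the whole pipeline is trainable and testable.
2. **DRR simulation** — digitally reconstructed radiographs under the
   biplanar geometry (frontal rays along $-Y$, sagittal along $-X$, shared
   vertical axis; parallel or translating-fan-beam mode), the clinical
   right-leg anterior shift (40–60 mm) and sagittal rotation (10°–20°)
   augmentation, single-leg target images through the logistic contrast
   transform $f(x) = 1/(1+e^{-(x-0.45)/0.12})$, and patient-level 90/10
   (then 80/20 train/val) splits.
3. **Three convolutional networks** (a compact NumPy layer framework with
   manual backprop — conv/pool/upsample/skip connections, Adam, He-normal
   init):
   * *leg separation* — one 2D encoder, two decoders; loss
     $\tfrac12(\mathrm{MSE} + (1 - L_{GC}))$ where $L_{GC}$ is the mean
     normalized cross-correlation of the horizontal and vertical image
     gradients;
   * *landmark localization* — U-net regressing per-landmark Gaussian
     heatmaps with binary cross-entropy;
   * *2D–3D reconstruction* — two 2D branches whose $S/4\times S/4$ feature
     maps are replicated $S/4$ times along the third axis, averaged into a
     fused 3D feature map, then a 3D encoder/decoder with softmax over
     {background, proximal tibia}; loss = Dice + cross-entropy.
4. **Measurement** — 2D landmarks are triangulated back to 3D; the
   mechanical axis angle MA is the frontal-plane deviation of the
   $H_C\!-\!K_C\!-\!A_C$ polyline from collinearity (positive = varus); the
   tibial slope TS is the sagittal-plane angle between the fitted articular
   plateau-plane normal and the $K_C\!-\!A_C$ line (positive = posterior).
   Surfaces come from marching cubes; reconstructions are scored with Dice
   overlap and mean vertex-to-closest-surface distance.
5. **Planning** — a 12-parameter medial opening-wedge plan (hinge-axis
   position 2 + orientation 2, opening angle, cutting-plane inclination,
   plate pose 6) scored by three objectives (|MA − Φ_MA|, |TS − Φ_TS|, mean
   plate–bone gap) and searched with NSGA-II under configurable clinical
   feasibility rules.

## Worked example

```python
import numpy as np
from osteoplan import phantom as ph, metrics as mx, planner as pl, nets

params = ph.PhantomParams(varus_angle=7.0, slope_angle=8.0, voxel_spacing=2.0)
vol, truth = ph.generate_leg(params, "right")        # truth: MA 7.0, TS 8.0

label = nets.LabelVolume((vol.labels == ph.PROX_TIBIA_RIGHT).astype("uint8"),
                         vol.spacing, vol.origin)
mesh = mx.marching_cubes(label)
dm = mx.measure_deformity(mesh, dict(vol.landmarks["right"]), side="right")
print(f"measured:  MA = {dm.MA:.2f} deg, TS = {dm.TS:.2f} deg")

case = pl.PlanningCase(mesh, dict(vol.landmarks["right"]), side="right")
result = pl.optimize(case, pl.PlanningTargets(MA=0.0, TS=dm.TS),
                     ga=pl.GAConfig(population=32, generations=25, seed=1))
f = result.selected_fitness
print(f"selected plan: opening {result.selected.opening_angle:.2f} deg, "
      f"dMA {f.dMA:.3f} deg, dTS {f.dTS:.3f} deg, plate gap {f.plate_gap:.2f} mm")
```

prints

```
measured:  MA = 7.00 deg, TS = 7.84 deg
selected plan: opening 9.06 deg, dMA 0.000 deg, dTS 0.004 deg, plate gap 7.49 mm
```

The voxelized 7° varus phantom measures back at 7.00° (MA) and 7.84°
(constructed slope 8° — the plane fit on a 2 mm surface mesh carries a
fraction of a degree of error, which is exactly the TS fragility the
measurement module exposes through the plane-fit residual).  The selected
plan opens a 9.06° wedge: more than 7° because the hinge sits distal to the
knee center, so the ankle's lever arm is shorter than the full tibia — the
optimizer finds the opening that zeroes the *measured* deviation (dMA =
0.000°) while holding the slope (dTS = 0.004°) and keeping the plate near
the medial cortex.

The end-to-end pipeline (cohort → DRRs → training → evaluation → planning →
report) runs from the command line:

```bash
osteoplan run --preset desk --seed 0 --out runs/desk
osteoplan report --run-dir runs/desk
```

## Layout

| module | contents |
| --- | --- |
| `osteoplan.phantom` | parametric legs, voxelization, cohort generator |
| `osteoplan.drr` | projection geometry, DRRs, augmentation, contrast transform, heatmaps, dataset/split assembly |
| `osteoplan.nets` | NumPy autodiff engine, the three losses, the three models, training, landmark decoding, study inference |
| `osteoplan.metrics` | triangulation, MA/TS, plateau-plane fit, marching cubes, Dice, surface distance |
| `osteoplan.planner` | wedge simulation, fitness, constraints, NSGA-II, plan comparison |
| `osteoplan.pipeline` | desk experiment harness, resumable on-disk pipeline, reports |
| `osteoplan.cli` | `osteoplan` command-line umbrella |

See `docs/methods.md` for the measurement conventions, network and
optimizer details, what the phantoms do and do not emulate, and known
limitations.
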