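# carotidfem

Patient-specific biomechanics of atherosclerotic carotid arteries, end
to end on synthetic anatomies: from segmented lumen / plaque surfaces
to the stresses in the plaque under blood pressure.

Rupture of a vulnerable carotid plaque is a mechanical event, and
image-based finite-element analysis is the standard desk instrument for
estimating the stresses involved. The bottleneck is geometry: CT
angiography (CTA) shows the lumen, calcium and (poorly) lipid, but the
vessel wall and the fibrous plaque tissue have the same attenuation as
the surrounding soft tissue and cannot be segmented. This package
implements a semi-automatic CAD-style reconstruction that fills that
gap, a tetrahedral linear-elastic solver to load the result, and the
summary statistics used to compare plaques and models. It is written
for researchers in vascular biomechanics who want a fully scripted,
reproducible version of that workflow that runs without any patient
data: a seeded generator emulates the segmentation output (and,
optionally, the underlying Hounsfield-unit volume).

## The workflow

1. **Synthetic anatomy** — a carotid bifurcation (CCA/ICA/ECA) or a
   single vessel with parametric stenoses: maximal area reduction `A`,
   eccentric angular profile, and calcific / lipid components occupying
   requested fractions of the stenotic gap. The generator also emits
   the ground-truth fibrous solid that plays the role of an expert's
   manual segmentation.
2. **Threshold segmentation** (optional) — HU classes: calcific
   ≥ 800, lipid ≤ 60, contrast-enhanced blood 200–700.
3. **Wall reconstruction** — cut the lumen and the convex hull of the
   plaque components with evenly spaced planes; rebuild each section as
   a periodic cubic spline; merge lumen + plaque sections by 2D convex
   hull; enlarge each merged section radially so its equivalent radius
   `√(A/π)` equals the distal inner radius of the branch **increased by
   30%**; drop sections that show a narrowing and re-interpolate; loft.
   The wall solid is outer − inner; the *healthy lumen* is the
   shrink-back (÷1.3) of the outer sections; the **fibrous component**
   is healthy lumen − stenotic lumen − other components.
4. **Discretization** — 4-node tetrahedra, global size 0.8 mm with
   0.3 mm refinement in the plaque region; element subsets assigned by
   the *minimum-distance-vector rule*: an element belongs to a
   component when the vector from its centroid to the nearest surface
   triangle points along that triangle's outward normal (the centroid
   is on the inner side). Priority calcific > lipid > fibrous.
5. **Static FEA** — isotropic linear elasticity (E in kPa: calcific
   20000, lipid 4, fibrous 400, wall 550; ν = 0.49), uniform pressure
   ΔP = P_S − P_D on the lumen facets, vessel ends fixed
   longitudinally and circumferentially (radially free).
6. **Post-processing** — per-element von Mises stress

   σ_VM = √(½[(σ₁₁−σ₂₂)² + (σ₂₂−σ₃₃)² + (σ₃₃−σ₁₁)²] + 3(σ₁₂²+σ₂₃²+σ₃₁²))

   and the **VM₉₉** statistic: sort the fibrous elements by increasing
   stress, accumulate volume, and report the stress of the first
   element at which the cumulative volume reaches 99% of the subset
   total — together with that element's location (fibrous cap /
   calcific shoulder / bifurcation), the plaque composition
   percentages, the fibrous-cap thickness on the VM₉₉ plane, and the
   signed mutual distance between fibrous models.

## Worked example

```bash
carotidfem all --seed 1 --outdir runs/demo
carotidfem compare --seed 1 --outdir runs/demo
```

or in Python:

```python
from carotidfem import RunConfig, run_pipeline, compare_models

cfg = RunConfig(seed=1, outdir="runs/demo")   # tube-mode synthetic patient,
res = run_pipeline(cfg)                        # pressures of patient 1 (ΔP 88.5 mmHg)
print(res.report["vm99_kpa"], res.report["composition_pct"])
cmp = compare_models(cfg, res)
```

The run writes STL/VTK/CSV artifacts plus `report.json`:

```
vm99_kpa                 31.30
composition_pct          calcific 18.1, lipid 8.6, fibrous 73.3
differential_pressure    88.5 mmHg
fc_thickness_mm          0.86
```

i.e. 99% of the fibrous plaque volume carries at most ≈ 31 kPa under
the 88.5 mmHg differential load, the plaque is predominantly fibrous,
and the fibrous cap over the lipid core on the VM₉₉ plane is ≈ 0.9 mm
thick. The comparison against the generator's ground-truth fibrous
model reports both volume–stress curves and

```
vm99_pct_difference       1.01 %
distance mean ± sd        0.136 ± 0.273 mm
```

— the reconstructed fibrous model is slightly smaller than the ground
truth (positive mean: the reference lies outside it), with VM₉₉ nearly
unchanged.

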