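# myonuc

Quantitative analysis of **myonuclei in isolated skeletal-muscle fibres**:
number, morphology, spatial organization and myonuclear domain, plus
nuclear movement in cultured myotubes — the measurements used to compare
wild-type and disease-model muscle (e.g. centronuclear-myopathy mouse
models) on DAPI-stained confocal z-stacks.

Because multinucleated muscle fibres are built by myoblast fusion, the
nuclear complement sets the fibre's transcriptional capacity and,
ultimately, its size. The package measures, per fibre:

- **geometry** — cross-section area `CSA = π(w/2)(t/2)` from width w and
  thickness t, and segment volume `CSA × 100` µm³ per 100 µm;
- **counts** — nuclei per 100 µm of fibre length and per unit volume, from
  3D segmentation of the z-stack (Otsu threshold, 26-connected components,
  volume filter, geometric centroids in µm);
- **shape** — projected area, best-fit-ellipse axes, roundness
  (minor/major), maximum Feret diameter, and the sine of the angle between
  the maximum diameter and the fibre long axis (0 = aligned,
  1 = perpendicular);
- **spatial order** — 3D nearest-neighbour (NN) distance per nucleus with
  per-fibre mean/SD, and the **myonuclear domain** `MND = v/n` on 20 µm
  slices of a 375 µm segment (v = slice volume, n = nuclei in the slice);
- **movement** — greedy nearest-neighbour tracking of time-lapse movies,
  percentage of time in motion and average velocity of moving nuclei;
- **statistics** — Student/Welch t, exact Mann-Whitney U, ANOVA + Tukey
  HSD, and a sequential two-group regression comparison (slope-equality
  F-test, then elevation under a common slope — the standard ANCOVA-style
  scheme).

No public dataset accompanies the original measurements, so the package
ships a **synthetic-fibre generator** (elliptic-cylinder fibres,
surface-positioned ellipsoidal nuclei with hard-core spacing and a
configurable orientation law, PSF blur, noise, drifting nuclei in 2D
time-lapse) that provides ground truth for every stage; all validation
runs against it.

## Worked example

```python
import numpy as np
from myonuc import (SyntheticFiberSpec, generate_fiber, render_stack,
                    segment_stack, SegmentationParams, nearest_neighbour,
                    myonuclear_domain, nuclei_per_100um)

spec = SyntheticFiberSpec(seed=42)           # 400 µm fibre, 6 nuclei/100 µm
nuclei, geometry = generate_fiber(spec)
stack = render_stack(nuclei, geometry, spec)
found = segment_stack(stack, SegmentationParams())

centroids = np.array([n.centroid_3d for n in found])
nn = nearest_neighbour(centroids)
mnd = myonuclear_domain(centroids[:, 0], geometry.csa,
                        segment_length=375, fiber_length=spec.fiber_length)

print(f"nuclei found:        {len(found)} (truth: {len(nuclei)})")
print(f"nuclei per 100 um:   {nuclei_per_100um(len(found), spec.fiber_length):.2f}")
print(f"fibre CSA:           {geometry.csa:.0f} um^2")
print(f"NN distance:         {nn.nn_mean:.1f} +/- {nn.nn_sd:.1f} um")
print(f"MND:                 {mnd.mnd_mean:.0f} +/- {mnd.mnd_sd:.0f} um^3")
```

prints

```
nuclei found:        28 (truth: 28)
nuclei per 100 um:   7.00
fibre CSA:           1885 um^2
NN distance:         26.8 +/- 7.4 um
MND:                 25342 +/- 10783 um^3
```

Segmentation recovers every simulated nucleus of this fibre (this seed drew
28 from Poisson(24)); the hard-core placement yields NN distances around
27 µm, and each nucleus serves ≈ 2.5 × 10⁴ µm³ of cytoplasm, with the
slice-to-slice SD reflecting occupancy fluctuations.

Cohort-level runs (simulate → segment → measure → compare) are driven by a
YAML config:

```bash
myonuc pipeline --config run.yaml          # writes CSVs, stats, manifest
myonuc simulate --seed 7 --out fiber/      # single stack + truth table
myonuc segment --in fiber/stack.tif --out nuclei.csv
```

See `docs/methods.md` for the models, defaults and their rationale, and
known limitations.

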