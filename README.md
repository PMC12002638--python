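# nanospine

Quantification of synaptic nano-organization from multi-channel
confocal/STED image stacks — puncta co-clustering along dendrites, 3D
nanocluster segmentation, trans-synaptic PSD-95/Bassoon pairing, per-spine
nanomodule counting and VGluT1/VGluT2 input classification — together with
a synthetic-scene generator that renders ground-truth scenes through the
same imaging model, so every stage can be validated by parameter recovery
without any raw microscopy data.

It is written for neuroscientists analyzing super-resolution images of
synapses in tissue: dendritic spines of cortical pyramidal neurons carry
postsynaptic density scaffolds (PSD-95) organized into discrete
nanoclusters (NCs, ~100–200 nm) that align across the synaptic cleft with
presynaptic active-zone scaffolds (Bassoon). An aligned PSD-95/Bassoon pair
is a *nanomodule*; spines carry one to four of them, and spine volume grows
roughly linearly with their number. Vesicular glutamate transporters
distinguish the input source: VGluT1 marks corticocortical (CC) and VGluT2
thalamocortical (TC) afferents.

## The analysis in brief

- **Puncta co-clustering (confocal, 2D).** Max projections thresholded at
  the frame mean + 2 SD; puncta are 8-connected components of 3–100 px;
  co-clusters require > 1 px cross-channel overlap; densities per 10 µm of
  dendrite.
- **Nanocluster segmentation (STED, 3D).** Local-maxima seeding (ellipsoid
  5 px XY / 2 px Z) above the mean + 2 SD frame threshold, per-seed region
  growth to a Gaussian-derived local level (SD 1.5), watershed resolution
  of contested voxels, 3–20,000-voxel size gate. NCs carry
  intensity-weighted centroids (nm), volumes (µm³) and peaks.
- **Trans-synaptic pairing.** Cross-channel NC pairs overlapping by ≥ 1
  voxel, with 3D center-to-center distances and XY/Z orientation classes.
- **Per-spine analysis.** PSD-95 NCs assign to a spine only when entirely
  inside its head ROI; Bassoon associates on partial overlap or 0.2 µm
  proximity; discrete NCs must exceed the ROI-local mean + 1.5 SD; the
  nanomodule count is the number of assigned PSD-95 NCs with an aligned
  Bassoon partner; spines classify as CC/TC by VGluT overlap with a
  nanomodule-colocalization tie-break.
- **Calibration.** Line-profile FWHM fitting, nano-ruler peak-to-peak
  separation with Rayleigh dip, confocal/STED channel offset, and a pooled
  matched-filter estimator for axially spaced rulers on coarse z-grids.
- **Statistics.** Size-scaling OLS (slope ± SE, R²), ANCOVA
  homogeneity-of-slopes, two-sample Kolmogorov–Smirnov, fraction tables.

See `docs/methods.md` for the full model description, parameter defaults
and their rationale, and known estimator limits.

## Worked example

Generate a 60-spine scene at the default (basal-dendrite) conditions,
render its five channels, and run the full per-spine pipeline:

```python
import numpy as np
from nanospine import (SceneConfig, build_scene, render_channels,
                       analyze_spines, fraction_tables)

cfg = SceneConfig(n_spines=60, seed=11, exact_fractions=True)
scene = build_scene(cfg)
grids = scene.default_grids()
stacks = render_channels(scene, {ch: grids[ch] for ch in
                                 ("psd95", "bassoon", "vglut1", "vglut2")})
result = analyze_spines(stacks, grids, truth=scene)

pairs = result["pairs"]
print(f"{len(result['psd95_ncs'])} PSD-95 NCs, "
      f"{len(result['bassoon_ncs'])} Bassoon NCs, "
      f"{len(pairs)} trans-synaptic pairs")
print(f"mean trans-synaptic distance: "
      f"{np.mean([p.distance_nm for p in pairs]):.1f} nm")
tables = fraction_tables(result["spines"])
print(tables["input_class"])
print(tables["single_multiple"][["n", "percent_single", "percent_multiple"]].round(1))
```

Output:

```
567 PSD-95 NCs, 562 Bassoon NCs, 437 trans-synaptic pairs
mean trans-synaptic distance: 140.9 nm
              n    percent
input_class
CC           52  86.666667
TC            8  13.333333
              n  percent_single  percent_multiple
input_class
CC           50            70.0              30.0
TC            8            75.0              25.0
```

The segmented NC counts include the dense non-spine neuropil synapses the
generator scatters through the field (they are what anchors the
frame-statistics threshold, as real tissue structure does). The mean pair
distance recovers the configured 140 nm cleft offset; 8/60 spines (13.3%)
classify as TC, matching the configured identity proportions; and 70% of
CC spines carry a single nanomodule, matching the configured count
distribution.

The same pipeline runs from the shell:

```sh
nanospine simulate --seed 7 --n-spines 25 --out scene/
nanospine spines --dir scene/ --out spines.csv
nanospine report --spines-csv spines.csv --out report/
```

On real data, `nanospine nanocluster3d` and `nanospine puncta2d` consume
OME-TIFF stacks (voxel spacing from OME metadata or a sidecar YAML).

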