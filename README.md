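# pseudoislet3d

Quantification of 3D pseudoislet microscopy and benchmarking of
software-style segmentation presets against exact synthetic ground
truth.

Pseudoislets are in-vitro aggregates of alpha (Alpha TC1), beta-like
(INS1E) and endothelial (HUVEC) cells, seeded at a 1:9:5 ratio
(~1500 cells per microwell), that mimic a pancreatic islet of
Langerhans. Imaging them as multi-channel z-stacks raises three
recurring quantification tasks, all covered here:

* **counting** nuclei and labelled cells in 3D, where touching cells,
  depth-dependent signal loss and noise make segmentation hard;
* **localisation** of cells to the spheroid **core vs mantle**, defined
  volumetrically (e.g. the deepest 80 % or 60 % of the spheroid volume)
  or by peripheral cell layers;
* **cell–ECM co-localization** against a collagen-IV channel, scored
  object-by-object at a 0 µm surface distance (overlap/touching).

Different analysis software answers these tasks very differently. The
package encodes four complete operator chains as presets — `fiji`
(rolling ball 50 px, 3D object counter, voxel filter > 250),
`cellprofiler` (rescale, median 5, adaptive two-class Otsu), `ga3`
(rolling ball 27 µm, z equalisation, Laplacian of Gaussian σ = 2,
60 % core volume) and `imaris` (Gaussian background 60/20 µm, 6 µm
spots, surfaces with 8 µm splitting and a 353 µm² size filter, 80 %
core volume) — and measures each against ground truth with the
relative-change metric

    relative change = 100 × (count − reference) / reference  [%],

the percent over/underestimation versus a reference count. A synthetic
pseudoislet simulator provides that reference exactly: seeded cell
packing at the 1:9:5 composition, unlabelled HUVECs, fibrous ECM,
exponential depth attenuation, anisotropic PSF, smooth background, and
Poisson + Gaussian camera noise.

See `docs/methods.md` for the models, parameter meanings and numerical
choices.

## Worked example

Simulate one small pseudoislet, run two presets, and compare nucleus
counts with the truth:

```python
import pseudoislet3d as p

geometry = p.VoxelGeometry(pixel_size_xy=0.5, z_step=0.5)  # µm
cfg = p.SimulationConfig(n_cells=50, aggregate_radius=25, ecm_fibre_count=5,
                         seed=1)
stack, truth = p.simulate_dataset(cfg, geometry)

for name in ("ga3", "imaris"):
    result = p.run_preset(stack, name)
    n = result.count("nuclei")
    print(name, n, round(p.relative_change(n, len(truth)), 1))
```

prints (default noise and attenuation on):

```
ga3 43 -14.0
imaris 50 0.0
```

i.e. the LoG-plus-threshold chain misses 7 of the 50 nuclei under noise
and depth attenuation (−14 % relative change), while the spot-detection
chain recovers all 50. The same objects carry core/mantle tags
(`result.objects["nuclei"]["region"]`) and, when an ECM channel is
present, a per-cell contact table (`result.contacts`).

The benchmark over both regimes runs from the shell:

```sh
pseudoislet3d benchmark --n-datasets 9 --seed 0 --regime hard --presets all --out scratch/bench
```

writing a per-dataset × preset × channel report CSV and a summary of
mean relative changes per preset. `pseudoislet3d simulate` and
`pseudoislet3d run` expose the simulator and single-stack analysis;
stacks are multi-page TIFF, tables are CSV.

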