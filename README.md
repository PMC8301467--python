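# mandmorph

Longitudinal CT dental morphometry for continuously erupting (elodont)
dentition, built so that every stage is verifiable without animal data:

* **`mandmorph.phantom`** — paired hemi-mandible voxel phantoms with
  analytically known incisor geometry (circular-arc tube with a planar
  occlusal bevel), cheek-tooth rows, surgical defect modes (CSD,
  intermediate defect, narrow/wide complete ramus osteotomy, body defect),
  pose perturbations, and a parametric cohort simulator.
* **`mandmorph.imagecore`** — `Volume` container with physical spacing and
  origin, NIfTI/MetaImage/TIFF-stack I/O, cropping, binarization, surface
  extraction and connected components.
* **`mandmorph.register`** — rigid co-registration by maximizing mutual
  information over all overlapping voxels with Nelder–Mead simplex
  optimization (no landmarks).
* **`mandmorph.morphometry`** — occlusal-plane reorientation (total
  least-squares plane through the molar cusps) and metric extraction in
  the mid-sagittal plane of each incisor: labial / lingual / occlusal path
  lengths, occlusal inclination angle, cheek-tooth heights.
* **`mandmorph.symstats`** — left–right symmetry inference: paired-t and
  percentile-bootstrap 90% confidence intervals for the mean paired
  difference, baseline-referenced Z scores, a coverage-simulation harness
  and dot-plot reports.
* **`mandmorph.cli`** — pipeline orchestration with manifests, YAML config
  and run logs.

## Command line

```sh
# generate a rat phantom with a wide-gap ramus osteotomy
mandmorph phantom --preset rat --defect cro_wide --noise 0.05 --seed 7 --out out/

# register a follow-up scan to baseline (writes a transform JSON)
mandmorph register --fixed baseline.nii.gz --moving wk1.nii.gz --out t.json

# measure a cohort (manifest: animal_id, species, timepoint, volume)
mandmorph measure --manifest cohort.csv --out results/

# symmetry CIs, Z scores and dot plots from the metrics CSV
mandmorph stats --metrics results/metrics.csv --out results/

# end-to-end demo on generated phantoms, compared against ground truth
mandmorph demo --out demo/
```

Metrics CSV schema: `animal_id, species, side, timepoint, metric, value,
units`. Transform JSON records angles (intrinsic x–y–z, degrees),
translation (mm), rotation center (mm) and the convention string.

## Conventions

* Arrays are indexed `(x, y, z)` = (left–right, rostral–caudal,
  ventral–dorsal); the physical coordinate of a voxel is its center,
  `origin + spacing * index`; boxes are zero-based, half-open.
* Phantom intensities: background 0, bone 800, teeth 1000 (a.u.);
  binarization thresholds 500 (bone+teeth) and 900 (teeth only).
* `RigidTransform` maps moving → fixed physical coordinates,
  `y = R(x - c) + c + t`, with intrinsic x–y–z rotations about the
  stated center.
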