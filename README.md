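# vertemetrics

Quantitative validation of synthetic-CT (sCT) spine reconstructions
against reference CT, at the level a spine surgeon cares about: does the
bone surface sit where it should, and do the clinically used vertebral
dimensions survive the reconstruction?

An sCT is a CT-like bone image generated computationally from MRI. For
surgical planning and navigation only its bone segmentation matters, and
the accepted tolerance for image-guided pedicle-screw placement is about
1 mm. `vertemetrics` implements the measurement side of that validation:

* **Vertebra labeling** — binarize a scan, split it into 26-connected
  components, and name vertebrae upward from the sacrum (L5, L4, …).
* **Directional surface-distance RMSE** — masks become marching-cubes
  meshes; each source-mesh vertex gets its exact minimum distance to the
  full target mesh and the values pool as `sqrt(mean(d²))`. The metric
  is asymmetric: RMSE(A→B) ≠ RMSE(B→A), and the direction is part of
  every result. Whole-vertebra and per-part (body, pedicles, spinous
  process) variants are provided.
* **Standardized vertebra frame and ten 2D measurements** — SI from the
  superior endplate plane, RL from the pedicle-centroid line, AP = SI×RL;
  then anterior/posterior body heights, body width/length at both
  endplates, pedicle width/height at the narrowest cross-section along
  the screw-like trajectory, and the longest straight center line of the
  spinous process — all in mm from analytic mesh cross-sections.
* **Cohort statistics** — per-measurement median / std / 75th / 95th
  percentile of absolute differences, Pearson correlation, and
  condition-tag grouping with a minimum-occurrence threshold.

Because paired patient CT/sCT data are not publicly available, the
package also ships a **parametric vertebra phantom** (a first-class,
tested module): vertebrae built from closed-form solids with analytically
known ground-truth measurements, plus a degradation model (boundary
shift, correlated surface noise, blur) that emulates sub-millimeter
reconstruction error. Every stage of the pipeline is validated by
parameter recovery on these phantoms. See `docs/methods.md` for the
model and its limitations.

## Worked example

Generate a five-vertebra phantom cohort, degrade each with 0.5 mm
correlated surface noise (the sCT stand-in), measure both, and compare:

```python
from vertemetrics.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=7, n_phantoms=5, spacing=1.0,
                noise_amplitude_mm=0.5, out_dir="demo_run")
paths = run_pipeline(cfg)
print(open(paths["table"]).read())
```

which prints (excerpt):

```
section,quantity,median_mm,std_mm,p75_mm,p95_mm,n
surface_distance_mm,full,0.464981,0.042187,0.498445,0.522448,5
surface_distance_mm,body,0.487673,0.029992,0.49797,0.511582,5
surface_distance_mm,spinous,0.378401,0.062245,0.477925,0.487869,5
measurement_differences_mm,body_height_anterior,0.4564,0.34183,0.64809,0.897344,5
measurement_differences_mm,pedicle_width_L,0.162141,0.615211,0.918907,1.33729,5
measurement_differences_mm,spinous_length,0.218233,0.297458,0.350809,0.695525,5
```

Read: under 0.5 mm imposed surface noise, the median whole-vertebra
surface distance between the degraded and reference masks is ≈0.46 mm,
and the ten 2D measurements typically move by a few tenths of a
millimeter — the sub-millimeter regime in which an sCT is clinically
usable. `report.json` carries the same numbers with provenance (config
hash, seed); identical config + seed reproduces the files byte for byte.

The same stages are scriptable from the shell:

```sh
vertemetrics phantom --spacing 0.5 --out phantom/
vertemetrics label --in bone.nii.gz --out labels.nii.gz
vertemetrics surfdist --source ct_parts.nii.gz --target sct.nii.gz \
    --per-part --direction ct2sct --out surfdist.json
vertemetrics measure --labels labels.nii.gz --parts parts.nii.gz --out records.json
vertemetrics compare --ref ref_records.json --cmp sct_records.json --out report/
vertemetrics run --config run.toml
```

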