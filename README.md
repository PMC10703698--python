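# gemquant

Quantification tools for **encapsulin-based multimeric tags (GEMs)** — ~25 nm
icosahedral protein shells used as genetically encoded, individually visible
labels in cellular cryo-electron tomography and fluorescence microscopy.
`gemquant` implements the measurement side of validating such a tag:

* **Tomographic pipeline** — turn per-voxel detector probability maps into
  curated particle coordinates (threshold → lamella mask → connected-component
  size filter → curation ledger), then measure particle-to-structure surface
  distances and the volumetric fold-enrichment around a target structure.
* **Fluorescence pipeline** — overlap fractions between tag and target
  segmentations, per-grid intensity normalization, Kruskal–Wallis + Dunn
  comparison of recruitment timepoints against baseline, and single-exponential
  FRAP recovery fitting (half-life).
* **Synthetic data** — seeded generators for every input: lamella scenes with
  ground-truth particle placements, probability maps, shell density volumes,
  recruitment timecourses, FRAP traces. These make the whole analysis testable
  end to end without any microscope data.

Intended users: cryo-ET and quantitative-imaging researchers who need the
numbers behind a labeling experiment — counts, distances, enrichment folds,
recovery half-lives — with explicit accounting and reproducible seeds.

## The statistics at the core

**Surface distance.** For a particle with refined centre $x$ and a structure
segmentation $S$ (membrane, contact site), the centre distance is
$d_c(x) = \min_{s \in S} \lVert x - s\rVert$, evaluated by trilinear
interpolation of the Euclidean distance transform of $S$'s complement. The
**surface distance** subtracts the particle radius $r$ (12.5 nm for a 25 nm
shell): $d_s = d_c - r$; negative values mean the shell overlaps the
structure. "Within 50 nm" is $d_s \le 50$ nm, boundary inclusive.

**Volumetric fold-enrichment (relative labeling index).** With $n_w$ of $n$
particles within the cutoff of the structure, and the structure dilated by
50 nm and intersected with the lamella mask occupying volume fraction
$f_V = V(\mathrm{dilated} \cap \mathrm{lamella}) / V(\mathrm{lamella})$,

$$\mathrm{fold} = \frac{f_P}{f_V}, \qquad f_P = \frac{n_w}{n}.$$

A fold of 1 is the uniform-placement expectation. Pooling across tomograms
sums counts and voxel volumes before dividing.

**Curation ledger.** Detector peaks minus categorized discards plus manual
additions: $n_\mathrm{final} = n_\mathrm{peaks} - \sum_c n_c + n_\mathrm{manual}$.

**FRAP.** Traces are background-subtracted and normalized to a prebleach mean
of 1, then fitted post-bleach with
$I(t) = I_\infty - (I_\infty - I_0)\,e^{-k (t - t_\mathrm{bleach})}$;
the reported half-life is $\ln 2 / k$.

## Worked example

```python
from gemquant.synthetic import SceneConfig, ProbMapConfig, simulate_scene, render_probability_map
from gemquant.detect import DetectionParams, postprocess_probability_map
from gemquant.spatial import SpatialParams, surface_distances, summarize_distances

scene = simulate_scene(SceneConfig(
    volume_shape=(192, 192, 110), voxel_size=1.37, lamella_thickness=110.0,
    structure_kind="plane", n_bound=10, bound_distance_mean=10.0,
    bound_distance_sd=6.0, n_background=5, min_separation=40.0,
    edge_margin=20.0, seed=1))
prob = render_probability_map(scene, ProbMapConfig(blob_radius=16.4, noise_sd=0.02, seed=2))
particles = postprocess_probability_map(prob, scene.lamella_mask, DetectionParams())
records = surface_distances(particles, scene.structure_mask, SpatialParams())
print(len(particles), "particles")
print(summarize_distances(records))
```

prints

```
15 particles
  tomo_id   n    mean_nm      sd_nm
0  pooled  15  23.924103  22.310368
```

— all 15 simulated particles recovered (10 bound near the membrane plane,
5 background scattered through the lamella; the background particles pull the
pooled mean and sd of the surface distances well above the bound particles'
generating mean of 10 nm). The same stages run from the shell:

```bash
gemquant run --seed 1 --out results/demo      # full synthetic pipeline
gemquant curate --ledger my_ledger.json       # curation accounting
gemquant frap traces.csv --prebleach 10       # half-life from a trace CSV
```

The numbered scripts under `analysis/` walk through the same stages as
narrative drivers (scene simulation, detection + curation audit, distance and
enrichment statistics, recruitment kinetics, FRAP), each writing its tables
under `results/`.

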