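# flowpol

Quantitative analysis of **subcellular polarity and localized calcium
signaling in flow-aligned endothelial monolayers**.

Endothelial cells under sustained laminar shear stress elongate and align
with the flow. Their downstream end — the portion of the cell the flow
passes over last — accumulates caveolin-1-rich membrane domains, becomes
stiffer and more lipid-ordered, and hosts localized, oscillatory
TRPV4-mediated Ca²⁺ influx. `flowpol` implements the image- and
time-series analysis needed to quantify this phenotype:

- **geometry** — cell segmentation (seeded watershed on a junction channel,
  or externally provided label masks), border-cell filtering, aspect-ratio
  measurement, and partition of every cell into three **equal-length
  segments along the flow axis**: upstream, mid-body, downstream.
- **polarity** — background-subtracted mean stain intensity per segment and
  the polarity index `down / (up + mid + down)` (uniform staining gives
  1/3); Laurdan generalized polarization maps
  `GP = (I_ord − G·I_dis) / (I_ord + G·I_dis)`; nuclear marker intensity;
  one-way ANOVA + Tukey and t-test reporting.
- **clusters** — punctum/cluster detection (white top-hat + within-cell Otsu
  with a robust noise floor), per-segment **cluster index** (clustered-area
  fraction), mean cluster area, and puncta-per-cell/segment counts (PLA-style).
- **calcium** — GCaMP trace extraction per cell and per segment, optional
  photobleaching detrend, the **index of dispersion**
  `IoD = s² / mean` of each trace, activity calls (`IoD > 2`), oscillation
  peak detection, subcellular localization of activity, and population
  summaries.
- **synthetic** — a ground-truthed generator (stretched-Voronoi monolayers,
  per-segment stain enrichment, discrete puncta, oscillating GCaMP movies
  with a two-stage Poisson + Gaussian noise model) so the entire pipeline is
  testable closed-loop with no external data.
- **pipeline / CLI** — validated YAML config, stage orchestration with a
  checksummed manifest, and a `flowpol` command-line tool
  (`simulate`, `segment`, `polarity`, `clusters`, `calcium`, `summarize`,
  `all`).

The flow direction is required experimental metadata (a unit vector per
field of view); it is never inferred from morphology, and negating it swaps
every upstream/downstream quantity exactly.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
field of view (seed 20, 120 cells, 200-frame GCaMP movie at 3 s/frame):

```sh
python analysis/01_simulate_monolayer.py
python analysis/02_segment_and_measure.py
python analysis/03_polarity_analysis.py
python analysis/04_cluster_analysis.py
python analysis/05_calcium_activity.py
```

Output (abridged):

```
rendered 120 cells (73 full-length) in a 400x520 px field
watershed recovered 120 cells; mean Jaccard vs ground truth = 0.888
73 full-length cells kept for analysis; aspect ratio 4.60 +/- 0.90
73 cells; polarity index 0.600 +/- 0.001 (uniform staining would give 0.333)
per-segment intensity: upstream 100.1+/-0.5, mid_body 100.1+/-0.4, downstream 300.1+/-0.9
mean puncta/cell: 1.9 (downstream share 74%)
73 cells analyzed, 49% active (IoD > 2 in any region)
among active: 86% downstream-restricted, 11% whole-cell
per-cell agreement with ground truth: 100.0%
```

Reading: the generator renders a 3-fold downstream stain enrichment, so the
expected polarity index is 3/(1+1+3) = 0.6 — recovered exactly. Half the
cells carry an oscillation (75% of them confined to the downstream third);
the IoD > 2 rule recovers both the active fraction and the localization of
every cell. All tables land under `results/`.

Library use mirrors the scripts:

```python
import flowpol as fp

scene = fp.generate_monolayer(fp.SceneSpec(n_cells=60, seed=1))
lm = fp.filter_full_length(scene.label_map)
geos = fp.measure_geometry(lm)
profile = fp.segment_intensity_profile(scene.channels["stain"], geos[0], 10.0)
print(profile.polarity_index)
```

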