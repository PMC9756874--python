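# rewildscape

Density, habitat and landscape-change analysis for ungulate rewilding
studies.

Reintroducing large wild herbivores (roe deer, red deer) to abandoned
Mediterranean mountain landscapes raises two linked questions: how are the
reintroduced populations growing and spreading, and is their grazing —
together with livestock — slowing the forest encroachment that follows
farmland abandonment?  `rewildscape` implements the full analysis chain a
wildlife ecologist needs to answer both from camera-trap surveys and
land-cover maps, plus a synthetic-data module so every stage can be tested
without field data.

## What it computes

**Random encounter model (REM).**  Density of unmarked animals from
camera-trap encounter rates:

    D = (y / t) · π / (v · r · (2 + θ))

with `y` independent events (detections ≥ 10 min apart per camera), `t`
trap-days, `v` daily movement (km/day), and detector geometry `r` (radius)
and `θ` (angle).  Cells are sampled by a stratified design (10 × 10 km
quadrats, one 2 × 2 km cell each, four corner cameras); per-cell SEs come
from a camera-level bootstrap.

**Habitat suitability thresholds.**  Any continuous suitability raster is
discretised with the 10th-percentile training-presence threshold (p10) and
the maximum sensitivity-plus-specificity threshold (maxSSS) into
unsuitable / medium / high levels; medium + high is the suitable-area
clipping mask.

**Land-cover succession.**  Two CLC level-III epochs are overlaid, slivers
< 0.25 ha dropped, and class-3 transitions classified as *Spontaneous
Succession* (toward forest: grassland → shrub → forest) or *Inverse
Succession* (the reverse), then rasterized at 100 m.

**Association statistics.**  IDW interpolation of cell densities, cumulative
(deer + livestock) grazer density, GLMs of density vs distance from the
release point (gamma / inverse-Gaussian, canonical links), Welch's t of
grazing density in SS vs IS pixels, a χ² of SS/IS occurrence inside/outside
suitable habitat, and an elevation control restricted to patches without
deer.

**Population viability (PVA).**  A two-sex individual-based projection
(breeding → survival → aging → ceiling at K) with the two-sex extinction
threshold, plus a Leslie-matrix growth-rate oracle.

## Worked example

```python
from rewildscape import rem, pipeline

# one cell: 36 independent events over 100 trap-days, roe deer
d = rem.rem_density(y=36, t=100, v=1.99, r_m=20, theta_rad=0.87)
print(f"REM density: {d:.2f} ind/km2")

# full synthetic pipeline: landscape -> survey -> REM -> succession -> stats
res = pipeline.run_pipeline(pipeline.PipelineConfig(seed=11))
cd = res["class_density"]
print(f"SS: {cd['SS']['mean']:.2f} ind/km2 (n={cd['SS']['n']})")
print(f"IS: {cd['IS']['mean']:.2f} ind/km2 (n={cd['IS']['n']})")
```

prints

```
REM density: 9.90 ind/km2
SS: 3.76 ind/km2 (n=4241)
IS: 6.92 ind/km2 (n=13498)
```

The first number converts a trapping rate of 0.36 events/day into an
absolute density of 9.9 individuals per km².  The second pair is the
pipeline recovering the effect it planted: epoch-2 land cover was simulated
so that grazing suppresses forest encroachment, and accordingly the pixels
where succession advanced (SS) carry a lower cumulative grazer density
(3.76 ind/km²) than the pixels where the landscape opened (IS,
6.92 ind/km²); the accompanying Welch test in `res["welch_ss_vs_is"]` is
strongly significant.  The same run reports per-species cell densities,
suitability areas, the GLM distance fits and the PVA trajectory; with
`out_dir` set it writes all rasters, CSVs and a `results.yaml`.

The same stages are available from the shell:

```
rewild all --seed 11 --out run1
rewild rem --detections det.csv --deployments dep.csv --species roe_deer
rewild suit --raster suitability.asc --p10 0.221 --maxsss 0.559
rewild pva --config examples/roe_deer_pva.yaml --years 19 --iterations 100
```

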