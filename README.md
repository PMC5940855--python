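# spherodyn

Spatiotemporal quantification of tumor-spheroid dynamics from time-lapse
microscopy.

Spheroids — 3-D multicellular aggregates embedded in a matrix — are a
standard in-vitro model for tumor growth and invasion. Time-lapse imaging of
spheroids captures behaviors that static snapshots miss: chain-like invasive
branches elongating over hours, single cells detaching and migrating away,
and steady growth of the proliferative core. `spherodyn` turns such
recordings into quantitative, statistically comparable measurements. It is
aimed at cell biologists running spheroid invasion assays (e.g. comparing
leader-like, follower-like and parental phenotypes, or drug vs. control)
who need objective, repeatable readouts instead of manual outlining.

## What it does

1. **Preprocessing.** Per-frame z-stacks are collapsed with a
   standard-deviation projection, `I_p(x, y, t) = σ_z[I(x, y, z, t)]`, which
   rescues structure from weakly illuminated focal planes, then smoothed with
   a separable 3-D Gaussian in space and time.
2. **Segmentation.** Foreground is delineated by an exact, energy-minimizing
   binary graph cut over the whole (x, y, t) volume:

       E(L) = Σ_i U_i(L_i) + Σ_(i,j) λ_(i,j) · exp(−(I_i − I_j)² / 2σ_c²) · [L_i ≠ L_j]

   with two-Gaussian intensity unaries and a 6-connected neighborhood
   (4 spatial + 2 temporal neighbors); solved globally by max-flow/min-cut.
   Temporal edges make the segmentation coherent across frames; a per-frame
   2-D mode is available for long imaging intervals.
3. **Morphometry**, per frame: area, Crofton perimeter, eccentricity,
   boundary complexity `P²/(4πA)` (1 for a circle), core radius (largest
   inscribed circle at the centroid), invasive radius (centroid-anchored
   enclosing circle), branch count (terminal endpoints of the pruned
   skeleton), single-cell count (small disconnected islands), and intensity
   statistics.
4. **Dynamics.** Each feature's time course is fitted by least squares with
   `y = a·t + b`, `y = a·t² + b·t + c`, and `y = a·e^(b·t)`; adjusted R²
   ranks the models, and model parameters are compared across conditions
   with Student's t-test (two groups) or one-way ANOVA (more).
5. **Reporting.** Masks, boundary overlays with timestamps, per-replicate
   feature CSVs, model and statistics CSVs, and mean ± 95% CI time plots.

A fully parameterized synthetic spheroid generator (growing core, quadratic
branch elongation, detaching cells, illumination falloff, photobleaching,
noise) provides exact ground truth, so the entire pipeline is testable with
no external data.

## Worked example

```python
from spherodyn import RunConfig, run_pipeline, write_synthetic_experiment

# six synthetic recordings: 3 compact "follower" and 3 branching "leader"
# spheroids, 30 frames at 10-minute intervals, 5 focal planes, moderate noise
write_synthetic_experiment("experiment", {"follower": 3, "leader": 3}, seed=7)

cfg = RunConfig(input_root="experiment", output_root="results", z_planes=5)
result = run_pipeline(cfg)

print("best models:", result.best_models)
print(result.stats_df.to_string(index=False))
```

prints (abridged):

```
best models: {'area_px2': 'quadratic', 'perimeter_px': 'quadratic', ...,
              'core_radius_px': 'quadratic', 'invasive_radius_px': 'quadratic'}
           feature     model parameter   test   statistic      p_value
          area_px2 quadratic         a t_test  -59.444645 4.796025e-07
    core_radius_px quadratic         b t_test  -43.791969 1.625793e-06
invasive_radius_px quadratic         a t_test  -37.512639 3.015686e-06
      eccentricity quadratic         a t_test    2.340509 7.933416e-02
```

Reading the output: area grows quadratically for both phenotypes (the core
radius grows linearly, so area ∝ r(t)²), but the quadratic coefficients
differ sharply between conditions (p ≈ 5·10⁻⁷) — leaders expand faster. The
invasive radius separates the phenotypes through its curvature term, driven
by accelerating branch elongation, while eccentricity barely discriminates
(p ≈ 0.08). Per-replicate outputs (masks, overlays, `features.csv`,
`parameters.csv` echoing every setting) land under `results/<condition>/
<replicate>/`, summary CSVs and figures under `results/`.

The same pipeline runs from the shell:

```sh
spherodyn simulate --output experiment --replicates 3 --seed 7
spherodyn run --input experiment --output results --z-planes 5
```

## Layout

- `src/spherodyn/synthetic.py` — ground-truthed synthetic generator + presets
- `src/spherodyn/io_experiment.py` — folder discovery, image I/O, CSV output
- `src/spherodyn/preprocess.py` — std-projection, Gaussian smoothing
- `src/spherodyn/segmentation.py` — spatiotemporal graph cut
- `src/spherodyn/morphometry.py` — per-frame feature panel
- `src/spherodyn/dynamics.py` — model fitting, selection, statistics
- `src/spherodyn/pipeline.py`, `cli.py`, `report.py` — driver, CLI, figures
- `docs/methods.md` — models, parameters, numerical choices, limitations
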