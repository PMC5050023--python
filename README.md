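# ktswivel

Geometry and statistics of human sister-kinetochore pairs from two-colour
3D fluorescence microscopy: intra-kinetochore distances (Δ3D and its 2D/1D
projections), inter-sister distances, the *swivel* of the outer kinetochore
domain about the sister–sister axis, chromatic-shift registration between
channels, sub-voxel spot localization in rendered stacks, and the exact
projection theory that explains why 1D distance measurements conflate
kinetochore stretch with rotation.

It is written for mitosis researchers analysing paired inner/outer
kinetochore markers (e.g. eGFP-CENP-A with Ndc80-tagRFP), and for anyone
who needs a fully synthetic, ground-truth-carrying test bed for such
pipelines.

## The measurements

In a right-handed plate frame (x̂ normal to the metaphase plate), for each
kinetochore of a pair:

- **Δ3D** = |outer − inner|, with components Δx, Δy, Δz and a 100 nm |Δz|
  quality filter; **Δ2D** is the in-plane projection.
- **Δ1D** = ½(d_y,2 − d_y,1), half the difference of the outer–outer and
  inner–inner in-plane inter-sister distances — signed, negative when the
  outer domains rotate inside the inner markers.
- **y-swivel** ϑy = 180° − cos⁻¹((d_y² + Δy² − ε_y²)/(2 d_y Δy)), from the
  triangle formed with the sister's inner marker, signed by the side of the
  sister axis; **ϑ3D**, **ϑz**, **twist** and **ϑkMT** follow the same
  conventions.
- Exact closed form and first-order approximation linking Δ1D to
  (Δy, ϑy) of both sisters:
  Δ1D ≈ ½(Δy,1 cos ϑy,1 + Δy,2 cos ϑy,2), with a worst-case error of
  exactly 10% of Δ at Δ/d = 0.1 (attained at cos ϑ = −0.1).

The statistical layer provides median ± bootstrap SE summaries,
Mann-Whitney U (exact enumeration for tiny samples), a two-sided variance
F test, a seeded permutation test of Pearson correlation with Gaussian-tail
extrapolation for far-tail p-values, polynomial curve/sheet fits of swivel
against plate position and thickness, displacement autocorrelation, and
rose-plot histogram tables.

## Worked example

Simulate two conditions with identical 98 nm intra-kinetochore magnitude
but different swivel dispersions (56.4° vs 89.5°), then measure and compare:

```python
from ktswivel import SimulationConfig
from ktswivel.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(conditions={
    "untreated":  SimulationConfig(n_pairs=600, swivel_sd=56.4, seed=101),
    "nocodazole": SimulationConfig(n_pairs=600, swivel_sd=89.5, seed=202),
}, seed=7, n_boot=300)
summary = run_pipeline(config)
u = summary["conditions"]["untreated"]
n = summary["conditions"]["nocodazole"]
print(f"delta3d median: {u['delta3d_median']:.1f} vs {n['delta3d_median']:.1f} nm")
print(f"delta1d median: {u['delta1d_median']:.1f} vs {n['delta1d_median']:.1f} nm")
print(f"delta3d Mann-Whitney p = {summary['tests']['delta3d_mann_whitney_p']:.3f}")
print(f"delta1d Mann-Whitney p = {summary['tests']['delta1d_mann_whitney_p']:.2e}")
```

prints

```
delta3d median: 98.0 vs 98.0 nm
delta1d median: 44.1 vs 18.4 nm
delta3d Mann-Whitney p = 0.487
delta1d Mann-Whitney p = 3.49e-41
```

Both ensembles have *exactly* the same 3D inner-to-outer distance; only the
rotational freedom differs. The 1D projected measurement nevertheless drops
by more than half and separates the conditions at p < 10⁻⁴⁰ — projection artefacts
masquerading as structural change, which is the effect the package
quantifies.

The same stages are scriptable from the shell:

```sh
ktswivel simulate --config cfg.yaml --seed 5 --out-dir out/
ktswivel measure out/truth.csv --out out/measurements.csv
ktswivel stats out/measurements.csv --column y_swivel --out out/stats.json
ktswivel run --config pipeline.yaml --out-dir out/
```

plus `fitspots` (OME-TIFF → spot table), `shift` (dual-label calibration →
chromatic shift) and `trajectory` (oscillations with P/AP phase labels).

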