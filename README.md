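# gastroquant

Quantification pipeline for *Caenorhabditis elegans* gastrulation time-lapse
imaging. During gastrulation, internalising cells (the endodermal precursors
Ea/Ep, later others) exhibit pulsatile apical actomyosin contractions;
neighbouring cells extend centripetally and seal over them as multicellular
rosettes, while the surface monolayer thins and spreads through coplanar cell
divisions. `gastroquant` implements the measurements such a study needs, as a
tested, reusable library with a command-line interface:

- **profiles** — line-profile fluorescence (mean ± SD across parallel lines),
  kymographs, maximum-intensity projection and frame superimposition.
- **foci** — detection and greedy nearest-neighbour tracking of cortical
  myosin foci, contraction-event counting from converging focus streams, and
  bleb-event extraction from cell-outline series.
- **coupling** — the time-shifted relationship between integrated local
  contraction intensity and extension-tip advancement: a lag scan reporting
  the r² of extension-position-vs-lagged-intensity per candidate lag
  (extension advancement lags contraction by ~20 s in this system, consistent
  with a viscoelastic cortex).
- **spread** — measured circumferential tissue spread from cross-sections,
  and the coplanar-division theory: one symmetric division at spindle angle θ
  to the A-P axis multiplies a cell's circumferential extent by
  g(θ) = √(4 sin²θ + cos²θ), with g(0°) = 1, g(36°) ≈ 1.427, g(90°) = 2.
- **tracks** — migration-path smoothing (moving average, width 5), pairwise
  left/right movement correlation matrices (displayed clipped to ±0.8),
  displacement as % of embryo length, and midline symmetrisation angles.
- **morpho** — apical/basolateral axis ratios and flatness, covering-fraction
  kinetics by exact polygon clipping, and the ordinary least-squares
  regression of bleb area on anterior translocation.
- **synth** — a seeded synthetic-data generator producing cortex movies,
  coupled traces, dividing lineages on an ellipsoidal embryo and bleb series,
  each with ground truth, so the whole pipeline runs and is validated with no
  acquisition data.

## Worked example

Generate a synthetic embryo and quantify the contraction–extension coupling:

```python
from gastroquant.synth import SynthConfig, generate_coupled_traces
from gastroquant.coupling import normalize_traces, lag_scan

cfg = SynthConfig(seed=42)            # 2 s frames, 20 s coupling delay
i, e = generate_coupled_traces(cfg)   # intensity (AU) and tip position (um)
ni, ne = normalize_traces(i, e)       # intensity / max; extension / final
scan = lag_scan(ni, ne, max_lag=60.0)
print(f"peak lag: {scan.peak_lag:g} s  r^2 at 20 s: {scan.r2_at(20.0):.3f}")
```

prints

```
peak lag: 18 s  r^2 at 20 s: 0.988
```

i.e. extension advancement is almost perfectly explained by contraction
intensity shifted by the generator's 20 s transport delay (the discrete scan
may land on a neighbouring 2 s grid point for a single noisy replicate, as
here; the median over replicates is 20 s).

The same from the shell, plus a full pipeline run:

```sh
gastroquant synth --seed 42 --out demo
gastroquant couple demo/traces.csv --max-lag 60
gastroquant run --seed 1 --out demo_run    # all stages, deterministic
```

`demo_run/` then contains `lag_scan.csv`, `spread.csv` (measured vs
theoretical circumferential spread and their residuals), `lr_correlation.csv`
(the L/R movement correlation matrix), `foci_tracks.csv`,
`bleb_regression.csv` and the generated inputs, every CSV carrying a
provenance header (version, seed, parameter hash).

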