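# eegwmnet

Graph-theoretic analysis of EEG functional networks during visual
short-term-memory binding, across the adult lifespan.

Healthy aging reorganizes task-related brain networks: integration
(characteristic path length, global efficiency, betweenness, hubness),
segregation (clustering, modularity) and small-world organization all
drift with age, differently in different frequency bands. `eegwmnet`
implements the full analysis chain for a 30-channel 10–20 montage at
256 Hz, from epoched voltages to age-effect statistics, together with a
synthetic-data generator so the whole chain is testable without any
recorded data. Optionally it reads real epoched EEG from EDF files plus a
delimited subject table.

## The analysis

1. **Epoching and artifact rejection.** Continuous recordings are cut
   into 1000-ms test-locked epochs (256 samples). An epoch is rejected if
   any channel (a) exceeds ±70 µV, (b) steps faster than 50 µV/ms,
   (c) ranges more than 50 µV within any 200-ms window, or (d) ranges
   less than 0.5 µV within any 100-ms window.
2. **Connectivity.** The weighted phase lag index
   (wPLI = |E[Im X<sub>ij</sub>]| / E[|Im X<sub>ij</sub>|], with X the
   cross-spectrum of the analytic signals) is estimated at centre
   frequencies 1–48 Hz with 1-Hz bandwidth, then averaged into delta
   (0.5–3.5), theta (4–7.5), alpha (8–13.5), beta (14–29.5) and gamma
   (30–48.5 Hz) band matrices. wPLI is insensitive to zero-lag
   (volume-conduction) coupling.
3. **Graphs.** Each 30×30 band matrix is proportionally thresholded —
   the top 55% of the 435 edges is retained (239 edges) — and weighted
   metrics are computed on distances d = 1/w: CPL, global efficiency,
   betweenness, Onnela clustering, seeded Louvain modules, within-module
   degree z and participation coefficient (the continuous "hub value").
   Small-worldness uses the binarized graph against a matched ring
   lattice: γ = L/L<sub>ref</sub>, λ = C/C<sub>ref</sub>, σ = γ/λ (a
   conventional Watts–Strogatz mode with a degree-preserving randomized
   reference is also available; results are tagged with the convention).
4. **Statistics.** Every outcome is modelled as y = β₀ + f(age) + ε with
   f a penalized cubic regression spline (basis order 10 for
   cognitive/behavioural outcomes, 12 for graph metrics), smoothing
   chosen by REML; the report carries the intercept (estimate, SE, t, p)
   and the smooth (EDF, reference df, F, approximate p). Metric–cognition
   associations are screened with partial Pearson correlations
   controlling for age, Benjamini–Hochberg FDR within metric family, and
   a moderate-effect filter |r| > 0.400.

## Worked example

```bash
eegwmnet run --seed 1 --outdir demo --n-subjects 12
eegwmnet report --outdir demo
```

or in Python:

```python
from eegwmnet.pipeline import RunConfig, run_pipeline
cfg = RunConfig(seed=1, n_subjects=12, bands=("alpha", "theta"), outdir="demo")
run_pipeline(cfg)
```

With this seed the simulated cohort of 12 subjects (ages stratified over
20–81) keeps 94.8% of its epochs after artifact rejection, and
`demo/gam_table.csv` contains, among others:

```
outcome            edf    ref_df  f_value  p_value
accuracy_shape     1.000  1.000   84.81    0.000003
rt_shape           4.314  5.219   34.69    0.000113
binding:alpha:cc   1.000  1.000    6.21    0.031930
binding:theta:cc   1.000  1.000    0.15    0.702309
```

Shape-condition accuracy declines with age and reaction time rises
non-linearly (EDF > 4); alpha-band clustering — whose underlying
synthetic coupling is built to weaken with age — shows a significant
age effect while theta clustering, generated age-stable, does not. The
correlation screen (`demo/correlations.csv`) reports one pair at this
small n: binding alpha clustering vs MMSE, r = 0.894, q = 0.008, which
survives both the FDR and the |r| > 0.400 filter.

Every output of a run lives under `--outdir`: `cohort.csv`, one EDF +
JSON sidecar per subject/condition, `rejection_report.csv`, band-matrix
CSVs with a JSON manifest, tidy `metrics.csv`, `table1.csv`,
`gam_table.csv`, `correlations.csv` and a `manifest.json` with config
hash, per-stage wall times and file checksums. Runs are deterministic
per seed.

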