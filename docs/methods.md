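# Methods

## Scope and data model

The package analyses epoched multichannel EEG recorded during a visual
short-term-memory binding (VSTMB) task with two conditions ("shape" and
colour–shape "binding"). The fixed montage is 30 channels of the
international 10–20 system; epochs are 1000 ms at 256 Hz, time-locked to
the test display. A session presents 96 stimuli, 48 per condition, with
the probe equal to the study display with probability 0.5.

All quantities flow through five stages — synthesis (or EDF import),
artifact rejection, wPLI connectivity, thresholded graph metrics, and
age-effect statistics — with file handoffs (EDF/CSV/JSON) between
stages so each is independently runnable and auditable.

## Synthetic cohorts and signals

**Cohort.** Ages are stratified-uniform over [20, 81] (the age axis is
split into n equal strata with one uniform draw each), so even n = 39
covers the range without gaps. Cognitive and behavioural outcomes are
piecewise-linear-with-hinge mean curves of age plus Gaussian noise, with
the hinge locations encoding the qualitative aging literature the
pipeline is meant to detect: task accuracy declining after ~50, language
peaking near 45, visuospatial ability dropping sharply after 70,
reaction time slowing late in life. The curve parameters are exposed
(`synth.cognition_means`), so recovery tests can compare against exact
ground truth; with the noise scale at 0 the generator returns the means
exactly. MMSE is clipped to [27, 30] and BDI to [0, 17] because the
cohort emulates *included* subjects (the screening rule excludes
MMSE < 27 or BDI > 17).

**Signals.** Each channel is a sum over the five canonical bands of a
narrowband oscillator — carrier at the band centre (2, 6, 10, 20,
38 Hz), uniform initial phase, slow random-walk phase drift (step s.d.
0.03 rad/sample) — plus 1/f noise scaled to a configured
signal-to-noise ratio (default 1.5). Band amplitudes (4, 3, 5, 2,
1.2 µV) follow a 1/f-like profile and keep clean epochs well inside the
±70 µV rejection bound.

**Coupling.** A coupling profile lists, per band, coupled channel pairs,
a phase lag δ ∈ (0, π) ∪ (−π, 0), and a strength curve g(age) ∈ [0, 1]
(constant, linear, or changepoint-with-ramp). On a fraction g of epochs
the target channel's band phase track is replaced by the source track
shifted by δ (phase-resetting coupling); otherwise the channels are
independent. This design gives analytically predictable wPLI limits —
g = 0 yields the estimator's null level, g = 1 yields wPLI → 1 — which
is what makes the estimator testable. The default profile couples
posterior alpha pairs with strength declining linearly from 0.8 at age
20 to 0.25 at 81 (the effect the analysis is designed to detect), with
age-constant coupling in the other bands. Because no per-band
connectivity strengths are reported for the real sample, these effect
sizes are calibration choices of the generator, not estimates of any
study's ground truth.

**Epoch counts.** Artifact-free epochs per condition are drawn from a
truncated normal (mean 38, s.d. 6, minimum 20), matching the epoch
numbers typical of this paradigm. A configurable fraction of epochs
(default 5%) is contaminated with suprathreshold artifacts so the
rejection stage operates on realistic input.

**What the generator does not emulate.** Ocular/muscle components (the
ICA step of real preprocessing is out of scope), volume conduction and
a realistic leadfield, spatially correlated noise, electrode drift,
behavioural response processes, and any true link between the coupling
profile and the cognitive scores beyond their shared age dependence.
Passing tests therefore demonstrate that the pipeline recovers what the
generator injects at realistic noise levels — not that it would recover
effects of a given size from real recordings.

## Artifact rejection

Four criteria are evaluated per epoch and channel: (a) |v| > 70 µV at
any sample; (b) adjacent-sample step above 50 µV/ms — the per-sample
limit is 50 × (1000/256) ≈ 195 µV, since the criterion's unit is µV/ms;
(c) max − min > 50 µV within any dense sliding 200-ms window
(51 samples); (d) max − min < 0.5 µV within any 100-ms window
(26 samples). Window lengths are rounded to the nearest sample count and
only windows fully inside the epoch are evaluated. Rejection is
whole-epoch and all-channels (no interpolation); the original procedure
was semi-automatic with human review — this implementation is fully
automatic and logs every verdict instead. Zero surviving epochs is an
error naming the subject and condition, because downstream spectra would
be undefined.

## wPLI estimation

For channels i, j: each epoch is band-passed with a 4th-order zero-phase
Butterworth filter of half-width 0.5 Hz around the centre frequency, the
analytic signal is taken by Hilbert transform, 25% of samples at each
epoch edge are discarded (filter transients), and

wPLI_ij = |E[Im X_ij]| / E[|Im X_ij|]

with the expectation pooled over all retained time points and epochs.
If the denominator is exactly zero the value is defined as 0 with a
logged note. This is the standard (not debiased) estimator. Whether the
expectation should pool within-epoch time points or use one
cross-spectral value per epoch is not fixed by the estimator's
definition; pooling is the implemented and documented choice.

Two numerical caveats are intrinsic. At centre frequencies ≤ 3 Hz a
one-second epoch holds fewer than four cycles; pooling across epochs is
what makes the expectation meaningful there, and a warning is logged
once per frequency. And with a 1-Hz bandwidth the analytic signal's
coherence time is on the order of the epoch length, so the effective
sample count is roughly the number of epochs, not epochs × samples: at
60 epochs the single-pair null distribution has mean ≈ 0.11 and 99th
percentile ≈ 0.31, and the *maximum* over all 435 pairs of a null
matrix averages ≈ 0.47. Tests and users should judge narrowband wPLI
values against this finite-sample null (the test suite carries a
permutation-null calibration), never against zero.

Spectra run over integer centres 1–48 Hz; band matrices are entrywise
means over the centres strictly inside each band's edges: delta {1,2,3},
theta {4..7}, alpha {8..13}, beta {14..29}, gamma {30..48}.

## Graph construction and metrics

The top floor(0.55 × 435) = 239 of the ranked upper-triangle weights are
retained (ties broken by ascending row, column for determinism), the
rest zeroed. Weighted metrics are computed on the thresholded weighted
graph with edge distances d = 1/w: all-pairs Dijkstra for CPL (mean over
connected ordered pairs, with a disconnection flag) and global
efficiency (mean of 1/d, zero for disconnected pairs — robust to
disconnection by construction); betweenness with fractional counting
over equal-cost paths, normalized by (n−1)(n−2)/2; Onnela
geometric-mean clustering with weights rescaled by the global maximum
(degree < 2 ⇒ 0); seeded weighted Louvain communities with modularity Q;
within-module strength z-scores (0 for singleton or zero-variance
modules); and the participation coefficient P_i = 1 − Σ_m (s_im/s_i)²
(P = 0 for zero-strength nodes), with a reporting flag at P > 0.3.
The continuous "hub value" analysed is the participation coefficient
and the "module value" is the within-module z — both are
operationalization decisions, stated here because nodewise hub/module
values admit more than one definition.

**Small-worldness.** σ alone is computed on the *binarized* graph so it
is commensurate with its unit-weight reference. The default convention
follows the definitions this analysis specifies against a ring-lattice
reference with matched node and edge counts (k = floor(m/n) neighbours
per side, remainder placed at distance k+1 from node 0 upward):
γ = L/L_ref, λ = C/C_ref, σ = γ/λ. Note this inverts the usual
Watts–Strogatz convention, where γ is the *clustering* ratio against a
*randomized* reference; the conventional mode (`watts_strogatz`,
degree-preserving rewiring, 10 seeded realizations averaged) is provided
and every result is tagged with the convention used, so the two are
never mixed silently.

## Age-effect statistics

**GAM.** y = β₀ + f(age) + ε, with f a natural cubic regression spline
through k knots at quantiles of age, parameterized by its values at the
knots, penalized by the exact integrated squared second derivative, and
centred (sum-to-zero over the data) for identifiability. Basis order
k = 10 for cognitive/behavioural outcomes and k = 12 for graph metrics.
The smoothing parameter minimizes the Gaussian restricted likelihood
(REML), optimized over log λ by grid-plus-bounded refinement; the
penalized solve uses the augmented-QR form for numerical stability at
extreme λ. Reported: intercept estimate, SE, t and p (Bayesian
covariance, residual df = n − total EDF); smooth EDF (trace of the
influence matrix minus one, so EDF = 1 means the penalty has shrunk the
fit to a straight line); reference df (the alternative EDF
2tr(F) − tr(F²) − 1); and an approximate F-test of the smooth — a
rank-based Wald statistic on the spline coefficients using a
pseudo-inverse of their covariance at rank equal to the reference df,
with the fractional part down-weighting the last eigendirection. On a
shared dataset this implementation reproduces R mgcv's
`gam(y ~ s(age, bs="cr", k=12), method="REML")` EDF, reference df,
intercept and SE to three decimals and F to within 0.5% (the test suite
runs that comparison); its simulated null rejection rate at n = 39,
k = 12 is 0.042 at α = 0.05. Exact equality with any particular mgcv
version's p-values is not promised, since the smooth-test fine print
differs across versions.

**Correlation screen.** Partial Pearson correlation of metric and score
controlling for age (residuals from separate linear regressions;
p from t = r√((n−3)/(1−r²)) on n − 3 df). Candidates are restricted to
metrics whose GAM smooth p < 0.05; Benjamini–Hochberg FDR is applied
within each metric family (integration | segregation | global — the
family structure is a configurable analysis choice, recorded in the
output); a pair is reported when the adjusted p < 0.05 *and*
|r| > 0.400. Exact linear dependence on the covariate (zero residual
variance, detected at relative tolerance 1e-10) is a degenerate-input
error.

## Problem sizes used by the validation suite

Simulation-based checks are run at desk scale, chosen once as the
package's configuration for these experiments: GAM type-I calibration
uses 500 null replicates at n = 39 and power 200 replicates;
permutation-null calibration uses 100 independent pairs × 200
permutations; the end-to-end recovery experiment (age-declining alpha
coupling vs an age-stable theta control, full chain from epoch synthesis
through wPLI, thresholding, clustering and GAM) uses 30 replicates of
100 subjects with 20 epochs each, one condition, alpha + theta bands,
and requires the alpha effect to be flagged and the theta control not
flagged in ≥ 85% of replicates.

## Known limitations

- The EDF writer emits plain EDF (one data record per epoch); EDF+
  annotations and discontinuity markers are not written.
- Louvain partitions on near-degenerate modular structure can differ
  across platforms despite seeding if networkx changes its internal
  iteration order; the seed and package version are recorded in the run
  manifest for that reason.
- CPL on a disconnected thresholded graph is the mean over connected
  pairs with a flag; at 55% density on 30 nodes disconnection is rare
  but not impossible.
- The GAM assumes Gaussian errors and a single smooth of age; no
  sex/education covariates, no mixed effects.
- Reaction-time and accuracy data are generated marginally; no
  drift-diffusion or speed–accuracy coupling is modelled.
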