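# Methods

This note records the models, the defaults and the judgment calls behind
them — what a maintainer needs to know before changing anything.

## 1. Untargeted metabolome arm

### Missingness filter

A peak is removed only when its missing fraction **strictly exceeds**
the threshold (default 0.5) **in every group**.  The rationale: a
metabolite well observed in one group but absent in the other is
biologically informative (presence/absence is itself a group
difference), so the remove-only-if-bad-everywhere reading is the
default; the stricter any-group rule is available via `mode="any"`.
The boundary case (exactly 50% missing per group) is retained.  Samples
are never removed.

### Imputation

`half_min` (default) replaces missing entries with half the observed
per-metabolite minimum — the common left-censoring surrogate for
LC-MS data, where missingness is abundance-biased.  `min` and `zero`
exist for sensitivity analysis.  A metabolite with no observed value at
all cannot be imputed and raises an error pointing at the filter.

Note a real cost measured during calibration: at 10% missingness,
half-min imputation inflates within-group variance enough to drop
t-test sensitivity for planted 2-log2-unit effects from ~0.96 to ~0.6
at n = 6/group.  This is a property of censoring surrogates generally,
not a bug; the recovery benchmark in the test suite therefore runs on
complete data, and users with heavy missingness should expect reduced
power.

### Scaling and PCA

Unit-variance (auto) scaling with mean-centering is the default for
both PCA and OPLS-DA — the standard chemometrics choice; Pareto and
no-scaling are config options.  Constant columns pass through with
scale 1 rather than dividing by zero.  PCA is a plain SVD of the scaled
matrix; component signs are fixed by the largest-|loading|-positive
convention so score plots are reproducible across platforms.

### OPLS-DA

Single response y = ±1 (low = −1 by the matrix's `group_order`),
centered.  Orthogonal components are extracted by the standard
projection-to-latent-structures filter (weight from Xᵀy; the
y-orthogonal part of the loading defines the orthogonal weight; X is
deflated), then a one-predictive-component PLS is fitted on the
filtered matrix.  Defaults: `n_orth = 1` (the convention for two-class
models with one predictive component), configurable.

**Q²** uses stratified k-fold CV (default 7-fold) in which *everything*
— centering, scaling, orthogonal filtering, fit — is re-estimated
inside each training fold; PRESS is compared against deviation from the
full-data label mean.  A stratified fold needs at least one member of
each class, so the fold count is capped at the smaller group size (6
folds at the study design of n = 6/group); the cap is logged.  With
metabolites ≫ samples, R²Y on training data is near 1 almost always
(including under the null); Q² and the permutation test carry the
actual evidence.  Q² can legitimately be negative.

**Permutation validation** (default 200 permutations) shuffles group
labels and refits the full model including CV.  Empirical p-values use
the add-one correction (1 + #{perm ≥ obs})/(n + 1), which is valid
(conservative) under the null.  Below 20 permutations a warning is
recorded since p-resolution is then worse than 0.05.

### VIP and SDM selection

VIP is computed over the predictive component only (whether the
upstream vendor platform used total components is unknowable; the
predictive-only choice is the documented one here):
VIP_j = √(p · w_j²/‖w‖²).  The algebraic identity mean(VIP²) = 1 is
asserted in tests to 1e-10.

SDM rule: **selected ⇔ VIP > 1 AND p < 0.05**, both strict, with
two-sided pooled t-tests run on log2 intensities (multiplicative data;
a raw-scale flag exists).  Direction comes from the sign of the log2
fold change (high over low), so up + down = selected by construction.
The class summary z-scores each selected metabolite across samples
(mean 0, sd 1) and orders rows by class — the heatmap substrate — plus
per-class up/down counts.

## 2. Quantified panel arm

Pooled-variance Student's t-test by default; df = n_low + n_high − 2
(14 at n = 8/group).  Welch is behind a flag — the published df of 14
at that design implies the pooled test.  The t sign follows the
low-minus-high convention (a metabolite higher at high elevation gets a
negative t); |t| is reported alongside and both appear in output
headers.  Percent change uses the low group as denominator.  p-values
are exact two-sided t probabilities; note that printed p-values in the
motivating literature are not always internally consistent with their
t and df, and no attempt is made to reproduce any specific printed p.

Assumption checks are advisory: Shapiro–Wilk per group and a two-sided
F-ratio test for variance homogeneity (the named checks do not pin
specific tests; these are the conventional choices).  A zero-variance
group is reported as a degenerate condition, not an exception, and
Shapiro on a constant vector returns NaN with the flag passing (no
evidence against normality is obtainable).

## 3. Flux arm

### The network

The packaged default (`data/cmp_network.json`) encodes a 10-reaction
CMP skeleton: glycolysis r1 (glucose→G6P) through r6 (PEP→pyruvate)
with the F6P→2 GAP split, a G6P→pentose-phosphate branch (r3), lactate
fermentation (r7), pyruvate dehydrogenase (r8), TCA entry (r9) and
ketogenesis (r10).  Six intermediates are pseudo-steady-state nodes
(G6P, F6P, GAP, PEP, pyruvate, acetyl-CoA); glucose, lactate, β-HB and
NADH are boundary-measured; ribose-5-phosphate and the TCA end-products
are unconstrained sinks.

Cofactor placement is a deliberate modeling choice: NADH is produced by
the GAPDH step (r5) and consumed by lactate dehydrogenase (r7) and
β-HB dehydrogenase (r10), while mitochondrial NADH turnover (r8, r9) is
treated as not exchanged with plasma.  With NADH also produced in
r8/r9, the determined system forces a negative TCA flux for any
plasma-like concentration ordering (glucose ≫ lactate ≫ β-HB ≫ NADH);
the chosen placement yields an all-positive solution in that regime and
makes net plasma NADH production equal the TCA entry flux exactly.
NADH is a boundary-measured net-accumulation node, not a
pseudo-steady-state node.  The network is a data file: replace it with
any other topology (JSON or TSV) without touching code.

### Concentration→rate proxy

The mapping from plasma concentrations to relative rates is modeled as
proportionality: the net production rate pinned for a measured
metabolite m is b_m = ±scale·C_m/C_ref with scale = 100 and C_ref the
glucose concentration.  This is the simplest rule consistent with
normalizing to glucose uptake; it is a proxy, not a kinetic claim, and
its sign is inferred from topology (negative only when the metabolite
appears exclusively as a substrate), overridable per node.  Users with
actual rate estimates can bypass the proxy entirely via
`boundary_rates`.  Because only the ratio C_m/C_ref enters, the solved
and normalized fluxes are invariant to any common rescaling of the
measurements (units cancel).

### Solving and diagnostics

The equality system (balances + anchor + pins) is solved exactly when
determined and by minimum-norm least squares otherwise (deterministic
and basis-independent); rank, equation/unknown counts and a determinacy
class are always reported so non-unique solutions are visible.  With
`nonnegative=True`, irreversible fluxes are bounded below by zero
(bounded least squares); if the constrained fit is materially worse
than the free fit, the violated reactions are listed in the error.  The
residual reported is the 2-norm over the pseudo-steady-state rows only;
the consistency threshold defaults to 1e-8 × scale.  Normalization
multiplies by scale/flux(reference) and sets the reference entry to
exactly 100 (idempotent).

### Graph export

One directed edge per substrate–product pair of each reaction, all
sharing the reaction's normalized flux attribute; GraphML via networkx,
DOT written directly (pen width = 0.5 + 4.5·|flux|/max|flux|, an affine
monotone map so line thickness orders as flux does).

## 4. Synthetic worlds

The generators' defaults state the emulated study design once:

- **Metabolome**: n = 6 per group, 300 metabolites, 20% planted
  differentials of ±2.0 log2 units (split evenly up/down), baseline
  log2 intensities N(20, 2) per metabolite with within-group sd 0.8
  (≈ CV 60–70%, typical untargeted LC-MS), 10% missingness
  (missing-completely-at-random by default; an abundance-biased
  left-censoring mode exists because real LC-MS missingness is
  abundance-biased).  The log-normal form is a modeling convention —
  no distributional information is available for real plasma
  intensities — and effects are additive on the log scale.
- **Panel**: low-group means glucose 5.0, lactate 2.5, β-HB 0.45,
  NADH 0.05 µmol/mL (plasma-physiological orders of magnitude), high
  group shifted +37%/−32%/−33%/0%, CV 0.15, n = 8 per group,
  zero-truncated normal.
- **Flux**: a random positive vector projected onto the null space of
  the internal balance rows (rejection-resampled until all
  irreversible fluxes are positive), rescaled to r1 = 100; boundary
  concentrations back-computed through the inverse proxy with
  multiplicative log-normal noise of scale `noise_frac`, glucose fixed
  at 5.0 µmol/mL.

What a green test does and does not establish: the generators share the
analysis's own distributional assumptions (log-normal intensities,
normal panel values, exact steady state), so recovery tests validate
the inference machinery, not its robustness to real-data violations
(drift, batch effects, heteroscedastic censoring, non-steady-state
physiology).  No spectra, retention times or instrument drift are
simulated.

## 5. Reproducibility

Every stochastic component takes an explicit seed.  Pipelines derive
per-stage seeds as crc32(stage_name) XOR global_seed (mod 2³¹), so each
stage is independently re-runnable; run manifests record config,
seeds, timings and sha256 checksums of every output.

## 6. Known limitations

- OPLS-DA supports exactly two classes and one predictive component.
- The flux model is linear and static: no kinetics, no thermodynamic
  constraints, no ¹³C labeling, no objective-function FBA.
- The concentration→rate proxy is a strong assumption; conclusions
  about absolute fluxes should not be drawn from it, only about
  relative redistribution between conditions.
- The default network is a documented reconstruction of a CMP skeleton
  at the stated granularity (10 reactions, 6 steady-state nodes);
  users with an exact published topology should load it as a file.
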