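# Methods

This note documents the statistical procedures grangernet implements,
the defaults it ships, and the places where a genuinely open design
choice was made. Everything quantitative stated here is computed by the
test suite or the acceptance script; nothing is quoted from elsewhere.

## Data model

A `PanelDataset` is a balanced N × T × V array: N ≥ 2 subjects, T ≥ 4
ordinal time points, V uniquely named variables, no missing cells.
Three policies are deliberate:

- **Ordinal time.** Sampling clocks in within-day designs are rarely
  equispaced; the panel estimators below assume integer lags, so time is
  the within-subject rank 0..T−1 and real clock times are carried only as
  metadata. Unequal physical spacing is thus *reinterpreted*, not
  resampled.
- **Reject, never impute.** At the scale these designs run (single-digit
  N), imputation error is invisible to any validation; the loader errors
  on unbalanced or missing data and names the offending subject/cell.
- **Conditions are separate panels.** One network per experimental
  condition; pooling across conditions would average over exactly the
  differences of interest.

Albumin-corrected calcium is the standard clinical formula
`corrected = total + 0.02 × (40 − albumin)` (calcium mmol/L, albumin
g/L), provided as a loader-level utility.

## Stationarity screen: Levin–Lin–Chu

The LLC test pools per-subject ADF regressions under a common
autoregressive root. Per subject, Δy_t and y_{t−1} (t = L+1..T−1) are
each residualized on {Δy_{t−1..t−L}, deterministic terms} and
standardized by the subject's ADF residual scale (RSS/(T−L−1)); the
standardized pairs are pooled into the no-intercept regression
ẽ = δ ṽ + err. The adjusted statistic is

    t* = (t_δ − N·T̃·Ŝ_N·σ̂_ε̃⁻²·SE(δ̂)·μ*) / σ*,

with T̃ the per-subject effective length, Ŝ_N the mean ratio of the
Bartlett-kernel long-run SD of Δy (truncation ⌈3.21·T^⅓⌉, capped at T−3)
to the ADF residual SD, and (μ*, σ*) adjustment moments. Left-tail
normal p-value; rejection means stationarity.

**Adjustment moments.** Published lookup tables for (μ*, σ*) start at
effective lengths far above the T = 9 these designs have, so the default
mode *simulates* the moments at run time under the driftless random-walk
null with the data's own (N, T, lag order, deterministic spec) — 2000
replicates by default, seeded, cached per configuration. This makes the
test self-calibrating at any panel geometry: measured size on random-walk
panels is 0.035–0.05 at nominal 0.05 (N=20/T=50 and N=6/T=9 alike). A
`tabulated` mode accepts a plug-in constant table; the built-in table was
itself calibrated by the same Monte-Carlo (N=25, 8000 replicates per
entry) at a small grid of effective lengths, with nearest-length lookup.

**Lag order.** Default 0 ADF augmentation lags for T < 15 (no room at
T = 9), else ⌊T^⅓⌋. Note a genuine trade-off: unnecessary augmentation
costs LLC considerable power (the adjustment term scales with Ŝ_N, which
the Bartlett kernel cannot drive to its theoretical zero under the
alternative at feasible truncations). Against stationary AR(0.3) panels
at N=20, T=50 the test rejects essentially always with 0 lags but only
~60% of the time with 3 lags. When the data are believed to be low-order
VARs, set `lags=0` explicitly.

**Deterministic spec.** Default `intercept`: physiological variables
have nonzero subject-specific levels. The test is one-sided (left tail).

`ensure_stationary` retests after each first-difference, up to
`max_diff` rounds (default 2); differencing one variable truncates the
whole panel by one point to preserve balance, and every decision lands
in a per-variable log. Still-nonstationary variables are flagged, not
silently transformed (configurable to hard-fail).

## Pairwise panel Granger test

Each ordered pair (cause x → effect y) is tested in the bivariate
information set only — own lags of y plus lags of x, never other
covariates. The estimator chain:

1. **Within transformation** per estimation window (subject means
   removed over the window's rows), absorbing fixed effects.
2. **Pooled OLS** across subjects, θ = (ρ₁..ρ_p, β₁..β_p).
3. **Half-panel jackknife**: the effective time range splits into first
   and last ⌊(T−p)/2⌋ regressand periods (odd middle period dropped;
   lags may reach before a window's start; each window re-demeans);
   θ̂_HPJ = 2θ̂_full − ½(θ̂_a + θ̂_b) removes the O(1/T) Nickell bias. At
   N=20, T=10 with ρ=0.5 the within estimate of ρ averages ≈0.32 while
   the HPJ estimate averages ≈0.55; with cross-correlated innovations the
   bias that leaks into β (≈+0.017) drops to ≈+0.006.
4. **Wald test** of β = 0, df = p.

**Variance estimator (clustered mode, default).** The HPJ estimator is
a linear combination of three pooled OLS fits sharing subjects, so its
subject-clustered sandwich uses the same combination of per-subject
influences, ψ_i = 2B_f s_i^f − ½(B_a s_i^a + B_b s_i^b). Two
small-sample corrections matter at T = 9 and are included: (i) each
window's scores use CR2 (bias-reduced) residual adjustment,
(M_i − X_i(X'X)⁻¹X_i')^{−1/2} with M_i the within-demeaning projector —
this accounts for the degrees of freedom the absorbed subject means and
slopes consume, which the plain sandwich ignores; (ii) residuals enter
at each window's own OLS solution (the CR2 derivation assumes own-window
residuals), with influences centered across subjects and the factor
N/(N−1). Without these corrections the estimated variance of β̂_HPJ is
~15% low and the nominal-0.05 test rejects at 0.09–0.14; with them the
variance is slightly conservative (≈+9%) and the measured size is
0.05–0.065 at N=50, T=9. The χ²_p reference is used as is; at very small
N the bootstrap mode is the safer choice.

**Bootstrap mode.** Subjects are resampled with replacement; each
resample's Wald statistic is computed on the recentered coefficient
(β* − β̂) with its own clustered variance, and the p-value is the tail
fraction (1 + #{W* ≥ W})/(n_boot + 1). Seeded and deterministic;
clustered and bootstrap modes agree on the 0.05 rejection decision in
≥90% of null replicates at N=50, T=9.

**Lag order default p = 1.** T = 9 leaves 8 effective periods; the
jackknife halves need 2p+1 periods each, so p = 2 already requires
T ≥ 16. Configurable.

## Network layer

Edges are pairs with p < α (default α = 0.05 per pair, no multiplicity
correction — matching the convention of reporting per-test significance;
Benjamini–Hochberg is available behind a flag and recorded in the run
log). Edge weight defaults to the Wald statistic ("larger = stronger
evidence"); 1−p and |β̂₁| are alternatives, since the weighted-adjacency
unit is a presentation choice, not an estimator property.

Metrics are computed on the binary thresholded digraph: in/out-degree
centrality = edge count / (n−1); betweenness = directed unweighted
shortest-path betweenness normalized by (n−1)(n−2) (an unnormalized
option exists; the normalization convention cannot be cross-checked
against published tables, which report only degree values as multiples
of 1/7); density = edges / n(n−1). Betweenness is validated exactly
against an exhaustive path-enumeration oracle on random 8-node digraphs.
Reports round to 2 decimals, half away from zero; full precision is kept
internally and in serialized outputs.

`realize_degree_sequence` constructs a simple digraph with an exact
in/out degree sequence via unit-capacity bipartite max-flow
(deterministic Edmonds–Karp); infeasible sequences fail with the violated
condition. This both supports consistency checks of published degree
tables and provides ground-truth supports for the diet-study preset.

## Synthetic data

`simulate_panel_var` iterates y_t = α_i + Σ_l A[l]' y_{t−l} + ε_t per
subject (α_i ~ N(0, diag(fixed_effect_sd²)), ε ~ N(0, Σ)), discards a
burn-in (default 100, ample for spectral radius ≤ 0.9), and keeps T
points; variables flagged as unit roots are cumulatively summed. Subject
heterogeneity enters through intercepts only, matching the pooled
estimator's homogeneous-slope assumption. Ground truth: edge j → k
exists iff some |A[l][j,k]| > 0 (j ≠ k), with weight max_l |A[l][j,k]| —
a simulation contract, since "strength" has no unique definition.
Stationarity of the companion matrix is enforced at construction unless
a unit root is requested. Sample autocovariances agree with the
discrete-Lyapunov solution within 10% at N=500.

**Diet-study preset.** N=6, T=9, the 8 analytes, VAR(1); the coefficient
support realizes the published integer degree sequence of the chosen
condition (26/27/13 edges). Nominal edge magnitude 0.5 with
deterministically alternating signs would be explosive at 26–27 edges on
8 nodes, so the off-diagonal block is rescaled once to companion
spectral radius 0.85 (support, hence ground truth, unchanged). Output is
mapped onto order-of-magnitude clinical scales; the real marginals are
published only graphically, so these scales are placeholders and carry
no inferential weight.

**Sparse-truth generator.** `random_sparse_var_spec` draws n_edges
directed edges of ±coef and nothing else. By default the support is
acyclic (edges placed forward along a random topological order). This is
a deliberate identifiability choice, not a convenience: a feedback pair
j ⇄ k makes j autocorrelated, which creates *population-level* bivariate
Granger relations between j and k's other neighbors — a pairwise
bivariate test then correctly rejects for pairs that have no direct
edge, and edge-set scores against direct-edge truth cap around 0.65–0.76
no matter how good the estimator is. With acyclic truth the pipeline's
mean edge-set F1 is ≈0.83 (N=30, T=9, 10 edges of 0.6, 50 seeds:
per-edge power ≈0.99, false-edge rate ≈0.06). Cyclic supports remain
available (`acyclic=False`) precisely to study that gap.

## Companion statistics

- **rmcorr**: ANCOVA with subject as factor and one common slope,
  computed by within-subject centering; r_rm = sign(slope)·√(SS_x /
  (SS_x + SS_err)), df = n_obs − n_subjects − 1, two-sided t test.
  Matches an explicit dummy-variable GLM solve to 10 significant digits
  and the independent `pingouin` implementation to 1e−10. Confidence
  intervals (Fisher-z on the rmcorr df) are optional and labeled
  approximate.
- **Kruskal–Wallis**: tie-corrected H against χ²_{k−1}; follow-ups are
  two-sided Mann–Whitney U per group pair with Bonferroni multiplication
  capped at 1. The Bonferroni family size is an explicit argument
  (default: number of group pairs, echoed in the result) because family
  definitions vary across reporting conventions and silently guessing
  one is worse than stating it.
- **mean ± SEM**: sample SD / √n.

## Pipeline and reproducibility

`run_pipeline` executes load/generate → stationarity screen → pairwise
tests → adjacency → metrics per condition and writes a self-contained
bundle (effective config echoed as YAML, per-variable transformation
log, pairwise TSV, adjacency TSV, centrality TSV, density+hubs JSON,
GraphML/DOT). All randomness (moment simulation, bootstrap, synthetic
data) derives from the single config seed via per-stage stable hashes;
two runs with the same config are byte-identical. Stage failures abort
with the stage name and leave a FAILED marker next to any partial
output.

## Experiment sizes used by the test suite

Monte-Carlo checks run at the sizes that make their conclusions stable
while keeping the suite fast: test size 500 replicates, power 200, HPJ
bias 500, LLC size 500 (with the 2000-replicate moment calibration
cached), edge recovery 50 seeds, oracle agreement 100–200 cases;
module-level variants of the same properties use smaller replicate
counts with correspondingly looser thresholds. LLC moment calibration
defaults to 2000 replicates, which puts a ±0.01-ish Monte-Carlo wobble
on borderline p-values; raise `n_moment_reps` for publication-grade
runs.

## Known limitations

- Pairwise bivariate conditioning only: indirect paths and common causes
  are part of what the method reports (see the acyclicity discussion);
  multivariate or partial Granger analysis is out of scope.
- Homogeneous coefficients across subjects; no heterogeneous-slope
  testing (e.g., averaged-individual-Wald statistics) — with N = 6 there
  is no realistic power for heterogeneity anyway.
- No instantaneous (lag-0) causality, no periodic/circadian forcing in
  the generator, no missing-data handling by design.
- The χ² reference for the clustered Wald is asymptotic in N; at the
  motivating study's N = 6, p-values from either variance mode should be
  read as descriptive orderings rather than calibrated error rates — the
  graph layer, not the individual p-value, is the deliverable there.
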