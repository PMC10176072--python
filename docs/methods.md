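# Methods

This note documents the models and procedures `scfc` implements, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical conventions that make results
deterministic.

## The synthetic cohort

The generator produces, per subject and wave: a streamline-count matrix, a
functional run, four outcomes, and MCAR missingness. It models the
*statistical* structure the downstream analysis consumes, nothing more.

**Structural networks.** A stochastic block model over the configured
communities (default: five near-equal blocks of a 162-node parcellation,
81 regions per hemisphere being the anatomical convention emulated).
Within-block edges appear with `p_intra = 0.95`, between-block with
`p_inter = 0.10`; present edges carry log-normal counts
(`log count ~ N(weight_scale, weight_sigma²)` within blocks, half the
log-mean between; defaults 4.0 and 1.0, giving counts spread over roughly
two orders of magnitude, as heavy-tailed as real streamline counts). The
high `p_intra` is deliberate: edge presence is independent across
subjects, so a 90% group-prevalence mask is only non-empty when the
shared backbone is itself near-deterministic. The prevalence mask
therefore consists almost entirely of within-community edges.

**Latent coupling.** Each subject has a scalar `kappa ∈ [0, 1]`
(`N(0.30, 0.07²)` clamped). The functional run of `n_timepoints_ts = 200`
samples is drawn from a zero-mean Gaussian whose correlation matrix is
the convex blend `kappa·C_struct + (1 − kappa)·I`, where `C_struct` is the
subject's own degree-normalised log-weight matrix scaled to a peak
off-diagonal of `structural_corr_max = 0.6`, given a unit diagonal, and
projected to the nearest positive-definite correlation matrix (eigenvalue
clip at 1e-8, rescale to unit diagonal). A Gaussian is sufficient because
only second-order statistics (pairwise correlations) feed the analysis; no
hemodynamics, autocorrelation, or scanner noise is modelled.

`kappa` is the quantity the coupling coefficient is supposed to estimate,
so parameter-recovery defines validity: measured whole-brain coupling must
increase monotonically in `kappa` (it does; Spearman 1.0 across a
0.1–0.9 grid) and correlate strongly with it across subjects (≈ 0.92 at
the defaults). The four defaults above (`kappa` mean/SD, correlation
scale, run length) were calibrated once so the reference cohort's measured
whole-brain coupling is centred near 0.22 with SD near 0.04–0.06, the
regime the analysis is designed for; they are configuration, not fitted
quantities.

**Outcomes.** Linear-Gaussian in (kappa, age, sex). Cognition and
processing speed live on a z-score scale; apathy and depression are
generated as `exp` of a Gaussian log-scale model, so raw scores are
positive, higher raw means more severe, and the natural-log transform
applied before modelling is always defined. Default effects carry the
sign pattern the analysis is meant to detect: positive coupling effects
on cognition (+1.5) and processing speed (+2.2), a negative effect on log
apathy (−0.83), and **no** effect on depression (the specificity
control). Intercepts put cohort means near: cognition 0.2, processing
speed −1.1, log-apathy 3.2, log-depression 2.7 at the default kappa and
age distribution (age ~ N(67.8, 8²) clipped to [50, 85], 43.5% female).

**Design.** Two waves, 4 years apart. The streamline matrix is shared
across waves (anatomy treated as stable over follow-up); `kappa` drifts by
`longitudinal_delta` (default 0 — stable coupling) plus N(0, 0.02²) noise,
clamped. A 50/262 attrition fraction drops subjects at wave 2, giving the
262/212 reference design. Missingness is MCAR per outcome at rates
2/262 (cognition), 5/262 (processing speed), 10/262 (apathy), 4/262
(depression); MCAR is an explicit simplification — the generator makes no
claim about informative missingness.

**What passing tests do not show.** The generator has no spatial
embedding, no distance-dependent connectivity, no inter-subject
topological variability beyond Bernoulli edge noise, Gaussian signals
with exchangeable time samples, and MCAR missingness. Recovery results
therefore certify the *pipeline's* correctness and operating
characteristics under its stated assumptions, not robustness to real
fMRI confounds (motion, hemodynamic variability, parcellation error).

## Network construction

* Prevalence mask: edge kept iff `count > 0` in ≥ 90% of wave-1 subjects
  (inclusive comparison; "present" means a nonzero raw count, judged
  before the log transform). The wave-1 mask is reused at wave 2 so both
  waves are measured over the same edge set.
* SCN weights: `ln(count + 1)` on masked-in edges, zero elsewhere.
* FCN weights: Pearson correlations clipped to ±(1 − 1e-7) (keeps
  Fisher-Z finite for numerically perfect correlations), then `atanh`,
  then negatives zeroed — the order is fixed as clip → transform → zero.
  A constant signal column is a contract violation reported with the
  node's label.
* Proportional threshold: keep the `k = round(density·n(n−1)/2)`
  strongest upper-triangle edges (half-away-from-zero rounding); ties at
  the cutoff break by ascending (i, j) order, making the operation
  deterministic. An all-zero matrix passes through with a warning.

## Community detection

Modularity is the Newman–Girvan weighted form at resolution γ = 1
(γ exposed as a parameter). Louvain runs use `networkx`'s seeded
implementation; the returned partition is canonicalised (labels 1..K by
descending size, ties by smallest member index) and its Q recomputed by
the package's own modularity — if a run ever fell below the trivial
one-community partition's Q = 0 it would be replaced by that partition.
The consensus scheme iterates: zero agreement entries below τ = 0.5, run
Louvain `reps` times on the thresholded agreement, rebuild — until all
runs agree (entries all 0/1), with the same `reps` reused inside every
iteration. Failure to stabilise in 20 iterations raises with advice to
increase τ. Nodes whose agreement rows all fall below τ become singleton
communities (retained, not merged). The consensus partition's modularity
is reported on the thresholded group FCN, not on the agreement matrix.

## Coupling

Eligible edges = group prevalence mask ∧ subject SCN weight > 0, upper
triangle. Whole-brain coupling is the Pearson correlation of the SCN and
FCN weight vectors over those edges; per-community coupling restricts to
edges with both endpoints in the community. Fewer than 3 eligible edges,
or a zero-variance weight vector, yields NaN — flagged, never fabricated.
FCN zeros produced by negative-zeroing are legitimate values and stay in.
Coupling enters the outcome models untransformed (a Fisher transform of
the per-subject r is available but off by default). Global efficiency
maps weights to lengths by 1/w (the standard convention for weighted
efficiency), uses Dijkstra shortest paths, and counts unreachable pairs
as zero contribution.

## Statistics

* Composite scores: mean of per-test z-scores against reference
  (mean, SD) pairs.
* Imputation: chained-equation PMM, m = 20 by default, 10 sweeps, donor
  pool k = 5, type-1 matching (posterior-draw predictions for missing
  cases, least-squares predictions for donors, coefficient draws from the
  normal approximation with a scaled inverse-chi-square residual
  variance). Imputed values are always copies of observed donors, so
  support, discreteness, and positivity are preserved automatically. Only
  outcome columns are imputed; undefined coupling values are structural
  flags and those rows are dropped instead.
* Cross-sectional models: OLS with unstandardised coefficients,
  covariates age, sex, global efficiency. Rank-deficient designs raise
  with the collinear columns named.
* Longitudinal models: random-intercept LMM fit by profiled REML — the
  variance ratio θ = σ_u²/σ_e² is the only free parameter; at each
  candidate the fixed effects solve in closed form because
  (I + θ·11')⁻¹ is analytic per subject. θ is maximised over log θ by
  bounded scalar search; a boundary estimate (θ = 0) reduces exactly to
  OLS. Fixed-effect dfs are the residual-style n − p, which feeds the
  Barnard–Rubin adjustment; simulation-based validation (variance
  components within 20% at 200 subjects × 2 waves, agreement with an
  independent mixed-model implementation to ~0.1% on well-conditioned
  data) backs this choice.
* Pooling: Rubin's rules with Barnard–Rubin df when a finite
  complete-data df is available; m = 1 degenerates to the single estimate
  with a warning. FDR: Benjamini–Hochberg, family = one results table
  (all networks × all outcomes at one design).

## Problem sizes used in validation

The validation experiments run at sizes chosen to make the checks sharp
yet cheap: consensus recovery uses 10 independently simulated 15-subject
group FCNs with 100 Louvain repetitions (the planted five-block structure
is recovered at ARI 1.0 well below the 1000-rep production default);
power and type-I use 50 replicate single-wave cohorts of 250 subjects
with m = 5 imputations, plus a 200-replicate null check that holds one
cohort's measured design fixed and redraws the null outcome (conditioning
on the design keeps the loop at outcome-model cost while exercising
imputation and inference end to end); the coupling dial uses 50 subjects
per kappa level. `scripts/acceptance.py` prints the size alongside every
quantity it reports.

## Known limitations

* The consensus modularity of a synthetic cohort reflects the generator's
  block contrast, not any empirical brain; with the default contrast the
  thresholded group FCN is nearly block-diagonal and Q ≈ 0.8.
* MCAR missingness means the imputation machinery is validated for
  efficiency, not for bias correction under MAR/MNAR.
* The LMM supports a single random intercept only — by design, matching
  the two-wave analysis; slopes or crossed effects are out of scope.
* Edge presence is independent across subjects, so prevalence masking is
  only meaningful near-deterministic backbones (see above); analyses of
  sparser, more variable topologies should lower the prevalence
  threshold explicitly.
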