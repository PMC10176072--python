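# scfc — structure–function connectome coupling

`scfc` is a tested, reusable pipeline for studying how tightly the brain's
functional organisation follows its anatomical wiring. It is aimed at
network-neuroscience and clinical-cohort analysts who have, per subject, a
symmetric streamline-count matrix (structural connectivity) and a
region-by-time signal table (functional data), plus a metadata table with
demographics and outcomes — and who want whole-brain and per-community
structure–function coupling coefficients related to outcomes with
imputation-aware cross-sectional and longitudinal models.

Because cohort MRI data is rarely shareable, the package ships a
first-class synthetic-cohort generator that emulates the statistical
structure such a study assumes: 162-node block-structured networks with
five functional communities, a latent per-subject coupling strength, a
two-wave design with attrition, outcome effects of coupling, and
item-level missingness. Every claim the package makes about its analysis
is tested by recovering what the generator planted.

## The quantities computed

**Networks.** The structural connectivity network (SCN) has weights
`ln(count + 1)` on edges present (count > 0) in at least 90% of the group;
the functional connectivity network (FCN) has weights
`z_ij = atanh(r_ij)` for positive Pearson correlations `r_ij` between
regional time series, with negative correlations set to zero.

**Communities.** On the group-average FCN, proportionally thresholded to
10% edge density, communities maximise the Newman–Girvan weighted
modularity

    Q = Σ_ij [ A_ij/2W − k_i k_j/(2W)² ] δ(c_i, c_j)

via repeated seeded Louvain runs; the co-assignment frequencies over runs
form an agreement matrix that is iterated (threshold at τ = 0.5, re-run
Louvain, rebuild) to a consensus partition.

**Coupling.** The coupling coefficient is the Pearson correlation between
a subject's nonzero SCN edge weights and the FCN weights at the same
(group-prevalent) edges — one number per subject, also computed per
community over within-community edges. Structural global efficiency
(mean inverse shortest-path length, edge length = 1/weight) is the
standard covariate.

**Statistics.** Outcomes with missing items are multiply imputed by
chained-equation predictive mean matching (donor pool k = 5); each
completed table is modelled by OLS (cross-sectional) or a random-intercept
linear mixed model fit by profiled REML (longitudinal), adjusting for age,
sex, global efficiency (and follow-up time); estimates are pooled by
Rubin's rules, `T = W̄ + (1 + 1/m)B`, with Barnard–Rubin degrees of
freedom, and p-values are Benjamini–Hochberg FDR-adjusted per results
table.

## Worked example

```python
import numpy as np
import scfc

config = scfc.SimulationConfig(n_subjects=15)
cohort = scfc.generate_cohort(config, seed=7)
wave1 = cohort.at_timepoint(1)
mask = scfc.prevalence_mask([s.streamline_matrix for s in wave1])

profiles = []
for s in wave1:
    scn = scfc.build_scn(s.streamline_matrix, mask)
    fcn = scfc.build_fcn(s.timeseries)
    profiles.append(scfc.coupling_profile(s.subject_id, s.timepoint,
                                          scn, fcn, mask))
table = scfc.cohort_coupling_table(profiles)
print(table[["subject_id", "whole_brain_r", "global_efficiency"]].head(3))
```

prints (see `examples/04_coupling_profile.py` for the full script):

```
subject_id  whole_brain_r  global_efficiency
    sub-01       0.179320           0.738615
    sub-02       0.403128           0.731545
    sub-03       0.157528           0.737622
```

Each `whole_brain_r` is one subject's structure–function coupling: sub-02's
functional correlations track their structural weights most closely. Over
this cohort the coupling mean is ≈ 0.23 with SD ≈ 0.06, and it correlates
≈ 0.92 with the latent coupling strength the generator planted — the
measured coefficient is a faithful proxy of the quantity it is meant to
estimate.

The other `examples/` scripts walk one capability each: cohort simulation
(01), network construction (02), consensus communities (03 — the planted
five blocks are recovered with adjusted Rand index 1.0 and Q ≈ 0.8), and
the pooled outcome models (05 — positive processing-speed and negative
apathy effects of coupling significant at FDR < 0.05, null depression
effect quiet).

A thin CLI wraps the same library: `scfc run-all --out DIR --seed 1`
executes simulate → build → communities → coupling → stats and writes a
manifest; the stage subcommands (`simulate`, `build-networks`,
`communities`, `coupling`, `stats`, `make-fixtures`) run pieces in
isolation. Reruns with the same config and seed are byte-identical.

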