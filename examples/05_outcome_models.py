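"""Relate coupling to outcomes with imputation-aware regression models.

Outcomes with item-level missingness are multiply imputed by predictive
mean matching; each completed table is modelled (OLS cross-sectionally, a
random-intercept mixed model longitudinally), estimates are pooled by
Rubin's rules, and p-values are FDR-adjusted per results table.
"""

import scfc
from scfc.stats import build_analysis_table, run_model_table

config = scfc.SimulationConfig(n_subjects=120)
cohort = scfc.generate_cohort(config, seed=7)
wave1 = cohort.at_timepoint(1)
mask = scfc.prevalence_mask([s.streamline_matrix for s in wave1])

profiles = []
for s in cohort:
    scn = scfc.build_scn(s.streamline_matrix, mask)
    fcn = scfc.build_fcn(s.timeseries)
    profiles.append(scfc.coupling_profile(s.subject_id, s.timepoint,
                                          scn, fcn, mask))
table = build_analysis_table(cohort.metadata(),
                             scfc.cohort_coupling_table(profiles))

outcomes = ["cognition", "processing_speed", "log_apathy", "log_depression"]
cross = run_model_table(table, "cross", ["whole_brain_r"], outcomes,
                        m=10, seed=1234)
print("cross-sectional (OLS, pooled over 10 imputations):")
print(cross.to_string(index=False))
longi = run_model_table(table, "long", ["whole_brain_r"], outcomes,
                        m=10, seed=1234)
print("\nlongitudinal (random-intercept mixed model):")
print(longi.to_string(index=False))
print("\nThe generator plants positive coupling effects on processing speed "
      "and cognition, a negative effect on (log) apathy, and none on "
      "depression; the pooled betas should carry those signs.")
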