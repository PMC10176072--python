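"""Build structural and functional connectivity matrices for one subject.

The structural network is the log(x+1) of raw streamline counts, masked to
edges present in at least 90% of the group. The functional network is the
Fisher-Z of pairwise time-series correlations with negatives zeroed.
"""

import numpy as np

import scfc

config = scfc.SimulationConfig(n_subjects=10)
cohort = scfc.generate_cohort(config, seed=7)
wave1 = cohort.at_timepoint(1)

mask = scfc.prevalence_mask([s.streamline_matrix for s in wave1], threshold=0.90)
n_edges = mask.sum() // 2
total = config.n_nodes * (config.n_nodes - 1) // 2
print(f"prevalence mask: {n_edges} of {total} edges present in >=90% of subjects")

subject = wave1[0]
scn = scfc.build_scn(subject.streamline_matrix, mask)
fcn = scfc.build_fcn(subject.timeseries)
iu = np.triu_indices(config.n_nodes, 1)
print(f"SCN weights (log-counts) on masked edges: "
      f"max {scn.values.max():.2f}, mean of nonzero {scn.values[scn.values > 0].mean():.2f}")
print(f"FCN weights (Fisher-Z): max {fcn.values.max():.3f}, "
      f"fraction zero (negative r) {np.mean(fcn.values[iu] == 0):.2f}")
print("\nBoth matrices are symmetric, nonnegative, zero-diagonal; they feed "
      "the coupling coefficient in example 04.")
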