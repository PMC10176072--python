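import numpy as np
import pytest

import scfc


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles on 6 nodes."""
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return a


@pytest.fixture
def path3():
    """3-node path A-B-C with unit weights."""
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 1.0
    a[1, 2] = a[2, 1] = 1.0
    return a


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort at default configuration.

    Session-scoped because several properties (calibration, coupling-kappa
    correlation, attrition counts) read the same cohort.
    """
    config = scfc.SimulationConfig()
    return scfc.generate_cohort(config, seed=101)


@pytest.fixture(scope="session")
def default_cohort_coupling(default_cohort):
    """Whole-brain coupling and kappa for every record of the default cohort."""
    wave1 = default_cohort.at_timepoint(1)
    mask = scfc.prevalence_mask([s.streamline_matrix for s in wave1])
    rows = []
    for s in default_cohort:
        scn = scfc.build_scn(s.streamline_matrix, mask)
        fcn = scfc.build_fcn(s.timeseries)
        rows.append({
            "subject_id": s.subject_id,
            "timepoint": s.timepoint,
            "kappa_true": s.kappa_true,
            "whole_brain_r": scfc.coupling_coefficient(scn.values, fcn.values, mask),
        })
    import pandas as pd
    return pd.DataFrame(rows)


def set_partitions(items):
    """Yield every partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i, block in enumerate(partial):
            yield partial[:i] + [[first] + block] + partial[i + 1:]
        yield [[first]] + partial
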