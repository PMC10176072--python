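"""End-to-end orchestration: simulate -> build -> communities -> coupling -> stats.

``run_all`` executes the whole analysis on a synthetic cohort and writes
every intermediate and final artifact plus a run manifest (config hash,
seeds, file checksums, package version). Stage randomness fans out from
one root seed through deterministic child seeds, so a rerun with the same
config and seed reproduces the data outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, generate_cohort, write_cohort
from .community import Partition, agreement, consensus, louvain
from .config import SimulationConfig
from .coupling import cohort_coupling_table, coupling_profile
from .errors import ConfigError
from .netbuild import (build_fcn, build_scn, group_average_fcn, prevalence_mask,
                       proportional_threshold, write_mask_tsv, write_matrix_tsv)
from .stats import build_analysis_table, run_model_table

__all__ = ["RunManifest", "run_all", "make_fixtures"]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    stage_timestamps: dict[str, float] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence([root, stage]).generate_state(1)[0]) % (2**31)


def run_all(config: SimulationConfig, out_dir: str | Path,
            seed: int | None = None, prevalence: float = 0.90,
            density: float = 0.10, reps: int = 1000, tau: float = 0.5,
            m: int = 20, write_subject_files: bool = False) -> RunManifest:
    """Run every stage on a freshly simulated cohort and write all outputs.

    Outputs under ``out_dir``: cohort metadata and config echo, prevalence
    mask, group-average FCN (raw and thresholded), consensus partition,
    ``coupling.csv``, ``results_crosssectional.csv``,
    ``results_longitudinal.csv``, and ``manifest.json``. Set
    ``write_subject_files`` to also emit per-subject adjacency and
    time-series TSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_yaml.encode()).hexdigest(),
        seed=seed, package_version=__version__)

    def stamp(stage: str) -> None:
        manifest.stage_timestamps[stage] = time.time()

    # 1. simulate -----------------------------------------------------------
    stamp("simulate")
    cohort = generate_cohort(config, seed=_child_seed(seed, 0))
    if write_subject_files:
        write_cohort(cohort, out / "cohort")
    cohort.metadata().to_csv(out / "cohort.csv", index=False)
    (out / "config.yaml").write_text(config_yaml)

    # 2. build networks -----------------------------------------------------
    stamp("netbuild")
    wave1 = cohort.at_timepoint(1)
    mask = prevalence_mask([s.streamline_matrix for s in wave1], prevalence)
    write_mask_tsv(mask, out / "prevalence_mask.tsv", config.node_labels)
    scns = {(s.subject_id, s.timepoint):
            build_scn(s.streamline_matrix, mask, config.node_labels)
            for s in cohort}
    fcns = {(s.subject_id, s.timepoint):
            build_fcn(s.timeseries, config.node_labels) for s in cohort}
    group_fcn = group_average_fcn([fcns[(s.subject_id, 1)] for s in wave1])
    write_matrix_tsv(group_fcn, out / "group_fcn.tsv")
    group_thr = proportional_threshold(group_fcn, density)
    write_matrix_tsv(group_thr, out / "group_fcn_thresholded.tsv")

    # 3. communities --------------------------------------------------------
    stamp("communities")
    comm_seed = _child_seed(seed, 1)
    ss = np.random.SeedSequence(comm_seed)
    run_seeds = [int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(reps)]
    runs = [louvain(group_thr, seed=s) for s in run_seeds]
    agree = agreement(runs)
    partition = consensus(agree, tau=tau, reps=reps, seed=comm_seed + 1,
                          modularity_matrix=group_thr)
    pd.DataFrame({"node_label": config.node_labels,
                  "community_id": partition.assignment}).to_csv(
        out / "consensus_partition.tsv", sep="\t", index=False)
    (out / "consensus_modularity.txt").write_text(f"{partition.q:.10f}\n")

    # 4. coupling -----------------------------------------------------------
    stamp("coupling")
    profiles = [coupling_profile(s.subject_id, s.timepoint,
                                 scns[(s.subject_id, s.timepoint)],
                                 fcns[(s.subject_id, s.timepoint)],
                                 mask, partition)
                for s in cohort]
    coupling_df = cohort_coupling_table(profiles)
    coupling_df.to_csv(out / "coupling.csv", index=False)

    # 5. stats --------------------------------------------------------------
    stamp("stats")
    table = build_analysis_table(cohort.metadata(), coupling_df,
                                 follow_up_years=config.follow_up_years)
    networks = ["whole_brain_r"] + [c for c in coupling_df.columns
                                    if c.startswith("community_")]
    outcomes = ["cognition", "processing_speed", "log_apathy", "log_depression"]
    stats_seed = _child_seed(seed, 2)
    cross = run_model_table(table, "cross", networks, outcomes,
                            m=m, seed=stats_seed)
    cross.to_csv(out / "results_crosssectional.csv", index=False)
    longi = run_model_table(table, "long", networks, outcomes,
                            m=m, seed=stats_seed + 1)
    longi.to_csv(out / "results_longitudinal.csv", index=False)
    stamp("done")

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.files[str(f.relative_to(out))] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Hand-checkable fixtures

def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Emit the tiny fixtures used in the documentation and tests.

    Each fixture comes with a sidecar entry in ``expected_values.json``
    stating the hand-derived value it should reproduce.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    two_triangles = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        two_triangles[i, j] = two_triangles[j, i] = 1.0
    write_matrix_tsv(two_triangles, out / "two_triangles.tsv")
    written.append(out / "two_triangles.tsv")

    path3 = np.zeros((3, 3))
    path3[0, 1] = path3[1, 0] = 1.0
    path3[1, 2] = path3[2, 1] = 1.0
    write_matrix_tsv(path3, out / "path3.tsv")
    written.append(out / "path3.tsv")

    counts4 = np.array([[0, 3, 0, 1],
                        [3, 0, 7, 0],
                        [0, 7, 0, 2],
                        [1, 0, 2, 0]], dtype=int)
    pd.DataFrame(counts4).to_csv(out / "counts4.tsv", sep="\t")
    written.append(out / "counts4.tsv")

    t = np.arange(12, dtype=float)
    toy_ts = np.column_stack([t, 2 * t + np.resize([0.5, -0.5], 12), -t])
    pd.DataFrame(toy_ts, columns=["a", "b", "c"]).to_csv(
        out / "toy_timeseries.tsv", sep="\t", index=False)
    written.append(out / "toy_timeseries.tsv")

    expected = {
        "two_triangles": {
            "modularity_of_components": 0.5,
            "provenance": "hand-derived: e11=e22=1/2, a1=a2=1/2, Q=2(1/2-1/4)",
        },
        "path3": {
            "global_efficiency": 5 / 6,
            "provenance": "hand-derived: d(A,B)=d(B,C)=1, d(A,C)=2, mean(1,1,1/2)",
        },
        "rubin_m2": {
            "betas": [1.0, 3.0], "variances": [1.0, 1.0],
            "pooled_beta": 2.0, "pooled_total_variance": 4.0,
            "provenance": "hand-derived: W=1, B=2, T=W+(1+1/2)B=4",
        },
        "toy_timeseries": {
            "edge_ab_positive": True, "edge_ac": 0.0,
            "provenance": "hand-derived: c=-a exactly, negative r zeroed",
        },
    }
    (out / "expected_values.json").write_text(json.dumps(expected, indent=2))
    written.append(out / "expected_values.json")
    return written
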