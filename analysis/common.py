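"""Shared study configuration for the numbered analysis scripts.

One synthetic longitudinal cohort is analysed throughout: 120 participants
aged 20-80 at two timepoints, a 120-node / 14-network parcellation, 200
samples per task series, and two cognitive domains.  Everything is derived
deterministically from the seed, so each script can rebuild the cohort in
memory instead of shuttling hundreds of matrix files between stages.
"""

from pathlib import Path

import topoconn as tc

RESULTS = Path(__file__).resolve().parent.parent / "results"

COHORT_CONFIG = tc.SimulationConfig(
    n_participants=120,
    n_nodes=120,
    n_networks=14,
    series_length=200,
    domains=("fluid", "mem"),
    seed=11,
)

ANALYSIS_CONFIG = tc.AnalysisConfig(n_perm=5000, n_boot=5000, seed=11)


def build_cohort() -> tc.SyntheticCohort:
    return tc.simulate_cohort(COHORT_CONFIG)


def build_table(cohort=None):
    cohort = cohort or build_cohort()
    measures, curves = tc.compute_measures(
        cohort.data,
        cohort.partition,
        step=ANALYSIS_CONFIG.step,
        collect_curves=True,
    )
    table = tc.assemble_cohort_table(cohort.covariates, cohort.behavior, measures)
    return table, measures, curves
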