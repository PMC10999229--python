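"""Shared fixtures.

The expensive calibration and recovery studies are session-scoped so that
every test asserting on them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import topoconn as tc


def random_matrix(rng: np.random.Generator, n: int) -> tc.ConnectivityMatrix:
    """Random symmetric Fisher-z-like matrix with continuous (tie-free) weights."""
    w = rng.normal(0.2, 0.4, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return tc.ConnectivityMatrix(tuple(range(n)), w)


@pytest.fixture(scope="session")
def recovery_study():
    """100 seeded cohorts at the recovery-study conditions.

    160 participants, 60 nodes, 6 networks, 200-sample series, one domain,
    generator defaults (negative age-graded coupling decline, positive
    behavior coupling).  Collects the change-model coefficients the recovery
    properties assert on.
    """
    out = {
        "age_beta_auc": [],
        "age_beta_seg": [],
        "beh_auc_beta": [],
        "beh_auc_fdr_p": [],
    }
    for s in range(100):
        cfg = tc.SimulationConfig(
            n_participants=160,
            n_nodes=60,
            n_networks=6,
            series_length=200,
            domains=("fluid",),
            seed=20_000 + s,
        )
        table = tc.cohort_table(tc.simulate_cohort(cfg))
        res = tc.run_full_analysis(table, ["fluid"])
        sel = res[res.time == "FU-BL"]
        out["age_beta_auc"].append(
            sel[(sel.outcome == "AUC") & (sel.predictor == "age")]["beta"].item()
        )
        out["age_beta_seg"].append(
            sel[(sel.outcome == "SEG") & (sel.predictor == "age")]["beta"].item()
        )
        row = sel[(sel.outcome == "BEH_AUC") & (sel.predictor == "auc")]
        out["beh_auc_beta"].append(row["beta"].item())
        out["beh_auc_fdr_p"].append(row["fdr_p"].item())
    return {k: np.asarray(v) for k, v in out.items()}


@pytest.fixture(scope="session")
def null_perm_pvalues():
    """Permutation p-values for the age effect under 200 null cohorts.

    All generator effect slopes are zero, so age carries no information about
    change in behavior; each cohort contributes one permutation p at 500
    permutations (age effect in the change-in-behavior model with the
    change-in-AUC predictor).
    """
    pvals = []
    for s in range(200):
        cfg = tc.SimulationConfig(
            n_participants=60,
            n_nodes=30,
            n_networks=6,
            series_length=80,
            domains=("fluid",),
            seg_decline_slope=0.0,
            seg_noise_sd=0.05,
            beta_age_behavior=0.0,
            beta_auc_behavior=0.0,
            beta_nart_behavior=0.0,
            seed=40_000 + s,
        )
        table = tc.cohort_table(tc.simulate_cohort(cfg))
        res = tc.run_permutation(
            table,
            "fluid",
            target="age",
            config=tc.AnalysisConfig(n_perm=500, seed=s),
        )
        pvals.append(res["p"])
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def null_acme_cis():
    """ACME percentile CIs from 100 seeded null mediations (pure-noise mediator)."""
    cis = []
    for s in range(100):
        rng = np.random.default_rng(60_000 + s)
        x = rng.normal(size=100)
        m = rng.normal(size=100)
        y = rng.normal(size=100)
        res = tc.mediation_bootstrap(x, m, y, n_boot=400, seed=s)
        cis.append(res.acme_ci)
    return np.asarray(cis)


@pytest.fixture(scope="session")
def small_cohort_table():
    """One small analyzed cohort shared by structural pipeline tests."""
    cfg = tc.SimulationConfig(
        n_participants=50,
        n_nodes=40,
        n_networks=6,
        series_length=60,
        domains=("fluid", "mem"),
        seed=7,
    )
    cohort = tc.simulate_cohort(cfg)
    return tc.cohort_table(cohort), cohort
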