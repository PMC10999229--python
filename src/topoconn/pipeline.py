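"""End-to-end analysis: participant measures -> longitudinal model battery.

For each participant, timepoint and cognitive domain the pipeline derives
three whole-brain summaries from the Fisher-z connectivity matrix: the AUC
of the Betti-0 curve under edge-density filtration (computed on the full
signed matrix), system segregation, and (optionally) modularity Q (both on
the positive-edge matrix).

The model battery then mirrors a two-timepoint ageing study.  Per domain:

* brain-measure models — outcome AUC or segregation at baseline, follow-up,
  or change (change = follow-up minus baseline, residualized on baseline);
  predictors age, NART, education, sex, cortical thickness and WMH volume
  (their changes, baseline-residualized, in the change models).  Scrubbing
  variance is removed from every brain measure beforehand.
* behavior models — same predictor set plus the matching brain measure,
  once with AUC and once with segregation as the seventh predictor.

That is 2 measures x 3 contrasts x 6 predictors + 2 behavior variants x 3
contrasts x 7 predictors = 78 predictor p-values per domain, which form one
Benjamini-Hochberg family.  Post-hoc utilities cover the permutation test of
the change-in-AUC effect on change in cognition, percentile-bootstrap
mediation of the age effect through change in AUC, and the exhaustive
127-model BIC search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, TimeSeries, correlation_matrix, positive_part
from .errors import ValidationError
from .inference import (
    MediationResult,
    bic_search,
    fdr_family,
    fit_model,
    mediation_bootstrap,
    permutation_test,
    remove_scrubbing,
    residualize_on_baseline,
)
from .metrics import modularity_q, system_segregation
from .partition import NetworkPartition
from .synthetic import TIMEPOINTS, SyntheticCohort
from .topology import auc, betti0_curve

__all__ = [
    "AnalysisConfig",
    "compute_measures",
    "assemble_cohort_table",
    "run_full_analysis",
    "run_permutation",
    "run_mediation",
    "run_bic_search",
    "FAMILY_SIZE",
]

#: per-domain FDR family size: 2 x 3 x 6 brain + 2 x 3 x 7 behavior entries
FAMILY_SIZE = 78

BASE_PREDICTORS = ("age", "nart", "education", "sex", "ct", "wmh")
CONTRASTS = ("bl", "fu", "delta")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis, with documented defaults."""

    step: float = 0.01
    filtration_mode: str = "density"
    include_zero_edges: bool = True
    compute_q: bool = False
    fdr_q: float = 0.05
    n_perm: int = 10000
    n_boot: int = 10000
    seed: int = 0


def _as_matrix(obj) -> ConnectivityMatrix:
    if isinstance(obj, ConnectivityMatrix):
        return obj
    if isinstance(obj, TimeSeries):
        return correlation_matrix(obj)
    raise ValidationError(f"cannot interpret {type(obj).__name__} as connectivity data")


def compute_measures(
    data: dict,
    partition: NetworkPartition,
    step: float = 0.01,
    mode: str = "density",
    include_zeros: bool = True,
    compute_q: bool = False,
    collect_curves: bool = False,
):
    """Per-(participant, timepoint, domain) topology and segregation summaries.

    ``data`` maps ``(participant, timepoint, domain)`` to a
    :class:`TimeSeries` or :class:`ConnectivityMatrix`.  Returns a measures
    DataFrame (and the long-format curve table when ``collect_curves``).
    """
    rows, curve_rows = [], []
    for (pid, tp, domain), obj in data.items():
        m = _as_matrix(obj)
        curve = betti0_curve(m, step=step, mode=mode)
        pos = positive_part(m)
        seg = system_segregation(pos, partition, include_zeros=include_zeros)
        row = {
            "participant": pid,
            "timepoint": tp,
            "domain": domain,
            "auc": auc(curve),
            "truncated": curve.truncated,
            "mean_within": seg.mean_within,
            "mean_between": seg.mean_between,
            "segregation": seg.segregation,
        }
        if compute_q:
            row["q"], _ = modularity_q(pos)
        rows.append(row)
        if collect_curves:
            for t, w, b in zip(curve.thresholds, curve.cutoff_weights, curve.b0_values):
                curve_rows.append(
                    {
                        "participant": pid,
                        "timepoint": tp,
                        "domain": domain,
                        "mode": curve.mode,
                        "threshold": t,
                        "cutoff_weight": w,
                        "b0": int(b),
                    }
                )
    measures = pd.DataFrame(rows)
    if collect_curves:
        return measures, pd.DataFrame(curve_rows)
    return measures


def assemble_cohort_table(
    covariates: pd.DataFrame,
    behavior: pd.DataFrame,
    measures: pd.DataFrame,
) -> pd.DataFrame:
    """One row per participant with per-domain measures at both timepoints."""
    table = covariates.set_index("participant").copy()
    beh = behavior.pivot(index="participant", columns="domain")
    for domain in behavior["domain"].unique():
        table[f"behavior_bl_{domain}"] = beh[("behavior_bl", domain)]
        table[f"behavior_fu_{domain}"] = beh[("behavior_fu", domain)]
    value_cols = [
        c for c in ("auc", "segregation", "q") if c in measures.columns
    ]
    wide = measures.pivot_table(
        index="participant", columns=["timepoint", "domain"], values=value_cols
    )
    rename = {"segregation": "seg"}
    for domain in measures["domain"].unique():
        for tp in TIMEPOINTS:
            for col in value_cols:
                key = (col, tp, domain)
                if key in wide.columns:
                    table[f"{rename.get(col, col)}_{tp}_{domain}"] = wide[key]
    return table.reset_index()


def cohort_table(cohort: SyntheticCohort, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Convenience: measures + assembly straight from a synthetic cohort."""
    config = config or AnalysisConfig()
    measures = compute_measures(
        cohort.data,
        cohort.partition,
        step=config.step,
        mode=config.filtration_mode,
        include_zeros=config.include_zero_edges,
        compute_q=config.compute_q,
    )
    return assemble_cohort_table(cohort.covariates, cohort.behavior, measures)


# --------------------------------------------------------------------------
# model battery


def _adjusted_measure(table: pd.DataFrame, col: str, scrub: str) -> pd.Series:
    """Scrubbing-adjusted brain measure (NaNs preserved through listwise use)."""
    vals = table[col].to_numpy(dtype=float)
    scr = table[scrub].to_numpy(dtype=float)
    keep = np.isfinite(vals) & np.isfinite(scr)
    out = np.full_like(vals, np.nan)
    if keep.sum() >= 3:
        out[keep] = remove_scrubbing(vals[keep], scr[keep])
    return pd.Series(out, index=table.index)


def _residual_change(table: pd.DataFrame, bl: pd.Series, fu: pd.Series) -> pd.Series:
    bl_v = bl.to_numpy(dtype=float)
    fu_v = fu.to_numpy(dtype=float)
    keep = np.isfinite(bl_v) & np.isfinite(fu_v)
    out = np.full_like(bl_v, np.nan)
    if keep.sum() >= 3:
        out[keep] = residualize_on_baseline(fu_v[keep] - bl_v[keep], bl_v[keep])
    return pd.Series(out, index=table.index)


def _domain_variables(table: pd.DataFrame, domain: str) -> dict:
    """All per-contrast outcomes and predictors for one domain."""
    scrub = f"scrub_{domain}"
    v: dict = {}
    for meas in ("auc", "seg"):
        bl = _adjusted_measure(table, f"{meas}_bl_{domain}", scrub)
        fu = _adjusted_measure(table, f"{meas}_fu_{domain}", scrub)
        v[f"{meas}_bl"] = bl
        v[f"{meas}_fu"] = fu
        v[f"{meas}_delta"] = _residual_change(table, bl, fu)
    v["behavior_bl"] = table[f"behavior_bl_{domain}"]
    v["behavior_fu"] = table[f"behavior_fu_{domain}"]
    v["behavior_delta"] = _residual_change(
        table, table[f"behavior_bl_{domain}"], table[f"behavior_fu_{domain}"]
    )
    v["ct_bl"], v["ct_fu"] = table["ct_bl"], table["ct_fu"]
    v["ct_delta"] = _residual_change(table, table["ct_bl"], table["ct_fu"])
    v["wmh_bl"], v["wmh_fu"] = table["wmh_bl"], table["wmh_fu"]
    v["wmh_delta"] = _residual_change(table, table["wmh_bl"], table["wmh_fu"])
    return v


def _predictor_frame(table: pd.DataFrame, v: dict, contrast: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": table["age"],
            "nart": table["nart"],
            "education": table["education"],
            "sex": table["sex"],
            "ct": v[f"ct_{contrast}"],
            "wmh": v[f"wmh_{contrast}"],
        }
    )


def run_full_analysis(
    table: pd.DataFrame,
    domains,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Fit the full per-domain model battery and FDR-correct per domain.

    Returns a long table (domain, outcome, time, predictor, n, beta, coef,
    ci_low, ci_high, p, fdr_p, eta_p2) whose per-domain blocks each contain
    ``FAMILY_SIZE`` predictor rows.
    """
    config = config or AnalysisConfig()
    all_rows = []
    for domain in domains:
        v = _domain_variables(table, domain)
        rows = []
        for contrast in CONTRASTS:
            base = _predictor_frame(table, v, contrast)
            # brain-measure models: 6 predictors each
            for meas, label in (("auc", "AUC"), ("seg", "SEG")):
                res = fit_model(v[f"{meas}_{contrast}"], base, outcome_name=label)
                rows.extend(_result_rows(res, domain, label, contrast))
            # behavior models: base + one brain measure, 7 predictors each
            for meas, label in (("auc", "BEH_AUC"), ("seg", "BEH_SEG")):
                preds = base.copy()
                preds[meas] = v[f"{meas}_{contrast}"]
                res = fit_model(
                    v[f"behavior_{contrast}"], preds, outcome_name=label
                )
                rows.extend(_result_rows(res, domain, label, contrast))
        block = pd.DataFrame(rows)
        adj, rej = fdr_family(block["p"].to_numpy(), q=config.fdr_q)
        block["fdr_p"] = adj
        block["fdr_reject"] = rej
        all_rows.append(block)
    return pd.concat(all_rows, ignore_index=True)


def _result_rows(res, domain, outcome_label, contrast):
    time_label = {"bl": "BL", "fu": "FU", "delta": "FU-BL"}[contrast]
    rows = []
    for pred, r in res.params.iterrows():
        rows.append(
            {
                "domain": domain,
                "outcome": outcome_label,
                "time": time_label,
                "predictor": pred,
                "n": res.n,
                "beta": r["beta_std"],
                "coef": r["coef"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "p": r["p"],
                "eta_p2": r["eta_p2"],
            }
        )
    return rows


# --------------------------------------------------------------------------
# post-hoc analyses (change-in-AUC effect on change in cognition)


def _delta_frame(table: pd.DataFrame, domain: str) -> pd.DataFrame:
    v = _domain_variables(table, domain)
    df = pd.DataFrame(
        {
            "age": table["age"],
            "nart": table["nart"],
            "education": table["education"],
            "sex": table["sex"],
            "ct": v["ct_delta"],
            "wmh": v["wmh_delta"],
            "auc": v["auc_delta"],
            "behavior": v["behavior_delta"],
        }
    )
    return df.dropna()


def run_permutation(
    table: pd.DataFrame,
    domain: str,
    target: str = "auc",
    config: AnalysisConfig | None = None,
) -> dict:
    """Permutation p for a predictor of change in behavior (default dAUC)."""
    config = config or AnalysisConfig()
    df = _delta_frame(table, domain)
    preds = df.drop(columns="behavior")
    p = permutation_test(
        df["behavior"], preds, target, n_perm=config.n_perm, seed=config.seed
    )
    return {"domain": domain, "target": target, "p": p, "n_perm": config.n_perm,
            "seed": config.seed, "n": len(df)}


def run_mediation(
    table: pd.DataFrame,
    domain: str,
    config: AnalysisConfig | None = None,
) -> MediationResult:
    """Mediation of the age -> change-in-behavior effect through change in AUC."""
    config = config or AnalysisConfig()
    df = _delta_frame(table, domain)
    return mediation_bootstrap(
        df["age"],
        df["auc"],
        df["behavior"],
        covariates=df[["nart", "education", "sex", "ct", "wmh"]],
        n_boot=config.n_boot,
        seed=config.seed,
    )


def run_bic_search(table: pd.DataFrame, domain: str):
    """Exhaustive BIC search over the 7 change-model predictors (127 fits)."""
    df = _delta_frame(table, domain)
    return bic_search(df["behavior"], df.drop(columns="behavior"),
                      outcome_name=f"delta_behavior_{domain}")
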