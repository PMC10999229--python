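"""Post-hoc battery for the fluid-reasoning domain.

Four robustness checks of the change-in-AUC effect on change in cognition:
a joint-row permutation test, a split-sample analysis repeating the model
on each half of the time series, percentile-bootstrap mediation of the age
effect through change in AUC, and the exhaustive 127-model BIC search.
Writes results/posthoc_fluid.json and results/bic_ranking.csv.
"""

import dataclasses
import json

from common import ANALYSIS_CONFIG, RESULTS, build_cohort, build_table

import topoconn as tc


def split_sample(cohort, half: int):
    """Recompute measures from one half of every time series and refit the
    change-in-behavior model."""
    halves = {
        key: tc.split_timeseries(ts, 2)[half] for key, ts in cohort.data.items()
    }
    measures = tc.compute_measures(halves, cohort.partition)
    table = tc.assemble_cohort_table(cohort.covariates, cohort.behavior, measures)
    res = tc.run_full_analysis(table, ["fluid"], ANALYSIS_CONFIG)
    row = res[(res.time == "FU-BL") & (res.outcome == "BEH_AUC")
              & (res.predictor == "auc")].iloc[0]
    return {"beta": float(row.beta), "p": float(row.p), "fdr_p": float(row.fdr_p)}


def main():
    cohort = build_cohort()
    table, _, _ = build_table(cohort)

    perm = tc.run_permutation(table, "fluid", config=ANALYSIS_CONFIG)
    print(f"permutation: dAUC -> dCognition p={perm['p']:.4f} "
          f"({perm['n_perm']} shuffles, n={perm['n']})")

    splits = [split_sample(cohort, h) for h in (0, 1)]
    for name, s in zip(("first", "second"), splits):
        print(f"split-sample {name} half: beta={s['beta']:+.3f} p={s['p']:.4f}")

    med = tc.run_mediation(table, "fluid", config=ANALYSIS_CONFIG)
    print(f"mediation: ACME={med.acme:+.4f} CI=({med.acme_ci[0]:+.4f}, "
          f"{med.acme_ci[1]:+.4f}) p={med.acme_p:.4f}; "
          f"direct={med.direct:+.4f}; proportion={med.proportion:.3f}")

    ranking, winner = tc.run_bic_search(table, "fluid")
    ranking.to_csv(RESULTS / "bic_ranking.csv", index=False)
    print(f"BIC search: {len(ranking)} models; winner "
          f"{ranking.loc[0, 'predictors']} (adj R2={winner.adj_r2:.3f})")

    with open(RESULTS / "posthoc_fluid.json", "w") as fh:
        json.dump(
            {"permutation": perm,
             "split_sample": {"first": splits[0], "second": splits[1]},
             "mediation": dataclasses.asdict(med),
             "bic_winner": ranking.loc[0, "predictors"]},
            fh, indent=2, default=float,
        )
    print(f"written to {RESULTS}")


if __name__ == "__main__":
    main()
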