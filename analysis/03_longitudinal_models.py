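"""Fit the full longitudinal model battery.

Per domain: AUC and segregation models (baseline, follow-up, change) on the
demographic + brain-integrity predictors, and behavior models adding each
brain measure — 78 predictor p-values per domain, FDR-corrected as one
family.  Writes the results table and prints the change-model effects the
generator programmed.
"""

from common import ANALYSIS_CONFIG, COHORT_CONFIG, RESULTS, build_table

import topoconn as tc


def main():
    table, _, _ = build_table()
    results = tc.run_full_analysis(table, list(COHORT_CONFIG.domains), ANALYSIS_CONFIG)
    RESULTS.mkdir(parents=True, exist_ok=True)
    results.to_csv(RESULTS / "model_results.tsv", sep="\t", index=False)

    print(f"{len(results)} predictor rows "
          f"({tc.FAMILY_SIZE} per domain, FDR within domain)")
    delta = results[results.time == "FU-BL"]
    for _, r in delta.iterrows():
        interesting = (
            (r.outcome in ("AUC", "SEG") and r.predictor == "age")
            or (r.outcome == "BEH_AUC" and r.predictor == "auc")
            or (r.outcome == "BEH_SEG" and r.predictor == "seg")
        )
        if interesting:
            print(f"  {r.domain:6s} {r.outcome:8s} {r.predictor:4s} "
                  f"beta={r.beta:+.3f}  p={r.p:.2e}  fdr_p={r.fdr_p:.2e}")
    sig = results[results.fdr_reject]
    print(f"{len(sig)} effects significant at FDR q=0.05 across "
          f"{results.domain.nunique()} domains")


if __name__ == "__main__":
    main()
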