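"""Simulate the synthetic longitudinal cohort and record its ground truth.

Writes the small text artifacts (covariates, behavior, latent truth,
partition) under results/cohort/ and prints the cohort's demographic
summary.  The imaging time series are fully determined by the seed and are
regenerated in memory by the later scripts.
"""

from common import COHORT_CONFIG, RESULTS, build_cohort


def main():
    cohort = build_cohort()
    out = RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    cohort.behavior.to_csv(out / "behavior.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    cohort.partition.write_csv(out / "partition.csv")

    cov = cohort.covariates
    print(f"cohort: {len(cov)} participants, 2 timepoints, "
          f"{len(COHORT_CONFIG.domains)} domains "
          f"({COHORT_CONFIG.n_nodes} nodes / {COHORT_CONFIG.n_networks} networks)")
    print(f"age {cov.age.mean():.1f} +- {cov.age.std():.1f} "
          f"(range {cov.age.min():.0f}-{cov.age.max():.0f}); "
          f"{int(cov.sex.sum())} of one sex; "
          f"education {cov.education.mean():.1f} y; NART {cov.nart.mean():.1f}")
    print(f"programmed: coupling decline {COHORT_CONFIG.seg_decline_slope}/yr, "
          f"behavior slopes age={COHORT_CONFIG.beta_age_behavior}, "
          f"topology={COHORT_CONFIG.beta_auc_behavior}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
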