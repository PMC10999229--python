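# Methods

## Scientific setting

`topoconn` implements a participant-level topological analysis of functional
brain connectivity and the longitudinal inference chain built on top of it.
The setting it targets is a two-timepoint (baseline and ~5-year follow-up)
ageing cohort in which each participant contributes, per cognitive domain,
an in-scanner task fMRI time series summarised as a node-by-node Pearson
correlation matrix over a fixed parcellation (canonically 264 nodes grouped
into 14 functional networks), plus demographics (age, sex, education, a
NART IQ estimate), brain-integrity covariates (mean cortical thickness, WMH
volume), per-domain motion scrubbing, and a z-scaled behavioral score per
domain at both timepoints.

## Connectivity

Pairwise Pearson correlations between node time series are Fisher
z-transformed, `z = atanh(r)`, giving a symmetric weight matrix whose
diagonal is excluded everywhere; a 264-node matrix carries
264·263/2 = 34,716 unique pairs. Correlations are clipped to
`|r| ≤ 1 − 1e−7` before `atanh` so degenerate (perfectly correlated)
synthetic inputs stay finite; with real or simulated noisy data the clip
never binds. Matrices with both signs are used for topology; segregation
and modularity use the sparse positive matrix (negative weights set to 0).

## Betti-0 filtration and AUC

The network is swept from empty to connected by an **edge-density
filtration**: at threshold ε the top `⌈ε·E⌉` edges by descending weight are
retained (E = number of unique pairs) and the number of connected
components B₀ is counted with a union-find structure (path compression,
union by size). B₀ equals the node count at ε = 0, is non-increasing, and
reaches 1 once a spanning edge set has entered. The participant-level
summary is the trapezoidal area under the B₀ curve from ε = 0 to the first
grid point with B₀ = 1, on a grid of step 0.01 by default.

Numerical conventions:

* The retained set is defined by **rank**, not by a weight inequality; ties
  are broken by node-index order so results are deterministic. For
  continuous weights ties have measure zero and the rank rule coincides
  with "weight strictly greater than the cutoff" up to the single boundary
  edge.
* The cutoff weight W at density ε is the `⌈ε·E⌉`-th ranked weight
  (`+inf` sentinel at ε = 0, the minimum off-diagonal weight at ε = 1).
* The density percentile runs over the full signed weight distribution;
  because the sweep stops at the first single-component threshold, negative
  edges can only enter while the graph is still disconnected.
* Density-mode curves depend on edge ranks only, so any strictly monotone
  weight transform (raw r vs Fisher z, adding a constant) leaves them
  unchanged. The supplementary **correlation mode** (fixed r cutoffs
  descending in steps of 0.01, stored against ascending 1 − r) does not
  share this invariance; that asymmetry is intended.
* A curve that never reaches B₀ = 1 on its grid (impossible in density mode
  on a complete weight matrix, bounded-grid correlation sweeps aside) is
  returned with a `truncated` diagnostic flag rather than an error.

## System segregation and modularity Q

Segregation = (mean within-network z − mean between-network z) / mean
within-network z, over all unique pairs of the positive-edge matrix under
the a-priori 14-network partition. Zeroed negative edges stay in the means
by default (the denominators are the full pair counts W and B); an
`include_zeros=False` flag restricts the means to strictly positive pairs.
A non-positive within mean raises an error rather than returning an
ill-defined ratio.

Modularity Q (Newman weighted modularity against the degree-preserving
null) is maximised by a fully deterministic pipeline: leading-eigenvector
recursive bisection of the (generalised) modularity matrix, a
Kernighan–Lin-style per-split refinement that moves every vertex once and
keeps the best intermediate state, then greedy single-node sweeps
(including moves to a new singleton community) and pairwise community
merges until no move improves Q. Ties resolve to the lowest index, so
repeated calls return the identical (Q, partition). On graphs of ≤ 8 nodes
the result matches exhaustive search over all set partitions in our tests;
on larger graphs determinism rather than global optimality is the
contract. The detected partition is agnostic to the a-priori network
labels.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; it
is the package's test bed, not a biophysical simulator.

* **Signals.** Node i's series is
  `a·f_{c(i)}(t) + b·g(t) + ε_i(t)` with community factors f, a global
  factor g, and unit-variance noise — the minimal generative model that
  produces the block-modular correlation structure the segregation measure
  assumes. Implied correlations: within `(a²+b²)/(a²+b²+1)`, between
  `b²/(a²+b²+1)`.
* **Defaults** `a = 0.65`, `b = 0.3` give within-r ≈ 0.34 and between-r ≈
  0.06, typical task-FC magnitudes. This loading regime was also chosen
  because the density-filtration AUC responds to coupling only through the
  overlap of the within- and between-edge weight distributions (ranks are
  all that matter): the dose–response of AUC in `a` is steepest near 0.65
  and flattens above 0.8, so the default sits where the measure is
  informative.
* **Longitudinal change.** At follow-up participant p's community loading
  becomes `a + s·(age_p − mean age) + η_p`, with `s = seg_decline_slope =
  −0.004`/year (age-graded decline) and `η_p ~ N(0, 0.08)` a
  participant-specific, age-independent component of the latent topology
  change. η is essential: without it the latent change would be an exact
  function of age and no regression could separate the age path from the
  topology path. Loadings are floored at zero.
* **Behavior.** Per domain, `Δz = β_age·(age − mean age) + β_topo·Δa_p +
  β_NART·(NART − mean) + N(0, σ)` with defaults β_age = −0.012/yr,
  β_topo = 2.5 per loading unit, β_NART = 0.02, σ = 0.25; baseline z is
  standard normal. Scores are emitted directly on the z scale the analysis
  uses.
* **Covariates.** Age uniform on 20–80 (the decade brackets of typical
  cohort tables are a reporting convenience, not a modelling claim); sex
  Bernoulli(½); education N(16, 2.4) y; NART N(117, 8); per-domain
  scrubbing N(0.45, 0.12) truncated; CT N(2.5, 0.10) mm with a small
  decline at follow-up; WMH log-normal with a programmed median increase.
  Covariates are drawn independently — their empirical covariance is
  deliberately not modelled, and null-calibration results should be read
  with that in mind.
* One task per domain per timepoint is simulated (real batteries average
  several tasks; averaging derived measures is a thin extension).
* `data_mode` selects time series (default), precomputed matrices, or no
  imaging data at all (for calibration studies that only need covariates
  and behavior). A single seed drives everything; identical configurations
  are bit-identical.

What passing recovery tests on this generator shows: that the pipeline
detects programmed age-graded topology decline and a programmed
topology→behavior coupling at realistic effect and sample sizes, with
calibrated nulls. What it does not show: anything about scanner noise
spectra, motion, task structure, spatial embedding, or empirical covariate
correlations, none of which are modelled.

## Inference chain

* Behavioral standardization uses baseline mean/SD per task (follow-up
  scores keep the baseline norms); reaction-time domains are sign-inverted.
* Change scores (follow-up − baseline) of any measure observed at both
  timepoints — behavior, AUC, segregation, CT, WMH — are residualized on
  their baseline values. Scrubbing variance is removed from every brain
  measure before modelling. Interpreting "both-timepoint factors" as
  including ΔCT and ΔWMH is a documented reading.
* OLS models report standardized betas (`b·SD(x)/SD(y)`), raw-coefficient
  95% t CIs (a standardized-scale CI would be incompatible with reporting
  both), p values, and partial eta-squared computed as `t²/(t² + df_res)`,
  which equals SS_effect/(SS_effect+SS_error) for a single-df term.
  Listwise deletion applies per model.
* The per-domain battery is 2 brain measures × 3 contrasts × 6 predictors
  plus 2 behavior variants × 3 contrasts × 7 predictors = **78 p-values**,
  corrected together by Benjamini–Hochberg as one family per domain.
* The permutation test shuffles whole predictor rows jointly against the
  outcome (10,000 permutations by default); the statistic is the target
  predictor's |standardized beta| (a documented, swappable choice), and p
  is the literal exceedance ratio, so the minimum attainable p is 0; a
  `(+1)/(N+1)` flag exists but defaults off. Internally the shuffle is
  applied to the outcome through the inverse permutation against a fixed
  pseudoinverse — algebraically identical and ~100× faster; a test verifies
  the equivalence against literal row shuffling.
* Mediation is product-of-coefficients ACME with a percentile bootstrap
  over whole participant rows (10,000 resamples by default), covariates
  held in both path models; direct + ACME = total exactly for nested OLS.
  The ACME p-value is the two-sided percentile position of zero — one of
  several conventions, adopted and documented.
* The BIC search fits every non-empty subset of the seven change-model
  predictors (127 models) under the standard Gaussian-profile OLS BIC with
  the intercept always included, so subsets are comparable.

## Problem sizes

The analysis scripts and the acceptance script run at reduced scale —
120–160 participants, 60–120 nodes, 200-sample series, one or two domains —
sizes at which every qualitative property of the full-scale setting
(modular structure, age-graded decline, calibrated nulls) is preserved and
a complete run takes seconds to minutes on one CPU. Calibration studies use
200 seeds × 500 permutations; the recovery study uses 100 seeds at 160
participants, 60 nodes, 6 networks.

## Known limitations

* The modularity maximiser is deterministic but heuristic beyond ~10 nodes;
  it is a comparator, not the core measure.
* The generator's independence assumptions (covariates, domains) make some
  null calibrations easier than real data would be.
* Correlation-mode filtration is provided for sensitivity analysis only;
  all defaults and tests centre on density mode.
* No homology above dimension 0 (no loops or voids, no barcodes beyond the
  B₀ curve), and no preprocessing of raw imaging data: matrices or time
  series are the entry point.
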