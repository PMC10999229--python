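"""Synthetic longitudinal cohorts with block-modular connectivity.

The generator emulates the statistical structure that the downstream
analysis assumes, at the study conditions of a two-timepoint ageing cohort
(163 adults aged 20-80, 264-node / 14-network parcellation, in-scanner task
series of ~430 samples):

* **Node signals** follow a factor model: each node loads on its community
  factor with weight ``within_coupling`` and on a global factor with weight
  ``between_coupling``, plus unit-variance Gaussian noise.  With loadings
  (a, b) the implied within-community correlation is
  ``(a^2 + b^2) / (a^2 + b^2 + 1)`` and the between-community correlation is
  ``b^2 / (a^2 + b^2 + 1)``, so ``within_coupling > between_coupling >= 0``
  yields the block-modular structure the segregation measure assumes.
* **Age-graded decline**: at follow-up the community loading of participant
  ``p`` becomes ``a + seg_decline_slope * (age_p - mean_age) + eta_p`` with
  ``eta_p ~ N(0, seg_noise_sd)``.  A negative slope programs steeper loss of
  within-community coupling with age; ``eta_p`` is the participant-specific,
  age-independent component of the latent topology change (without it the
  latent change would be an exact function of age and no analysis could
  separate the two).
* **Behavioral change** per domain is linear in age, in the latent coupling
  change, and in NART, plus Gaussian noise; behaviour is emitted directly on
  the z scale used by the analysis.
* **Covariates** (sex, education, NART, per-domain scrubbing, cortical
  thickness, WMH volume at both timepoints) are drawn independently with
  realistic ranges; their empirical covariance is deliberately not modelled.

Everything is driven by a single seed; identical configurations reproduce
the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import TimeSeries, correlation_matrix
from .errors import InvalidConfigError
from .partition import NetworkPartition

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_partition",
    "simulate_timeseries",
    "simulate_cohort",
]

TIMEPOINTS = ("bl", "fu")
DEFAULT_DOMAINS = ("mem", "fluid", "speed", "vocab")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults reflect the emulated study conditions.

    ``seg_decline_slope`` is in loading units per year (negative = age-graded
    loss of within-community coupling at follow-up); ``beta_age_behavior`` in
    z units per year; ``beta_auc_behavior`` in z units per loading unit of
    latent topology change; ``beta_nart_behavior`` in z units per NART point.
    """

    n_participants: int = 163
    n_nodes: int = 264
    n_networks: int = 14
    series_length: int = 430
    domains: tuple = DEFAULT_DOMAINS
    within_coupling: float = 0.65
    between_coupling: float = 0.3
    age_range: tuple = (20.0, 80.0)
    seg_decline_slope: float = -0.004
    seg_noise_sd: float = 0.08
    beta_age_behavior: float = -0.012
    beta_auc_behavior: float = 2.5
    beta_nart_behavior: float = 0.02
    noise_sd: float = 0.25
    data_mode: str = "timeseries"
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if not (self.n_nodes >= self.n_networks >= 2):
            raise InvalidConfigError(
                f"need n_nodes >= n_networks >= 2, got "
                f"{self.n_nodes} nodes / {self.n_networks} networks"
            )
        if self.data_mode != "none" and self.series_length < 10:
            raise InvalidConfigError("series_length must be >= 10")
        if not (self.within_coupling > self.between_coupling >= 0):
            raise InvalidConfigError(
                "need within_coupling > between_coupling >= 0 "
                f"(got {self.within_coupling}, {self.between_coupling})"
            )
        if self.age_range[0] >= self.age_range[1]:
            raise InvalidConfigError("age_range must be (low, high) with low < high")
        if self.data_mode not in ("timeseries", "matrices", "none"):
            raise InvalidConfigError(f"unknown data_mode {self.data_mode!r}")
        if len(self.domains) == 0:
            raise InvalidConfigError("at least one domain required")

    @property
    def mean_age(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass
class SyntheticCohort:
    """Generated cohort: covariates, behaviour, imaging data, ground truth.

    ``data`` maps ``(participant_id, timepoint, domain)`` to a
    :class:`TimeSeries` or :class:`ConnectivityMatrix` (empty in
    ``data_mode="none"``); ``truth`` holds the realized latent per-participant
    quantities next to the configuration for recovery tests.
    """

    config: SimulationConfig
    partition: NetworkPartition
    covariates: pd.DataFrame
    behavior: pd.DataFrame
    data: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    @property
    def participant_ids(self) -> list:
        return list(self.covariates["participant"])


def simulate_partition(n_nodes: int, n_networks: int, seed: int = 0) -> NetworkPartition:
    """Assign nodes to networks as evenly as divisibility allows.

    With ``n_nodes = q * n_networks + r`` the first ``r`` networks (in label
    order) receive ``q + 1`` nodes and the rest ``q`` — e.g. 264 nodes over
    14 networks gives 12 networks of 19 and 2 of 18.  Deterministic; the
    seed is accepted for interface uniformity only.
    """
    if not (n_nodes >= n_networks >= 2):
        raise InvalidConfigError(
            f"need n_nodes >= n_networks >= 2, got {n_nodes}/{n_networks}"
        )
    q, r = divmod(n_nodes, n_networks)
    labels = []
    for net in range(n_networks):
        labels.extend([f"net{net:02d}"] * (q + 1 if net < r else q))
    return NetworkPartition(tuple(range(n_nodes)), tuple(labels))


def _community_index(partition: NetworkPartition) -> np.ndarray:
    nets = {lab: i for i, lab in enumerate(partition.networks)}
    return np.array([nets[l] for l in partition.labels])


def _factor_series(
    partition: NetworkPartition,
    within: float,
    between: float,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    comm = _community_index(partition)
    n_comm = comm.max() + 1
    community = rng.standard_normal((n_comm, length))
    global_f = rng.standard_normal(length)
    noise = rng.standard_normal((partition.n_nodes, length))
    return within * community[comm] + between * global_f[None, :] + noise


def simulate_timeseries(
    partition: NetworkPartition,
    config: SimulationConfig,
    timepoint: str,
    age: float,
    seed: int,
    coupling_offset: float = 0.0,
) -> TimeSeries:
    """One participant's node-by-time series under the factor model.

    At follow-up the community loading is reduced by
    ``seg_decline_slope * (age - mean_age)`` (plus any ``coupling_offset``,
    used by :func:`simulate_cohort` to inject participant-level noise in the
    coupling change).  Loadings are floored at 0.
    """
    if config.series_length < 10:
        raise InvalidConfigError("series_length must be >= 10")
    if timepoint not in TIMEPOINTS:
        raise InvalidConfigError(f"timepoint must be one of {TIMEPOINTS}")
    within = config.within_coupling
    if timepoint == "fu":
        within = within + config.seg_decline_slope * (age - config.mean_age)
    within = max(within + coupling_offset, 0.0)
    rng = np.random.default_rng(seed)
    values = _factor_series(
        partition, within, config.between_coupling, config.series_length, rng
    )
    return TimeSeries(tuple(partition.node_ids), values)


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    lo, hi = config.age_range
    rows = {
        "participant": [f"p{i:04d}" for i in range(n)],
        "age": np.round(rng.uniform(lo, hi, n), 2),
        "sex": rng.integers(0, 2, n),
        "education": np.clip(np.round(rng.normal(16.0, 2.4, n), 1), 8, 22),
        "nart": np.clip(np.round(rng.normal(117.0, 8.0, n), 1), 85, 140),
        "ct_bl": np.round(rng.normal(2.5, 0.10, n), 4),
        "wmh_bl": np.round(np.exp(rng.normal(0.0, 0.8, n)), 4),
    }
    rows["ct_fu"] = np.round(rows["ct_bl"] - 0.02 + rng.normal(0, 0.02, n), 4)
    rows["wmh_fu"] = np.round(
        rows["wmh_bl"] * np.exp(rng.normal(0.2, 0.3, n)), 4
    )
    for d in config.domains:
        rows[f"scrub_{d}"] = np.clip(
            np.round(rng.normal(0.45, 0.12, n), 4), 0.05, None
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full two-timepoint cohort from a single seed.

    The realized latent coupling change per participant and domain
    (``delta_coupling``) is stored in ``truth`` so recovery tests can compare
    measured topology changes to the programmed ones.
    """
    root = np.random.SeedSequence(config.seed)
    ss_cov, ss_latent, ss_behav, ss_data = root.spawn(4)
    partition = simulate_partition(config.n_nodes, config.n_networks, config.seed)
    covariates = _draw_covariates(config, np.random.default_rng(ss_cov))

    rng_lat = np.random.default_rng(ss_latent)
    rng_beh = np.random.default_rng(ss_behav)
    age = covariates["age"].to_numpy()
    nart = covariates["nart"].to_numpy()
    n = config.n_participants

    truth_rows, behav_rows = [], []
    latent = {}
    for d in config.domains:
        eta = rng_lat.normal(0.0, config.seg_noise_sd, n)
        delta = config.seg_decline_slope * (age - config.mean_age) + eta
        latent[d] = (eta, delta)
        z_bl = rng_beh.standard_normal(n)
        dz = (
            config.beta_age_behavior * (age - config.mean_age)
            + config.beta_auc_behavior * delta
            + config.beta_nart_behavior * (nart - nart.mean())
            + rng_beh.normal(0.0, config.noise_sd, n)
        )
        for i, pid in enumerate(covariates["participant"]):
            truth_rows.append(
                {
                    "participant": pid,
                    "domain": d,
                    "coupling_noise": eta[i],
                    "delta_coupling": delta[i],
                    "delta_behavior_signal": dz[i],
                }
            )
            behav_rows.append(
                {
                    "participant": pid,
                    "domain": d,
                    "behavior_bl": z_bl[i],
                    "behavior_fu": z_bl[i] + dz[i],
                }
            )

    data: dict = {}
    if config.data_mode != "none":
        child_seeds = ss_data.generate_state(
            n * len(config.domains) * 2, dtype=np.uint32
        )
        idx = 0
        for d in config.domains:
            eta, _ = latent[d]
            for i, pid in enumerate(covariates["participant"]):
                for tp in TIMEPOINTS:
                    offset = eta[i] if tp == "fu" else 0.0
                    ts = simulate_timeseries(
                        partition,
                        config,
                        tp,
                        float(age[i]),
                        int(child_seeds[idx]),
                        coupling_offset=offset,
                    )
                    idx += 1
                    if config.data_mode == "matrices":
                        data[(pid, tp, d)] = correlation_matrix(ts)
                    else:
                        data[(pid, tp, d)] = ts

    return SyntheticCohort(
        config=config,
        partition=partition,
        covariates=covariates,
        behavior=pd.DataFrame(behav_rows),
        data=data,
        truth=pd.DataFrame(truth_rows),
    )
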