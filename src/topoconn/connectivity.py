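"""Functional-connectivity matrices from node time series.

Pairwise Pearson correlations between node time series are Fisher
z-transformed (``z = atanh(r)``) into a symmetric weight matrix.  Correlations
are clipped to ``|r| <= 1 - CLIP_EPS`` before the transform so every weight is
finite even for exactly (anti)correlated synthetic signals.  The diagonal is
excluded from all downstream computations; a 264-node matrix therefore carries
264*263/2 = 34,716 unique connectivity pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidParameterError,
    ValidationError,
)

#: Correlations are clipped to 1 - CLIP_EPS in magnitude before atanh.
CLIP_EPS = 1e-7

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class TimeSeries:
    """Node-by-time real matrix with ordered node ids.

    ``sampling_step`` (seconds per sample) is informational only.
    """

    node_ids: tuple
    values: np.ndarray
    sampling_step: float = 2.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("time series values must be a 2-D node x time array")
        if len(self.node_ids) != values.shape[0]:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for {values.shape[0]} rows"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node-by-node matrix of Fisher-z connectivity weights."""

    node_ids: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weights must be a square matrix")
        if len(self.node_ids) != w.shape[0]:
            raise ValidationError("node ids do not match matrix size")
        if not np.all(np.isfinite(w)):
            raise ValidationError("connectivity weights must be finite")
        if not np.allclose(w, w.T, atol=_SYM_TOL, rtol=0.0):
            raise ValidationError("connectivity matrix is not symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of unique off-diagonal pairs, n(n-1)/2."""
        n = self.n_nodes
        return n * (n - 1) // 2

    def pair_weights(self) -> np.ndarray:
        """Upper-triangle weights (one entry per unique pair)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.node_ids), columns=list(self.node_ids)
        )


def correlation_matrix(ts: TimeSeries, clip: float = 1.0 - CLIP_EPS) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of node rows, Fisher z-transformed.

    Parameters
    ----------
    ts
        Node-by-time series; every row must be non-constant and at least 3
        samples long.
    clip
        Magnitude at which correlations are clipped before ``atanh``
        (must be < 1 so the output is finite).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 time samples.
    DegenerateInputError
        A node row has zero variance; the error names the node.
    """
    if not (0 < clip < 1):
        raise InvalidParameterError(f"clip must lie in (0, 1), got {clip}")
    if ts.n_samples < 3:
        raise InsufficientDataError(
            f"need at least 3 samples to correlate, got {ts.n_samples}"
        )
    dead = np.flatnonzero(np.ptp(ts.values, axis=1) == 0)
    if dead.size:
        names = ", ".join(str(ts.node_ids[i]) for i in dead[:5])
        raise DegenerateInputError(f"constant (zero-variance) node row(s): {names}")
    r = np.corrcoef(ts.values)
    r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # kill float asymmetry from corrcoef
    np.fill_diagonal(z, 0.0)  # diagonal excluded from all computations
    return ConnectivityMatrix(tuple(ts.node_ids), z)


def positive_part(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero out negative edge weights (sparse positive matrix convention)."""
    return ConnectivityMatrix(m.node_ids, np.maximum(m.weights, 0.0))


def split_timeseries(ts: TimeSeries, n_segments: int = 2) -> list[TimeSeries]:
    """Split into contiguous, order-preserving segments covering all samples.

    When the length is not divisible, earlier segments receive the extra
    samples (length 9 in 2 segments -> 5, 4).
    """
    if n_segments < 1:
        raise InvalidParameterError("n_segments must be >= 1")
    if ts.n_samples < 3 * n_segments:
        raise InsufficientDataError(
            f"series of length {ts.n_samples} too short for "
            f"{n_segments} segments of >= 3 samples"
        )
    base, extra = divmod(ts.n_samples, n_segments)
    lengths = [base + (1 if k < extra else 0) for k in range(n_segments)]
    bounds = np.cumsum([0] + lengths)
    return [
        TimeSeries(ts.node_ids, ts.values[:, bounds[k] : bounds[k + 1]], ts.sampling_step)
        for k in range(n_segments)
    ]


def read_timeseries_csv(path) -> TimeSeries:
    """Read a wide CSV: first column node id, remaining columns samples."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"time series file {path}: no sample columns")
    node_ids = tuple(df.iloc[:, 0])
    return TimeSeries(node_ids, df.iloc[:, 1:].to_numpy(dtype=float))


def write_timeseries_csv(ts: TimeSeries, path) -> None:
    df = pd.DataFrame(ts.values)
    df.insert(0, "node_id", list(ts.node_ids))
    df.to_csv(path, index=False)


def read_matrix_csv(path) -> ConnectivityMatrix:
    """Read a square CSV with a header row of node ids."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"matrix file {path}: not square ({df.shape})")
    # CSV headers are strings; restore integer node ids where applicable
    ids = tuple(
        int(c) if str(c).lstrip("-").isdigit() else c for c in df.columns
    )
    return ConnectivityMatrix(ids, df.to_numpy(dtype=float))


def write_matrix_csv(m: ConnectivityMatrix, path) -> None:
    m.to_frame().to_csv(path)
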