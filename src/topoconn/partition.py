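"""Node-to-network partitions.

A :class:`NetworkPartition` assigns every node of a parcellation to exactly
one functional network (community).  The reference scheme this package
emulates is a 264-node parcellation organised into 14 networks; the type is
agnostic to the particular atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InvalidConfigError, ValidationError


@dataclass(frozen=True)
class NetworkPartition:
    """Mapping from node id to network label.

    Parameters
    ----------
    node_ids
        Ordered node identifiers; the order defines matrix row/column order.
    labels
        Network label per node, aligned with ``node_ids``.

    Partitions used for segregation need at least two non-empty networks
    (enforced where such partitions are built or read); community detection
    may legitimately return a single community on an indivisible network.
    """

    node_ids: tuple
    labels: tuple
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(self.node_ids) != len(self.labels):
            raise InvalidConfigError("node_ids and labels differ in length")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise InvalidConfigError("duplicate node ids in partition")
        if len(self.labels) == 0:
            raise InvalidConfigError("empty partition")
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.node_ids)}
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def networks(self) -> tuple:
        """Distinct network labels in first-appearance order."""
        seen = dict.fromkeys(self.labels)
        return tuple(seen)

    @property
    def n_networks(self) -> int:
        return len(set(self.labels))

    def label_of(self, node_id) -> object:
        return self.labels[self._index[node_id]]

    def members(self, label) -> tuple:
        return tuple(n for n, l in zip(self.node_ids, self.labels) if l == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.node_ids, "network_label": self.labels})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_partition(path) -> NetworkPartition:
    """Read a two-column CSV (node_id, network_label)."""
    df = pd.read_csv(Path(path))
    required = {"node_id", "network_label"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"partition file {path}: missing columns {sorted(required - set(df.columns))}"
        )
    part = NetworkPartition(tuple(df["node_id"]), tuple(df["network_label"]))
    if part.n_networks < 2:
        raise ValidationError(
            f"partition file {path}: needs at least 2 networks for segregation"
        )
    return part
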