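"""Study design and network scheme containers.

The experimental unit throughout the package is the *design cell*: one of the
four (drug condition x scan half) combinations measured for every participant
in a placebo-controlled within-subject design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed (drug, half) cell order used for labels, confusion matrices and
#: tie-breaking everywhere in the package.
CELLS: tuple[tuple[str, str], ...] = (
    ("placebo", "first"),
    ("placebo", "second"),
    ("drug", "first"),
    ("drug", "second"),
)

#: The eight canonical resting-state network labels (medial frontal,
#: frontoparietal, default mode, subcortical-cerebellum, somatosensory-motor,
#: medial visual, occipital pole, lateral visual).
DEFAULT_NETWORKS: tuple[str, ...] = (
    "MF", "FP", "DM", "SubC", "SM", "MedV", "OccP", "LatV",
)


def cell_label(drug: str, half: str) -> str:
    return f"{drug}_{half}"


CELL_LABELS: tuple[str, ...] = tuple(cell_label(d, h) for d, h in CELLS)


@dataclass(frozen=True)
class NetworkScheme:
    """Assignment of nodes to networks.

    Parameters
    ----------
    node_to_network
        Mapping from node identifier to network label.
    networks
        Ordered network labels. With K networks the scheme induces K
        within-network edge sets and K*(K-1)/2 between-network pairs.
    """

    node_to_network: dict[str, str]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = set(self.node_to_network.values())
        missing = labels - set(self.networks)
        if missing:
            raise ValueError(f"nodes assigned to unknown networks: {sorted(missing)}")
        empty = [n for n in self.networks if n not in labels]
        if empty:
            raise ValueError(f"empty networks in scheme: {empty}")

    @classmethod
    def balanced(
        cls,
        nodes_per_network: int = 5,
        networks: tuple[str, ...] = DEFAULT_NETWORKS,
    ) -> "NetworkScheme":
        """Balanced scheme: ``nodes_per_network`` nodes in each network."""
        mapping = {
            f"{net}_{i + 1:02d}": net
            for net in networks
            for i in range(nodes_per_network)
        }
        return cls(node_to_network=mapping, networks=tuple(networks))

    @property
    def node_ids(self) -> list[str]:
        """Node identifiers ordered by network then label."""
        order = {net: k for k, net in enumerate(self.networks)}
        return sorted(self.node_to_network, key=lambda n: (order[self.node_to_network[n]], n))

    @property
    def n_nodes(self) -> int:
        return len(self.node_to_network)

    @property
    def between_pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.networks, 2))

    @property
    def interactions(self) -> list[tuple[str, ...]]:
        """The K within-sets followed by the K(K-1)/2 between-pairs."""
        return [("within", n) for n in self.networks] + [
            ("between", a, b) for a, b in self.between_pairs
        ]

    def labels_for(self, node_ids: list[str]) -> np.ndarray:
        return np.array([self.node_to_network[n] for n in node_ids])

    def edge_interaction_index(self, node_ids: list[str]) -> dict[tuple[str, ...], np.ndarray]:
        """Map each interaction to the flat indices of its edges.

        Edges are the upper triangle (i < j) of the node ordering given,
        flattened row-major — the vectorization used for connectome features
        and long-format edge tables.
        """
        labels = self.labels_for(node_ids)
        iu, ju = np.triu_indices(len(node_ids), k=1)
        li, lj = labels[iu], labels[ju]
        index: dict[tuple[str, ...], np.ndarray] = {}
        for net in self.networks:
            index[("within", net)] = np.flatnonzero((li == net) & (lj == net))
        for a, b in self.between_pairs:
            mask = ((li == a) & (lj == b)) | ((li == b) & (lj == a))
            index[("between", a, b)] = np.flatnonzero(mask)
        return index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": self.node_ids,
             "network_label": [self.node_to_network[n] for n in self.node_ids]}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        mapping = dict(zip(df["node_id"], df["network_label"]))
        networks = tuple(pd.unique(df["network_label"]))
        return cls(node_to_network=mapping, networks=networks)


@dataclass(frozen=True)
class StudyDesign:
    """Participants x (drug x half) design with per-half scan length.

    ``timepoints_per_half`` is the number of volumes in each scan half; DCC
    estimation requires at least 30.
    """

    participants: tuple[str, ...] = tuple(f"sub-{i + 1:02d}" for i in range(12))
    timepoints_per_half: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timepoints_per_half < 30:
            raise ValueError("timepoints_per_half must be >= 30 for DCC estimation")
        if len(set(self.participants)) != len(self.participants):
            raise ValueError("duplicate participant identifiers")

    @property
    def cells(self) -> tuple[tuple[str, str], ...]:
        return CELLS

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def scan_keys(self) -> list[tuple[str, str, str]]:
        """All (participant, drug, half) keys — 4 scans per participant."""
        return [(p, d, h) for p in self.participants for d, h in CELLS]


def n_edges(n_nodes: int) -> int:
    """Number of unique undirected edges among ``n_nodes`` nodes."""
    return n_nodes * (n_nodes - 1) // 2
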