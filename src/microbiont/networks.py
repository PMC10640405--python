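"""Ancestral bipartite networks from posterior interaction probabilities.

At a requested age the host lineages crossing that time slice form the rows
of a bipartite network whose edges are the posterior probabilities that the
lineage hosted each ASV; edges below the probability threshold (default
0.70, kept when equal) are discarded and the probability itself is the edge
weight.  Node-level ancestral state reconstruction uses a separate, strict
threshold (default > 0.60).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny, lineage_name, lineages_at_time

__all__ = [
    "AncestralNetwork",
    "build_ancestral_network",
    "asr_node_states",
    "time_point_schedule",
]

NETWORK_THRESHOLD = 0.70  # edges kept iff pp >= threshold
ASR_THRESHOLD = 0.60      # node states kept iff pp > threshold (strict)


@dataclass
class AncestralNetwork:
    """Dated bipartite host-lineage x ASV network with probability weights."""

    time: float
    lineages: list[str]
    asvs: list[str]
    weights: np.ndarray  # (n_lineages, n_asvs); zeros = no edge
    threshold: float
    isolated_asvs: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        kept = self.weights[self.weights > 0]
        if kept.size and kept.min() < self.threshold:
            raise ValueError("edge below threshold survived filtering")

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum())

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, lin in enumerate(self.lineages):
            for j, asv in enumerate(self.asvs):
                if self.weights[i, j] > 0:
                    rows.append({"lineage": lin, "asv": asv,
                                 "weight": self.weights[i, j]})
        return pd.DataFrame(rows, columns=["lineage", "asv", "weight"])

    def to_adjacency(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.lineages,
                            columns=self.asvs)


def build_ancestral_network(pp: pd.DataFrame, time: float,
                            threshold: float = NETWORK_THRESHOLD,
                            drop_isolated: bool = True) -> AncestralNetwork:
    """Threshold a posterior-probability matrix into a dated network.

    ``pp``: DataFrame, rows = lineages at the time slice, columns = ASVs,
    entries in [0, 1].  Interactions with pp strictly below ``threshold``
    are discarded; surviving edges are weighted by pp.  ASVs left without
    any edge are dropped from the network but reported as isolated.
    """
    vals = pp.to_numpy(dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    w = np.where(vals >= threshold, vals, 0.0)
    keep = w.sum(axis=0) > 0
    isolated = [c for c, k in zip(pp.columns, keep) if not k]
    if drop_isolated:
        w = w[:, keep]
        asvs = [c for c, k in zip(pp.columns, keep) if k]
    else:
        asvs = list(pp.columns)
    return AncestralNetwork(
        time=float(time), lineages=list(pp.index), asvs=asvs,
        weights=w, threshold=threshold, isolated_asvs=isolated,
    )


def asr_node_states(pp: pd.DataFrame,
                    threshold: float = ASR_THRESHOLD) -> dict[str, set]:
    """Ancestral repertoires at internal nodes: ASVs with pp > threshold.

    The comparison is strict, so pp exactly at the threshold is excluded.
    """
    vals = pp.to_numpy(dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    out: dict[str, set] = {}
    for node, row in pp.iterrows():
        out[str(node)] = {a for a, p in row.items() if p > threshold}
    return out


def time_point_schedule(tree: Phylogeny, requested=None) -> list[float]:
    """Ages (Ma) at which ancestral networks are reconstructed.

    Default: [2.0, 1.0, 0.0] clipped to ages strictly below the root; a
    custom schedule passes through unchanged but any age at or beyond the
    root is an error.
    """
    root_age = tree.root_age
    if requested is None:
        return [t for t in (2.0, 1.0, 0.0) if t < root_age]
    out = []
    for t in requested:
        if t >= root_age:
            raise ValueError(f"requested age {t} >= root age {root_age}")
        if t < 0:
            raise ValueError(f"negative age {t}")
        out.append(float(t))
    return out


def descent_map_at(tree: Phylogeny, t: float) -> dict[str, set]:
    """Lineage name -> set of extant descendant species at age ``t``."""
    return {lineage_name(tips): set(tips)
            for tips in lineages_at_time(tree, t).values()}
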