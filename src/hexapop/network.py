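"""Chloroplast haplotype calling and Goldstein-distance network analysis.

Distinct cpSSR haplotypes are deduplicated and labelled, connected into a
complete weighted network under the Goldstein distance, and the network is
thresholded at the percolation point: the edge-weight cutoff at which the
network fragments, estimated as the susceptibility peak over the scan of
candidate thresholds.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .distances import goldstein_distance
from .model import Haplotype

logger = logging.getLogger("hexapop")

__all__ = [
    "HaplotypeTable",
    "HaplotypeNetwork",
    "call_haplotypes",
    "count_unique_haplotypes",
    "build_network",
    "percolation_threshold",
    "write_network",
]


def _labels(n: int) -> list[str]:
    """Deterministic haplotype labels AA, AB, ... (widened beyond 676)."""
    width = 2
    while 26 ** width < n:
        width += 1
    gen = itertools.product(string.ascii_uppercase, repeat=width)
    return ["".join(t) for _, t in zip(range(n), gen)]


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with counts and per-data-set frequencies.

    ``table`` is indexed by haplotype id, with one column per locus position
    (``locus_1`` ...), a ``count`` column, and ``count_<ds>`` / ``freq_<ds>``
    columns per data-set label.
    """

    table: pd.DataFrame
    vectors: dict[str, tuple[int, ...]]
    assignment: dict[str, str]  # sample_id -> haplotype id


def call_haplotypes(
    haplotypes: Sequence[Haplotype],
    dataset_of: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Deduplicate repeat-vectors into labelled haplotypes with frequencies.

    Labels are assigned to the lexicographically sorted distinct vectors
    (AA, AB, ...), so the labelling is independent of input row order.
    Haplotypes with a missing locus are excluded with a warning.
    """
    clean: list[Haplotype] = []
    for h in haplotypes:
        if any(r is None or (isinstance(r, float) and np.isnan(r)) for r in h.repeats):
            logger.warning("haplotype of %s has a missing locus; excluded", h.sample_id)
            continue
        clean.append(h)
    if not clean:
        raise ValueError("no callable haplotypes")
    lengths = {len(h.repeats) for h in clean}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent haplotype lengths: {sorted(lengths)}")
    dataset_of = dict(dataset_of or {})
    datasets = sorted(set(dataset_of.values())) or ["ALL"]

    distinct = sorted({h.repeats for h in clean})
    labels = _labels(len(distinct))
    vec_to_label = dict(zip(distinct, labels))
    vectors = dict(zip(labels, distinct))
    assignment = {h.sample_id: vec_to_label[h.repeats] for h in clean}

    n_loci = len(distinct[0])
    rows = []
    for label, vec in zip(labels, distinct):
        members = [h for h in clean if h.repeats == vec]
        row: dict[str, object] = {f"locus_{i + 1}": v for i, v in enumerate(vec)}
        row["count"] = len(members)
        for ds in datasets:
            row[f"count_{ds}"] = sum(
                1 for h in members if dataset_of.get(h.sample_id, "ALL") == ds
            )
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(labels, name="haplotype_id"))
    for ds in datasets:
        total = table[f"count_{ds}"].sum()
        table[f"freq_{ds}"] = table[f"count_{ds}"] / total if total else 0.0
    return HaplotypeTable(table, vectors, assignment)


def count_unique_haplotypes(table: HaplotypeTable) -> int:
    """Number of haplotypes that occur exactly once over all data sets."""
    return int((table.table["count"] == 1).sum())


@dataclass
class HaplotypeNetwork:
    """Complete Goldstein-weighted haplotype graph with its percolation
    threshold; the thresholded view keeps edges with weight <= threshold."""

    graph: nx.Graph
    percolation_threshold: float
    mode: str = "mean"

    def thresholded(self, threshold: float | None = None) -> nx.Graph:
        t = self.percolation_threshold if threshold is None else threshold
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes(data=True))
        g.add_edges_from(
            (u, v, d) for u, v, d in self.graph.edges(data=True) if d["weight"] <= t
        )
        return g

    @property
    def components(self) -> list[set[str]]:
        return sorted(
            (set(c) for c in nx.connected_components(self.thresholded())),
            key=lambda c: (-len(c), sorted(c)),
        )


def percolation_threshold(graph: nx.Graph) -> float:
    """Susceptibility-peak estimate of the percolation threshold.

    Candidate thresholds are the sorted unique edge weights; for each, the
    susceptibility ``chi = sum(s^2 * n_s) / N`` is computed over the
    component-size distribution excluding the largest component.  The
    smallest threshold maximizing chi is returned.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("percolation threshold needs >= 3 nodes")
    weights = sorted({d["weight"] for _, _, d in graph.edges(data=True)})
    if not weights:
        raise ValueError("graph has no edges")
    best_t, best_chi = weights[0], -1.0
    for t in weights:
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from(
            (u, v) for u, v, d in graph.edges(data=True) if d["weight"] <= t
        )
        sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        chi = sum(s * s for s in sizes[1:]) / n
        if chi > best_chi + 1e-12:
            best_chi, best_t = chi, t
    return float(best_t)


def build_network(table: HaplotypeTable, mode: str = "mean") -> HaplotypeNetwork:
    """Complete Goldstein-distance graph over distinct haplotypes, annotated
    with counts and the automatically estimated percolation threshold."""
    labels = list(table.table.index)
    if len(labels) < 2:
        raise ValueError("network needs >= 2 haplotypes")
    g = nx.Graph()
    for label in labels:
        g.add_node(label, count=int(table.table.loc[label, "count"]))
    for a, b in itertools.combinations(labels, 2):
        w = goldstein_distance(
            Haplotype(a, table.vectors[a]), Haplotype(b, table.vectors[b]), mode=mode
        )
        g.add_edge(a, b, weight=w)
    threshold = percolation_threshold(g) if len(labels) >= 3 else max(
        d["weight"] for _, _, d in g.edges(data=True)
    )
    return HaplotypeNetwork(g, threshold, mode)


def write_network(net: HaplotypeNetwork, out_prefix: str | Path) -> None:
    """Write node/edge lists as TSV and the full graph as GraphML; all edges
    are retained with the threshold stored so viewers can re-threshold."""
    prefix = Path(out_prefix)
    nodes = pd.DataFrame(
        [(n, d.get("count", 1)) for n, d in net.graph.nodes(data=True)],
        columns=["haplotype_id", "count"],
    )
    nodes.to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
    edges = pd.DataFrame(
        [
            (u, v, d["weight"], d["weight"] <= net.percolation_threshold)
            for u, v, d in net.graph.edges(data=True)
        ],
        columns=["from", "to", "goldstein_distance", "below_threshold"],
    )
    edges.to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    g = net.graph.copy()
    g.graph["percolation_threshold"] = net.percolation_threshold
    nx.write_graphml(g, str(prefix.with_suffix(".graphml")))
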