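"""Cluster/subcluster/singleton assignment and genome-network analysis.

Phages are clustered when they share at least 35% of their genes (edges in
a GCS graph, clusters = connected components); clusters are optionally
subdivided into subclusters by ANI. MaxGCDGap quantifies a phage's genetic
isolation; genome networks connect pairs with intra-cluster-like distances
(gcd < 0.89 and nucleotide distance < 0.42, both strict).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .genome_io import PhageGenome
from .pairwise_metrics import SymmetricMatrix

__all__ = [
    "TaxonomyConfig",
    "ClusterAssignment",
    "SINGLETON",
    "assign_clusters",
    "assign_subclusters",
    "max_gcd_gap",
    "max_gcd_gap_table",
    "build_network",
    "order_heatmap",
    "flag_lifestyle_markers",
]

SINGLETON = "SINGLETON"

TEMPERATE_MARKER_PATTERNS = [
    re.compile(r"\bintegrase\b", re.IGNORECASE),
    re.compile(r"\bimmunity repressor\b", re.IGNORECASE),
    re.compile(r"\brepressor\b", re.IGNORECASE),
]


@dataclass(frozen=True)
class TaxonomyConfig:
    """Thresholds for clustering, subclustering, and network edges.

    ``cluster_gcs_min`` is inclusive (a pair at exactly 35% is clustered);
    the network cutoffs are strict (a pair at exactly gcd 0.89 or nd 0.42
    gets no edge).
    """

    cluster_gcs_min: float = 35.0  # percent, inclusive
    subcluster_ani_min: float = 75.0  # percent, inclusive
    network_gcd_max: float = 0.89  # fraction, strict
    network_nd_max: float = 0.42  # fraction, strict

    def __post_init__(self) -> None:
        if not 0 <= self.cluster_gcs_min <= 100 or not 0 <= self.subcluster_ani_min <= 100:
            raise ValueError("GCS/ANI thresholds must be percentages")
        if not 0 <= self.network_gcd_max <= 1 or not 0 <= self.network_nd_max <= 1:
            raise ValueError("network thresholds must be fractions")


@dataclass
class ClusterAssignment:
    """Phage -> cluster/subcluster labels plus the config that produced them."""

    cluster: dict[str, str]
    subcluster: dict[str, Optional[str]] = field(default_factory=dict)
    config: TaxonomyConfig = field(default_factory=TaxonomyConfig)

    def members(self, label: str) -> list[str]:
        return sorted(p for p, c in self.cluster.items() if c == label)

    @property
    def cluster_labels(self) -> list[str]:
        return sorted({c for c in self.cluster.values() if c != SINGLETON})

    @property
    def singletons(self) -> list[str]:
        return sorted(p for p, c in self.cluster.items() if c == SINGLETON)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (p, self.cluster[p], self.subcluster.get(p) or "")
            for p in sorted(self.cluster)
        ]
        return pd.DataFrame(rows, columns=["phage_id", "cluster", "subcluster"])


def _threshold_components(matrix: SymmetricMatrix, minimum: float) -> list[list[str]]:
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(matrix.labels)
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= minimum:
                graph.add_edge(matrix.labels[i], matrix.labels[j])
    return [sorted(c) for c in nx.connected_components(graph)]


def assign_clusters(
    gcs: SymmetricMatrix,
    config: TaxonomyConfig = TaxonomyConfig(),
    label_map: Optional[dict[str, str]] = None,
) -> ClusterAssignment:
    """Cluster phages by connected components of the GCS >= threshold graph.

    Components of size >= 2 become clusters named C1, C2, ... by descending
    size, ties broken by lexicographically smallest member (so labels do
    not depend on input order). Size-1 components are labeled SINGLETON.
    ``label_map`` optionally renames clusters (EA/EB-style) keyed by their
    smallest member.
    """
    components = _threshold_components(gcs, config.cluster_gcs_min)
    multi = sorted((c for c in components if len(c) >= 2), key=lambda c: (-len(c), c[0]))
    cluster: dict[str, str] = {}
    for rank, members in enumerate(multi, start=1):
        name = f"C{rank}"
        if label_map and members[0] in label_map:
            name = label_map[members[0]]
        for p in members:
            cluster[p] = name
    for c in components:
        if len(c) == 1:
            cluster[c[0]] = SINGLETON
    return ClusterAssignment(cluster=cluster, config=config)


def assign_subclusters(
    assignment: ClusterAssignment,
    ani: SymmetricMatrix,
    config: Optional[TaxonomyConfig] = None,
) -> ClusterAssignment:
    """Subdivide each multi-member cluster by ANI connected components.

    Within one cluster, edges join pairs at ANI >= ``subcluster_ani_min``;
    if the graph splits into k >= 2 components they are numbered
    ``<cluster>1..<cluster>k`` by descending size (EA1-style). A cluster
    that stays in one component gets no subcluster labels.
    """
    config = config or assignment.config
    subcluster: dict[str, Optional[str]] = {p: None for p in assignment.cluster}
    for cluster_label in assignment.cluster_labels:
        members = assignment.members(cluster_label)
        sub = ani.submatrix(members)
        components = _threshold_components(sub, config.subcluster_ani_min)
        if len(components) < 2:
            continue
        components.sort(key=lambda c: (-len(c), c[0]))
        for rank, comp in enumerate(components, start=1):
            for p in comp:
                subcluster[p] = f"{cluster_label}{rank}"
    return ClusterAssignment(
        cluster=dict(assignment.cluster), subcluster=subcluster, config=config
    )


def max_gcd_gap(gcd: SymmetricMatrix, phage_id: str) -> float:
    """Largest gap between consecutive sorted GCD values for one phage.

    The phage's GCD values to all other phages are sorted ascending with a
    leading sentinel at 0 (the self comparison); the gap is the maximum
    difference between consecutive values. Large values mean the phage is
    genetically isolated from its nearest sampled relatives.
    """
    if len(gcd.labels) < 2:
        raise ValueError("MaxGCDGap requires at least 2 phages")
    i = gcd.labels.index(phage_id)
    others = np.delete(gcd.values[i], i)
    d = np.concatenate([[0.0], np.sort(others)])
    return float(np.max(np.diff(d)))


def max_gcd_gap_table(
    gcd: SymmetricMatrix, groups: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Per-phage MaxGCDGap table, optionally annotated with group means."""
    rows = [(p, max_gcd_gap(gcd, p)) for p in gcd.labels]
    table = pd.DataFrame(rows, columns=["phage_id", "max_gcd_gap"])
    if groups is not None:
        table["group"] = table["phage_id"].map(groups)
        means = table.groupby("group")["max_gcd_gap"].transform("mean")
        table["group_mean"] = means
    return table


def build_network(
    gcd: SymmetricMatrix,
    nd: SymmetricMatrix,
    config: TaxonomyConfig = TaxonomyConfig(),
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Genome network: edges where gcd < cutoff AND nd < cutoff (both strict).

    Returns the edge list (phage_a, phage_b, gcd, nd) and the connected
    components (every phage appears in exactly one component; isolated
    phages form their own).
    """
    if gcd.labels != nd.labels:
        raise ValueError("gcd and nd matrices must share labels in the same order")
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(gcd.labels)
    rows = []
    n = len(gcd.labels)
    for i in range(n):
        for j in range(i + 1, n):
            g, d = gcd.values[i, j], nd.values[i, j]
            if g < config.network_gcd_max and d < config.network_nd_max:
                a, b = gcd.labels[i], gcd.labels[j]
                graph.add_edge(a, b)
                rows.append((a, b, g, d))
    edges = pd.DataFrame(rows, columns=["phage_a", "phage_b", "gcd", "nucleotide_distance"])
    components = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    return edges, components


def order_heatmap(matrix: SymmetricMatrix) -> list[str]:
    """Leaf order for heatmap display: Chebyshev distances, single linkage.

    Row distances use the maximum (Chebyshev) metric on matrix rows and the
    dendrogram is built by single-linkage agglomeration; the returned label
    permutation puts related genomes in contiguous blocks.
    """
    if len(matrix.labels) < 2:
        return list(matrix.labels)
    distances = pdist(matrix.values, metric="chebyshev")
    order = leaves_list(linkage(distances, method="single"))
    return [matrix.labels[i] for i in order]


def flag_lifestyle_markers(genome: PhageGenome) -> pd.DataFrame:
    """Flag genes whose product suggests a temperate-lifestyle marker.

    Matches integrase / (immunity) repressor keywords in product text,
    case-insensitively. This reports marker presence only — it is not a
    lifestyle prediction.
    """
    rows = []
    for g in genome.genes:
        for pattern in TEMPERATE_MARKER_PATTERNS:
            if pattern.search(g.product):
                rows.append((genome.phage_id, g.gene_id, g.product, pattern.pattern))
                break
    return pd.DataFrame(rows, columns=["phage_id", "gene_id", "product", "matched_pattern"])
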