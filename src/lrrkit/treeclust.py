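"""Tree-based receptor clustering.

An externally built sequence-similarity tree (newick, branch lengths in
substitutions per site) is converted to a cophenetic distance matrix
(path-length sums between leaves).  Pairs closer than a cutoff (0.2 by
default) become weighted edges of a similarity network, whose Louvain
communities group highly similar receptors; cluster composition is then
summarised by the family/subgroup labels of the member leaves.
"""

from __future__ import annotations

import io as _io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import dendropy
import networkx as nx
import numpy as np

from .config import AnalysisConfig


@dataclass
class PhyloTree:
    tree: dendropy.Tree
    leaf_labels: List[str]
    metadata: Dict[str, Dict[str, str]] = field(default_factory=dict)


@dataclass
class CommunitySet:
    clusters: List[FrozenSet[str]]
    seed: int
    label_of: Dict[str, str] = field(default_factory=dict)


@dataclass
class CompositionSummary:
    n_clusters: int
    n_single_label: int
    n_two_label: int
    n_multi_label: int
    pair_counts: Dict[Tuple[str, str], int]
    cluster_labels: List[FrozenSet[str]]


def parse_newick(text: str, metadata: Optional[Dict[str, Dict[str, str]]] = None
                 ) -> PhyloTree:
    """Parse a newick string; internal support labels are tolerated.

    Missing branch lengths default to 0 with a warning; duplicate leaf
    labels are an error.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = [lab for lab, k in Counter(labels).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    missing = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing = True
    if missing:
        warnings.warn("missing branch lengths set to 0")
    return PhyloTree(tree=tree, leaf_labels=labels, metadata=metadata or {})


def load_newick(path: str, metadata: Optional[Dict[str, Dict[str, str]]] = None
                ) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), metadata)


def load_leaf_metadata(path: str) -> Dict[str, Dict[str, str]]:
    """TSV with header leaf_id, family, lineage, species (extras kept)."""
    meta: Dict[str, Dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            meta[row[header[0]]] = row
    return meta


def cophenetic_matrix(ptree: PhyloTree) -> Tuple[List[str], np.ndarray]:
    """Leaf-by-leaf matrix of path-length sums (cophenetic distances)."""
    pdm = ptree.tree.phylogenetic_distance_matrix()
    labels = ptree.leaf_labels
    taxa = {t.label: t for t in ptree.tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, d


def threshold_network(labels: List[str], d: np.ndarray, cutoff: float = 0.2,
                      mode: str = "scaled") -> nx.Graph:
    """Similarity network from a distance matrix.

    An edge joins every pair with distance strictly below ``cutoff``.
    Weights: ``"scaled"`` gives 1 - d/cutoff (positive, bounded,
    cutoff-relative); ``"linear"`` gives 1 - d.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            dij = d[i, j]
            if dij < cutoff:
                w = 1.0 - dij / cutoff if mode == "scaled" else 1.0 - dij
                g.add_edge(labels[i], labels[j], weight=w, distance=dij)
    return g


def louvain_communities(network: nx.Graph, seed: int = 0) -> CommunitySet:
    """Seeded Louvain modularity communities; isolated nodes are singletons."""
    parts = nx.community.louvain_communities(
        network, weight="weight", resolution=1.0, seed=seed
    )
    clusters = sorted((frozenset(p) for p in parts), key=lambda c: sorted(c)[0])
    return CommunitySet(clusters=clusters, seed=seed)


def composition_summary(communities: CommunitySet,
                        metadata: Dict[str, Dict[str, str]],
                        label_key: str = "family") -> CompositionSummary:
    """Count single-label, two-label and multi-label clusters and label pairs."""
    pair_counts: Counter = Counter()
    cluster_labels: List[FrozenSet[str]] = []
    n_single = n_two = n_multi = 0
    for cluster in communities.clusters:
        labels = set()
        for leaf in cluster:
            if leaf not in metadata or label_key not in metadata[leaf]:
                raise ValueError(f"leaf {leaf!r} has no {label_key!r} label")
            labels.add(metadata[leaf][label_key])
        cluster_labels.append(frozenset(labels))
        if len(labels) == 1:
            n_single += 1
        elif len(labels) == 2:
            n_two += 1
            pair_counts[tuple(sorted(labels))] += 1
        else:
            n_multi += 1
    return CompositionSummary(
        n_clusters=len(communities.clusters),
        n_single_label=n_single,
        n_two_label=n_two,
        n_multi_label=n_multi,
        pair_counts=dict(pair_counts),
        cluster_labels=cluster_labels,
    )


def cluster_tree(ptree: PhyloTree, cutoff: float = 0.2, seed: int = 0,
                 mode: str = "scaled") -> Tuple[CommunitySet, nx.Graph]:
    """Full pipeline: cophenetic matrix -> threshold network -> Louvain."""
    labels, d = cophenetic_matrix(ptree)
    net = threshold_network(labels, d, cutoff=cutoff, mode=mode)
    return louvain_communities(net, seed=seed), net
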