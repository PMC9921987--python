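"""The merge algorithm proper.

Pipeline: sort the directed hits by e-value, drop self-hits, keep the pairs
that are *reciprocal* (a hit in each direction survives the threshold —
mutual presence, not mutual-best), build the undirected graph on
representative ids, merge its connected components, and relabel every
sequence of the input clustering with its component's label.

The component label is the member that appears earliest in the traversal
order: first appearance in the e-value-sorted reciprocal hit list, falling
back to clustering order for representatives that never occur in an edge.
Components are computed with a union of all reciprocal edges (never
best-per-node), so the output partition is always a coarsening of the
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from completplus.errors import ClusteringError, CompletPlusError
from completplus.io_formats import AlignmentHit, Clustering, RelabeledRow, SequenceRecord
from completplus.pairwise_search import ScoringScheme, SearchParams, all_vs_all, _passes


@dataclass
class ReciprocalGraph:
    """Undirected graph on representative ids whose edges are reciprocal
    hit pairs passing the e-value threshold.

    ``edge_order`` lists edges as (query, target) of the earlier direction
    in the e-value-sorted hit list; ``seed_order`` is the order in which
    representative ids first appear in that sorted list — it decides which
    member labels a merged component.
    """

    nodes: set[str]
    edges: set[frozenset] = field(default_factory=set)
    edge_order: list[tuple[str, str]] = field(default_factory=list)
    seed_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise CompletPlusError(f"self-loop or malformed edge {set(e)}")
            if not e <= self.nodes:
                raise CompletPlusError(f"edge {set(e)} has endpoint outside node set")


@dataclass
class MergeResult:
    """Outcome of a merge: old-representative -> new-representative map,
    the relabeled per-sequence rows (input order), and the number of
    components that actually merged (>= 2 old representatives)."""

    rep_map: dict[str, str]
    rows: list[RelabeledRow]
    n_merged_components: int

    @property
    def n_clusters_in(self) -> int:
        return len(self.rep_map)

    @property
    def n_clusters_out(self) -> int:
        return len(set(self.rep_map.values()))

    def as_clustering(self) -> Clustering:
        """The merged partition as a Clustering (new representative first)."""
        return Clustering([(r.new_cluster_id, r.sequence_id) for r in self.rows])


def _sort_key(hit: AlignmentHit):
    # Ascending e-value; ties by descending bitscore, then lexicographic
    # (query, target) — purely for determinism.
    return (hit.evalue, -hit.bitscore, hit.query_id, hit.target_id)


def filter_reciprocal(
    hits: Iterable[AlignmentHit],
    evalue_threshold: float,
    nodes: Iterable[str] | None = None,
) -> ReciprocalGraph:
    """Reduce directed hits to the undirected reciprocal-hit graph.

    Hits are sorted from lowest e-value to highest, self-hits are removed,
    and an edge {a, b} exists iff a hit a->b AND a hit b->a both survive
    ``evalue <= evalue_threshold``.  Reciprocity is mutual presence under
    the threshold — a node may carry many edges; mutual-best is *not*
    required.  ``nodes`` (normally all representative ids of the input
    clustering) adds isolated nodes that had no surviving hits.
    """
    hits = list(hits)
    for h in hits:
        if h.evalue < 0:
            raise CompletPlusError(
                f"negative e-value on hit {h.query_id}->{h.target_id}"
            )
    surviving = sorted(
        (h for h in hits if h.evalue <= evalue_threshold and h.query_id != h.target_id),
        key=_sort_key,
    )
    directed = {(h.query_id, h.target_id) for h in surviving}
    node_set: set[str] = set(nodes) if nodes is not None else set()
    if nodes is None:
        for h in hits:
            node_set.add(h.query_id)
            node_set.add(h.target_id)
    edges: set[frozenset] = set()
    edge_order: list[tuple[str, str]] = []
    seed_order: list[str] = []
    seen: set[str] = set()
    for h in surviving:
        if (h.target_id, h.query_id) not in directed:
            continue
        node_set.add(h.query_id)
        node_set.add(h.target_id)
        e = frozenset((h.query_id, h.target_id))
        if e not in edges:
            edges.add(e)
            edge_order.append((h.query_id, h.target_id))
        for x in (h.query_id, h.target_id):
            if x not in seen:
                seen.add(x)
                seed_order.append(x)
    return ReciprocalGraph(node_set, edges, edge_order, seed_order)


def merge_components(graph: ReciprocalGraph, clustering: Clustering) -> MergeResult:
    """Merge the connected components of the reciprocal graph and relabel.

    Each component is labeled by its seed — the member earliest in
    ``graph.seed_order`` (clustering order for isolated nodes).  Every old
    representative maps to the label of its component; sequences are
    relabeled through that map, in input order.
    """
    reps = clustering.representatives
    rep_set = set(reps)
    stray = sorted(n for n in graph.nodes if n not in rep_set)
    if stray:
        raise ClusteringError(
            f"graph node(s) {stray} are not representatives of the clustering"
        )
    # Traversal order: reciprocal-hit-list first, then clustering order.
    rank: dict[str, int] = {}
    for name in list(graph.seed_order) + reps:
        if name not in rank:
            rank[name] = len(rank)
    g = nx.Graph()
    g.add_nodes_from(rep_set | graph.nodes)
    g.add_edges_from(tuple(e) for e in graph.edges)
    rep_map: dict[str, str] = {}
    n_merged = 0
    for comp in nx.connected_components(g):
        label = min(comp, key=rank.__getitem__)
        if len(comp) >= 2:
            n_merged += 1
        for node in comp:
            rep_map[node] = label
    rows = [
        RelabeledRow(rep, member, rep_map[rep])
        for rep, member in clustering.assignments
    ]
    return MergeResult(rep_map=rep_map, rows=rows, n_merged_components=n_merged)


def extract_representatives(
    sequences: Sequence[SequenceRecord], clustering: Clustering
) -> list[SequenceRecord]:
    """Keep exactly the sequences named in the clustering's first column,
    in clustering order.  A representative with no sequence is an error;
    extra (non-representative) sequences are permitted and ignored."""
    by_id = {s.id: s for s in sequences}
    missing = [r for r in clustering.representatives if r not in by_id]
    if missing:
        raise CompletPlusError(
            f"representative(s) {missing} have no sequence in the FASTA input"
        )
    return [by_id[r] for r in clustering.representatives]


def run_complet_plus(
    sequences: Sequence[SequenceRecord],
    clustering: Clustering,
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
    external_hits: Sequence[AlignmentHit] | None = None,
) -> MergeResult:
    """End-to-end merge: extract representatives, search all-vs-all (or
    take pre-computed external hits), filter to reciprocal pairs, merge
    components, relabel every sequence.

    The output has at most as many clusters as the input and is always a
    coarsening of it: sequences sharing an input cluster share an output
    cluster.
    """
    if params is None:
        params = SearchParams()
    if len(clustering) == 0:
        raise ClusteringError("empty clustering")
    reps = extract_representatives(sequences, clustering)
    if external_hits is not None:
        hits = [h for h in external_hits if _passes(h, params)]
    else:
        hits = all_vs_all(reps, params, scheme)
    graph = filter_reciprocal(
        hits, params.evalue_threshold, nodes=clustering.representatives
    )
    return merge_components(graph, clustering)
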