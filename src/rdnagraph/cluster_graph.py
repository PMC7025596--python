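"""All-to-all read comparison, overlap graph, and modularity-guided clustering.

Two reads are joined by an edge when their best ungapped diagonal segment (on
either strand) reaches 90% identity over at least ``max(min_overlap,
min_read_coverage * read_length)`` bases — the classic similarity threshold
for read clustering of repeats ("90% similarity across 55% of the read").
All-to-all semantics are exact: a shared-k-mer prefilter is used for speed,
with k chosen by a pigeonhole bound so that no qualifying pair can be missed
(see :func:`rdnagraph._align.lossless_prefilter_k`).

Clusters are connected groups of frequently overlapping reads.  Communities
from modularity maximization (Louvain) are used to detect and cut *sparse*
bridges — e.g. a retroelement appendage attached to the 5S circle by one or
two chimeric reads — while community pairs connected by more than
``bridge_max_edges`` edges are merged back, since modularity splits large
dense rings into arcs that are not biologically separate clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities

from rdnagraph import _align
from rdnagraph._align import encode, identity_scaled, revcomp_codes
from rdnagraph.readio import ReadPool, TaggedRead

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds for overlap detection and cluster admission.

    ``min_identity``/``min_read_coverage``/``min_overlap`` define the edge
    criterion; ``cluster_threshold`` is the minimum fraction of input reads a
    cluster must reach to be reported; ``min_overlap_assembly`` is passed to
    within-cluster contig assembly; ``bridge_max_edges`` is the largest number
    of inter-community edges still treated as a spurious bridge.
    """

    min_identity: float = 0.90
    min_read_coverage: float = 0.55
    min_overlap: int = 55
    cluster_threshold: float = 0.0001
    min_overlap_assembly: int = 40
    bridge_max_edges: int = 2

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        if not 0 < self.min_read_coverage <= 1:
            raise ValueError("min_read_coverage must lie in (0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be positive")

    def min_span(self, read_length: int) -> int:
        # guard against float artifacts (0.55 * 100 == 55.000000000000007)
        span = max(self.min_overlap,
                   int(np.ceil(self.min_read_coverage * read_length - 1e-9)))
        if span > read_length:
            raise ValueError(
                f"required overlap {span} exceeds read length {read_length}")
        return span


@dataclass(frozen=True)
class OverlapEdge:
    """An accepted pairwise overlap.

    ``offset`` is the position of ``read_b``'s origin in ``read_a``'s forward
    coordinates for the winning segment; for ``strand_relation='opposite'`` it
    refers to the reverse complement of ``read_b``.  ``score`` is the integer
    identity-margin score of the segment (shared with the brute-force oracle).
    """

    read_a: str
    read_b: str
    identity: float
    overlap_len: int
    strand_relation: Literal["same", "opposite"]
    offset: int
    score: int


def pairwise_overlap(a: TaggedRead, b: TaggedRead,
                     params: ClusteringParams) -> OverlapEdge | None:
    """Overlap criterion for a single read pair; symmetric in (a, b)."""
    if len(a.seq) != len(b.seq):
        raise ValueError("pairwise_overlap expects uniform-length reads")
    if b.read_id < a.read_id:  # canonical order => exact symmetry
        edge = pairwise_overlap(b, a, params)
        return edge
    min_span = params.min_span(len(a.seq))
    id_sc = identity_scaled(params.min_identity)
    seqs = np.vstack([encode(a.seq), encode(b.seq)])
    rcs = np.vstack([revcomp_codes(seqs[0]), revcomp_codes(seqs[1])])
    pairs = np.array([[0, 1]], dtype=np.int64)
    acc, w, matches, span, strand, diag = _align._verify_pairs(
        seqs, rcs, pairs, min_span, id_sc)
    if not acc[0]:
        return None
    return OverlapEdge(
        a.read_id, b.read_id,
        identity=int(matches[0]) / int(span[0]),
        overlap_len=int(span[0]),
        strand_relation="same" if strand[0] == 0 else "opposite",
        offset=int(diag[0]),
        score=int(w[0]),
    )


def build_overlap_graph(pool: ReadPool,
                        params: ClusteringParams | None = None) -> nx.Graph:
    """All-to-all overlap graph of a uniform-length read pool.

    Vertices are read ids (attributes: ``genome_code``); edges carry
    ``identity``, ``span``, ``strand_relation``, ``offset`` and ``score``.
    Every pair is considered; the shared-k-mer diagonal filter inside the
    kernel is lossless at the configured thresholds.  The graph records the
    pool size in ``graph['pool_size']``.
    """
    if params is None:
        params = ClusteringParams()
    if len(pool) == 0:
        raise ValueError("empty read pool")
    L = pool.uniform_length
    min_span = params.min_span(L)
    id_sc = identity_scaled(params.min_identity)
    n = len(pool)
    seqs = np.vstack([encode(r.seq) for r in pool.reads])
    rcs = np.vstack([revcomp_codes(row) for row in seqs])
    ids = [r.read_id for r in pool.reads]

    g = nx.Graph(pool_size=n, read_length=L)
    for r in pool.reads:
        g.add_node(r.read_id, genome_code=r.genome_code or "")

    k = min(_align.lossless_prefilter_k(min_span, L, params.min_identity), 10)
    if k >= 4 and n > 1:
        ii, jj, w, matches, span, strand, diag = _align._all_pairs_edges(
            seqs, rcs, k, min_span, id_sc)
        for t in range(len(ii)):
            # offset is relative to the first read; record it explicitly, as
            # graph views may later yield the edge in either orientation
            g.add_edge(
                ids[int(ii[t])], ids[int(jj[t])],
                identity=int(matches[t]) / int(span[t]),
                span=int(span[t]),
                strand_relation="same" if strand[t] == 0 else "opposite",
                offset=int(diag[t]),
                offset_ref=ids[int(ii[t])],
                score=int(w[t]),
            )
    elif n > 1:  # thresholds too permissive for a safe k-mer filter
        pi, pj = np.triu_indices(n, k=1)
        pairs = np.column_stack([pi, pj]).astype(np.int64)
        acc, w, matches, span, strand, diag = _align._verify_pairs(
            seqs, rcs, pairs, min_span, id_sc)
        for p in np.flatnonzero(acc):
            g.add_edge(
                ids[int(pairs[p, 0])], ids[int(pairs[p, 1])],
                identity=int(matches[p]) / int(span[p]),
                span=int(span[p]),
                strand_relation="same" if strand[p] == 0 else "opposite",
                offset=int(diag[p]),
                offset_ref=ids[int(pairs[p, 0])],
                score=int(w[p]),
            )
    logger.info("overlap graph: %d vertices, %d edges", n, g.number_of_edges())
    return g


def ordered_subgraph(graph: nx.Graph, nodes) -> nx.Graph:
    """Materialized subgraph with deterministic (sorted) node order.

    networkx subgraph *views* iterate their node filter set in hash order,
    which leaks the interpreter's string-hash seed into anything sensitive
    to node or edge order (community detection, BFS trees).  All downstream
    stages use this instead of ``graph.subgraph``.
    """
    wanted = set(nodes)
    h = nx.Graph()
    h.add_nodes_from((n, graph.nodes[n]) for n in sorted(wanted))
    for u in sorted(wanted):
        for v, data in graph.adj[u].items():
            if v in wanted and u < v:
                h.add_edge(u, v, **data)
    return h


@dataclass(frozen=True)
class ReadCluster:
    """A reported read cluster (sorted read ids; proportion of input reads)."""

    cluster_id: int
    read_ids: tuple[str, ...]
    genome_proportion: float

    @property
    def size(self) -> int:
        return len(self.read_ids)


def cluster_by_modularity(graph: nx.Graph, params: ClusteringParams | None = None,
                          seed: int = 0) -> list[ReadCluster]:
    """Partition the overlap graph into repeat clusters.

    Connected components are the clustering backbone; within each component a
    Louvain partition proposes cuts, and only cuts crossed by at most
    ``bridge_max_edges`` edges are kept (sparse, chimera-like bridges).
    Clusters below ``cluster_threshold`` of the input reads go to the
    remainder (singletons and tiny groups are not reported).  Clusters are
    ordered by size (ties: smallest read id) and numbered from 1.
    """
    if params is None:
        params = ClusteringParams()
    if graph.number_of_nodes() == 0:
        return []
    pool_size = graph.graph.get("pool_size", graph.number_of_nodes())
    groups: list[set[str]] = []
    for comp in sorted(nx.connected_components(graph), key=min):
        if len(comp) <= 2:
            groups.append(set(comp))
            continue
        sub = ordered_subgraph(graph, comp)
        communities = louvain_communities(sub, seed=seed)
        if len(communities) == 1:
            groups.append(set(comp))
            continue
        # merge community pairs joined by more than bridge_max_edges edges
        comm_of = {}
        for ci, comm in enumerate(communities):
            for v in comm:
                comm_of[v] = ci
        cut_counts: dict[tuple[int, int], int] = {}
        for u, v in sub.edges():
            cu, cv = comm_of[u], comm_of[v]
            if cu != cv:
                key = (min(cu, cv), max(cu, cv))
                cut_counts[key] = cut_counts.get(key, 0) + 1
        parent = list(range(len(communities)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (cu, cv), cnt in cut_counts.items():
            if cnt > params.bridge_max_edges:
                parent[find(cu)] = find(cv)
        merged: dict[int, set[str]] = {}
        for ci, comm in enumerate(communities):
            merged.setdefault(find(ci), set()).update(comm)
        # a kept cut may still leave a merged group disconnected; split back
        for grp in merged.values():
            for piece in nx.connected_components(graph.subgraph(grp)):
                groups.append(set(piece))

    min_size = params.cluster_threshold * pool_size
    kept = [grp for grp in groups if len(grp) >= min_size and len(grp) > 1]
    kept.sort(key=lambda grp: (-len(grp), min(grp)))
    return [
        ReadCluster(i + 1, tuple(sorted(grp)), len(grp) / pool_size)
        for i, grp in enumerate(kept)
    ]


def clusters_table(clusters: Sequence[ReadCluster]) -> pd.DataFrame:
    return pd.DataFrame({
        "cluster_id": [c.cluster_id for c in clusters],
        "n_reads": [c.size for c in clusters],
        "genome_proportion_pct": [100 * c.genome_proportion for c in clusters],
    })


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))
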