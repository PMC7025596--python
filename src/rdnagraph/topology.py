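"""Cluster graph topology: orientation, circularity, loops, type classification.

A tandem repeat cluster, once its reads are strand-oriented, induces a
directed graph (suffix-to-prefix overlaps).  The *connected component index*
C — the fraction of reads in the largest strongly connected component — is
close to 1 for a closed tandem circle.  Removing the conserved coding-region
("genic") reads decomposes the remaining spacer reads into loops: one loop
per homogeneous IGS family.  A single loop marks a type 1 (diploid-like)
graph, two or more loops mark a type 2 (hybrid/allopolyploid-like) graph, and
clusters that fail to circularize are unresolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from rdnagraph import _align
from rdnagraph._align import encode, identity_scaled, revcomp, revcomp_codes
from rdnagraph.cluster_graph import ReadCluster, ordered_subgraph
from rdnagraph.consensus import (
    ConsensusUnit,
    ReconstructionFailed,
    cycle_kmer_score,
    reconstruct_monomer,
)
from rdnagraph.readio import ReadPool

logger = logging.getLogger(__name__)

TypeClass = Literal["type1", "type2", "unresolved"]


@dataclass
class OrientedGraph:
    """Strand assignment plus the induced directed overlap graph.

    ``strand`` maps read id -> +1/-1 (flipping all strands is equivalent);
    ``digraph`` contains an edge u->v when v's oriented sequence starts
    strictly inside u's (both directions for perfectly stacked reads);
    ``discarded_edges`` counts overlaps inconsistent with the assignment.
    """

    digraph: nx.DiGraph
    strand: dict[str, int]
    discarded_edges: int

    def oriented_seqs(self, pool: ReadPool) -> dict[str, str]:
        by_id = {r.read_id: r.seq for r in pool.reads}
        return {
            rid: by_id[rid] if s == 1 else revcomp(by_id[rid])
            for rid, s in self.strand.items()
        }


def orient_reads(graph: nx.Graph, cluster: ReadCluster) -> OrientedGraph:
    """Assign strands by BFS propagation of the same/opposite edge labels.

    The smallest read id of each component anchors the + strand.  Edges whose
    label disagrees with the final assignment (odd inconsistency cycles, rare
    at low error rates) are discarded and counted.
    """
    sub = ordered_subgraph(graph, cluster.read_ids)
    strand: dict[str, int] = {}
    for comp in sorted(nx.connected_components(sub), key=min):
        root = min(comp)
        strand[root] = 1
        for u, v in nx.bfs_edges(ordered_subgraph(sub, comp), root):
            rel = sub.edges[u, v]["strand_relation"]
            strand[v] = strand[u] if rel == "same" else -strand[u]
    for rid in cluster.read_ids:  # isolated vertices keep + strand
        strand.setdefault(rid, 1)

    dg = nx.DiGraph()
    dg.add_nodes_from(cluster.read_ids)
    discarded = 0
    for u, v, data in sub.edges(data=True):
        rel = data["strand_relation"]
        consistent = (strand[u] == strand[v]) == (rel == "same")
        if not consistent:
            discarded += 1
            continue
        # the stored offset is relative to offset_ref's forward strand
        ref = data.get("offset_ref", u)
        other = v if ref == u else u
        d = data["offset"] if strand[ref] == 1 else -data["offset"]
        if d > 0:
            dg.add_edge(ref, other, offset=d)
        elif d < 0:
            dg.add_edge(other, ref, offset=-d)
        else:
            dg.add_edge(ref, other, offset=0)
            dg.add_edge(other, ref, offset=0)
    if discarded:
        logger.info("orientation discarded %d strand-inconsistent edges", discarded)
    return OrientedGraph(dg, strand, discarded)


def connected_component_index(og: OrientedGraph) -> float:
    """|largest strongly connected component| / |vertices|, in [0, 1]."""
    n = og.digraph.number_of_nodes()
    if n == 0:
        raise ValueError("empty oriented graph")
    largest = max(len(c) for c in nx.strongly_connected_components(og.digraph))
    return largest / n


def annotate_genic(pool: ReadPool, cluster: ReadCluster, gene_ref: str,
                   min_identity: float = 0.80, min_span: int = 30) -> set[str]:
    """Read ids whose sequence aligns to the coding-region reference.

    A read is genic when either strand reaches ``min_identity`` over at least
    ``min_span`` aligned bases against ``gene_ref``; everything else is IGS.
    """
    if min_span > pool.uniform_length:
        raise ValueError("min_span exceeds read length")
    gene_f = np.ascontiguousarray(encode(gene_ref))
    gene_r = np.ascontiguousarray(revcomp_codes(gene_f))
    id_sc = identity_scaled(min_identity)
    wanted = set(cluster.read_ids)
    genic: set[str] = set()
    for r in pool.reads:
        if r.read_id not in wanted:
            continue
        codes = np.ascontiguousarray(encode(r.seq))
        wf, *_ = _align._best_segment(codes, gene_f, min_span, id_sc)
        if wf >= 0:
            genic.add(r.read_id)
            continue
        wr, *_ = _align._best_segment(codes, gene_r, min_span, id_sc)
        if wr >= 0:
            genic.add(r.read_id)
    if not genic:
        logger.warning("cluster %s: no genic reads found; may not be rDNA",
                       cluster.cluster_id)
    return genic


def decompose_loops(graph: nx.Graph, cluster: ReadCluster, genic: set[str],
                    loop_min_identity: float = 0.95,
                    min_loop_fraction: float = 0.05) -> list[set[str]]:
    """IGS loops: components of the cluster graph after junction removal.

    The junction comprises the genic reads and their direct neighbours (reads
    carrying conserved gene flanks, which connect divergent families).  Among
    the remaining spacer reads only high-identity edges
    (>= ``loop_min_identity``) are kept, because family separation — unlike
    cluster admission — requires distinguishing spacer variants whose overall
    similarity may still exceed the clustering threshold in conserved
    stretches.  Components holding at least ``min_loop_fraction`` of the
    cluster's reads are loops, sorted by size (descending, ties by smallest
    read id).
    """
    sub = graph.subgraph(cluster.read_ids)
    junction = set(genic)
    for g in genic:
        junction.update(sub.neighbors(g))
    h = nx.Graph()
    h.add_nodes_from(v for v in cluster.read_ids if v not in junction)
    for u, v, data in sub.edges(data=True):
        if u in junction or v in junction:
            continue
        if data["identity"] >= loop_min_identity:
            h.add_edge(u, v)
    min_size = max(2, min_loop_fraction * cluster.size)
    loops = [set(c) for c in nx.connected_components(h) if len(c) >= min_size]
    loops.sort(key=lambda c: (-len(c), min(c)))
    return loops


def classify_topology(C: float, loops: Sequence[set[str]],
                      min_circularity: float = 0.5) -> TypeClass:
    """Type 1 (one IGS loop), type 2 (>= 2 loops), or unresolved (no cycle)."""
    if C < min_circularity or not loops:
        return "unresolved"
    return "type1" if len(loops) == 1 else "type2"


def reconstruct_and_score(pool: ReadPool, cluster: ReadCluster,
                          og: OrientedGraph, k: int = 17,
                          min_count: int = 2
                          ) -> tuple[ConsensusUnit | None, float | None]:
    """Circular consensus of the cluster plus its k-mer coverage score.

    The score is the fraction of all k-mer occurrences in the cluster's
    oriented reads that lie on the consensus cycle — 1.0 for a perfectly
    homogeneous tandem family, lower when divergent families share the
    cluster.  Returns (None, None) when no cycle can be reconstructed.
    """
    if k >= pool.uniform_length:
        raise ValueError(f"k={k} must be smaller than the read length")
    seqs = list(og.oriented_seqs(pool).values())
    try:
        unit = reconstruct_monomer(seqs, k=k, min_count=min_count)
    except ReconstructionFailed:
        return None, None
    return unit, cycle_kmer_score(seqs, unit.seq, k)


@dataclass
class ClusterTopology:
    """Per-cluster topology metrics and classification."""

    cluster_id: int
    n_reads: int
    genome_proportion: float
    C: float
    kmer_score: float | None
    consensus: ConsensusUnit | None
    genic_vertices: set[str]
    igs_loops: list[set[str]]
    type_class: TypeClass
    discarded_edges: int

    @property
    def loop_read_counts(self) -> list[int]:
        return [len(l) for l in self.igs_loops]


def analyze_cluster(pool: ReadPool, graph: nx.Graph, cluster: ReadCluster,
                    gene_ref: str, k: int = 17,
                    genic_min_identity: float = 0.80,
                    loop_min_identity: float = 0.95,
                    min_loop_fraction: float = 0.05,
                    min_circularity: float = 0.5,
                    min_count: int = 2) -> ClusterTopology:
    """Full topology workup of one cluster (orientation through type call)."""
    og = orient_reads(graph, cluster)
    C = connected_component_index(og)
    genic = annotate_genic(pool, cluster, gene_ref,
                           min_identity=genic_min_identity)
    loops = decompose_loops(graph, cluster, genic,
                            loop_min_identity=loop_min_identity,
                            min_loop_fraction=min_loop_fraction)
    unit, score = reconstruct_and_score(pool, cluster, og, k=k,
                                        min_count=min_count)
    type_class = classify_topology(C, loops, min_circularity=min_circularity)
    if unit is None:
        type_class = "unresolved"
    return ClusterTopology(
        cluster_id=cluster.cluster_id,
        n_reads=cluster.size,
        genome_proportion=cluster.genome_proportion,
        C=C,
        kmer_score=score,
        consensus=unit,
        genic_vertices=genic,
        igs_loops=loops,
        type_class=type_class,
        discarded_edges=og.discarded_edges,
    )


def topology_report(topologies: Sequence[ClusterTopology]) -> pd.DataFrame:
    """Summary table mirroring the standard cluster-report columns."""
    return pd.DataFrame({
        "cluster_id": [t.cluster_id for t in topologies],
        "n_reads": [t.n_reads for t in topologies],
        "genome_proportion_pct": [100 * t.genome_proportion for t in topologies],
        "repeat_size_bp": [t.consensus.length if t.consensus else np.nan
                           for t in topologies],
        "kmer_coverage": [t.kmer_score if t.kmer_score is not None else np.nan
                          for t in topologies],
        "connected_component_index_C": [t.C for t in topologies],
        "n_loops": [len(t.igs_loops) for t in topologies],
        "loop_sizes": [";".join(str(n) for n in t.loop_read_counts)
                       for t in topologies],
        "graph_type": [{"type1": "1", "type2": "2"}.get(t.type_class,
                                                        "unresolved")
                       for t in topologies],
    })


def annotated_graphml(graph: nx.Graph, cluster: ReadCluster, genic: set[str],
                      path) -> None:
    """Export the cluster subgraph with genic/IGS vertex colors."""
    sub = nx.Graph(graph.subgraph(cluster.read_ids))
    for v in sub.nodes:
        sub.nodes[v]["region"] = "genic" if v in genic else "igs"
        sub.nodes[v]["color"] = "green" if v in genic else "grey"
    nx.write_graphml(sub, str(path))
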