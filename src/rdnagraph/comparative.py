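"""Comparative multi-genome clustering: tracking homoeolog families to parents.

Reads from a putative hybrid and its candidate progenitors are pooled (with
per-genome provenance codes), clustered jointly, and the 5S cluster's IGS
loops are scored for per-genome composition.  A candidate parent is supported
("contributes") when some loop is essentially exclusive to it *and* hybrid
reads co-occupy that loop; a loop occupied by hybrid reads alone points to an
unsampled donor or an introgressed family.  Neighbor-joining trees of
assembled contigs against parental references provide an independent check of
loop identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from rdnagraph._align import revcomp
from rdnagraph.cluster_graph import (
    ClusteringParams,
    ReadCluster,
    build_overlap_graph,
    cluster_by_modularity,
)
from rdnagraph.readio import ReadPool
from rdnagraph.topology import ClusterTopology, analyze_cluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoopComposition:
    """Per-genome read counts of one IGS loop and its exclusivity call.

    ``exclusive_to`` is a genome code when at least ``exclusivity_threshold``
    of the loop's non-hybrid reads come from that genome, ``'hybrid_only'``
    when the loop holds no non-hybrid reads at all, and ``'shared'``
    otherwise.
    """

    loop_id: int
    per_genome_read_counts: dict[str, int]
    exclusive_to: str

    @property
    def size(self) -> int:
        return sum(self.per_genome_read_counts.values())


@dataclass
class ComparativeResult:
    """Joint clustering output: graph, clusters, 5S topology, compositions."""

    graph: nx.Graph
    clusters: list[ReadCluster]
    rdna_cluster: ReadCluster
    topology: ClusterTopology
    compositions: list[LoopComposition]
    junction_counts: dict[str, int]
    missing_genomes: list[str]


@dataclass(frozen=True)
class ComparativeVerdict:
    """Parentage diagnosis from loop compositions."""

    parent_support: dict[str, Literal["contributes", "absent", "ambiguous"]]
    hybrid_reads_span_multiple_loops: bool
    hybrid_only_loops: list[int]
    notes: list[str]


def merge_pools(pools: Sequence[ReadPool]) -> ReadPool:
    lengths = {p.uniform_length for p in pools}
    if len(lengths) != 1:
        raise ValueError(f"pools have different read lengths: {sorted(lengths)}")
    codes: set[str | None] = set()
    for p in pools:
        pc = set(p.per_genome_counts)
        if pc & codes:
            raise ValueError(f"duplicate genome codes across pools: {pc & codes}")
        codes |= pc
    return ReadPool([r for p in pools for r in p.reads], lengths.pop())


def _compose(loop: set[str], code_of: Mapping[str, str], hybrid_code: str,
             loop_id: int, exclusivity_threshold: float) -> LoopComposition:
    counts: dict[str, int] = {}
    for rid in loop:
        code = code_of[rid]
        counts[code] = counts.get(code, 0) + 1
    non_hybrid = {c: n for c, n in counts.items() if c != hybrid_code}
    total_nh = sum(non_hybrid.values())
    if total_nh == 0:
        exclusive = "hybrid_only"
    else:
        top = max(sorted(non_hybrid), key=lambda c: non_hybrid[c])
        exclusive = top if non_hybrid[top] >= exclusivity_threshold * total_nh \
            else "shared"
    return LoopComposition(loop_id, counts, exclusive)


def comparative_cluster(pools: Sequence[ReadPool], gene_ref: str,
                        hybrid_code: str,
                        params: ClusteringParams | None = None,
                        seed: int = 0, k: int = 17,
                        exclusivity_threshold: float = 0.9,
                        **topology_kw) -> ComparativeResult:
    """Joint clustering of hybrid + candidate progenitor read pools.

    Provenance codes influence reporting only: the graph and clusters are
    computed from sequences alone.  The 5S cluster is the largest cluster
    containing coding-region reads; per-loop genome compositions and the
    genic-junction composition are derived from it.
    """
    if params is None:
        params = ClusteringParams()
    pool = merge_pools(pools)
    all_codes = sorted(c for c in pool.per_genome_counts if c is not None)
    if len(all_codes) < 2:
        raise ValueError("comparative clustering needs at least two genomes")
    if hybrid_code not in all_codes:
        raise ValueError(f"hybrid code {hybrid_code!r} not present in the pools")
    graph = build_overlap_graph(pool, params)
    clusters = cluster_by_modularity(graph, params, seed=seed)
    if not clusters:
        raise ValueError("no clusters above the reporting threshold")
    topo = None
    rdna = None
    for cand in clusters[:10]:  # the 5S cluster is invariably near the top
        t = analyze_cluster(pool, graph, cand, gene_ref, k=k, **topology_kw)
        if t.genic_vertices:
            topo, rdna = t, cand
            break
    if topo is None:
        raise ValueError("no cluster contains coding-region reads")
    code_of = {r.read_id: r.genome_code or "" for r in pool.reads}
    compositions = [
        _compose(loop, code_of, hybrid_code, i + 1, exclusivity_threshold)
        for i, loop in enumerate(topo.igs_loops)
    ]
    junction: dict[str, int] = {}
    for rid in topo.genic_vertices:
        junction[code_of[rid]] = junction.get(code_of[rid], 0) + 1
    in_cluster = {code_of[rid] for rid in rdna.read_ids}
    missing = [c for c in all_codes if c not in in_cluster]
    for c in missing:
        logger.warning("genome %s contributed no reads to the 5S cluster", c)
    return ComparativeResult(graph, clusters, rdna, topo, compositions,
                             junction, missing)


def diagnose_parentage(compositions: Sequence[LoopComposition],
                       parent_codes: Sequence[str], hybrid_code: str,
                       min_cooccupancy: float = 0.05) -> ComparativeVerdict:
    """Call each candidate parent as contributing, absent, or ambiguous.

    A parent contributes when one of its exclusive loops also holds hybrid
    reads (at least ``min_cooccupancy`` of the loop); an exclusive loop with
    no meaningful hybrid presence marks the candidate absent; a candidate
    without any exclusive loop is ambiguous.
    """
    support: dict[str, str] = {}
    hybrid_loops = []
    for comp in compositions:
        h = comp.per_genome_read_counts.get(hybrid_code, 0)
        if h >= min_cooccupancy * comp.size and h > 0:
            hybrid_loops.append(comp.loop_id)
    for parent in parent_codes:
        exclusive = [c for c in compositions if c.exclusive_to == parent]
        if not exclusive:
            support[parent] = "ambiguous"
        elif any(c.loop_id in hybrid_loops for c in exclusive):
            support[parent] = "contributes"
        else:
            support[parent] = "absent"
    hybrid_only = [c.loop_id for c in compositions
                   if c.exclusive_to == "hybrid_only"]
    notes = []
    for lid in hybrid_only:
        notes.append(
            f"loop {lid} holds hybrid reads only: possible unsampled donor "
            f"or introgressed family")
    for comp in compositions:
        if comp.exclusive_to == "shared":
            notes.append(f"loop {comp.loop_id} is shared between genomes "
                         f"(families may be too similar to separate)")
    return ComparativeVerdict(
        parent_support=support,
        hybrid_reads_span_multiple_loops=len(hybrid_loops) >= 2,
        hybrid_only_loops=hybrid_only,
        notes=notes,
    )


def p_distance(a: str, b: str) -> float:
    """Pairwise distance between sequences of possibly different lengths.

    For equal-length sequences this is the global edit distance divided by
    the length (the p-distance under substitution-only divergence).  When the
    lengths differ — short reads against a full monomer reference — the
    shorter sequence is aligned as an infix of the longer, so the distance
    measures divergence over the homologous stretch rather than the length
    difference.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    mode = "NW" if len(short) == len(long_) else "HW"
    d = min(
        edlib.align(short, long_, mode=mode, task="distance")["editDistance"],
        edlib.align(revcomp(short), long_, mode=mode,
                    task="distance")["editDistance"],
    )
    return d / len(short)


def nj_tree(labeled_seqs: Sequence[tuple[str, str]]) -> TreeNode:
    """Neighbor-joining tree from pairwise p-distances.

    Deterministic for a fixed input order; negative branch lengths are
    clamped to zero.
    """
    if len(labeled_seqs) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    labels = [l for l, _ in labeled_seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("sequence labels must be unique")
    n = len(labeled_seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(labeled_seqs[i][1],
                                             labeled_seqs[j][1])
    return nj(DistanceMatrix(dm, ids=labels))


@dataclass(frozen=True)
class CladeRatio:
    """Leaf counts (and fractions) on each side of the reference split."""

    count_a: int
    count_b: int
    frac_a: float
    frac_b: float
    n_sampled: int
    unclassified: int


def _tip_names(node: TreeNode) -> set[str]:
    if node.is_tip():
        return {node.name}
    return {t.name for t in node.tips()}


def clade_ratio(labeled_seqs: Sequence[tuple[str, str]], ref_a: tuple[str, str],
                ref_b: tuple[str, str], sample_size: int = 200,
                seed: int = 0, min_ref_distance: float = 0.05) -> CladeRatio:
    """Homoeolog ratio from clade membership in an NJ tree.

    Samples up to ``sample_size`` sequences, builds an NJ tree together with
    the two references, cuts the longest edge on the path between the
    references (the edge separating their subtrees) and counts sampled leaves
    on each side.  Requires the references to be separable
    (p-distance >= ``min_ref_distance``).

    The input sequences must cover a shared homologous region — e.g. reads
    extracted with a subregion query, as in the ITS1 homoeolog-ratio
    workflow.  Reads scattered across the phases of a tandem unit are not
    mutually alignable and their tree reflects position, not family.
    """
    la, sa = ref_a
    lb, sb = ref_b
    if p_distance(sa, sb) < min_ref_distance:
        raise ValueError(
            f"references not separable: p-distance below {min_ref_distance}")
    if not 3 <= sample_size:
        raise ValueError("sample_size must be at least 3")
    rng = np.random.default_rng(seed)
    n = min(sample_size, len(labeled_seqs))
    idx = sorted(rng.choice(len(labeled_seqs), size=n, replace=False))
    sampled = [labeled_seqs[i] for i in idx]
    tree = nj_tree(sampled + [ref_a, ref_b])

    tip_a = tree.find(la)
    tip_b = tree.find(lb)
    anc_a = [tip_a] + list(tip_a.ancestors())
    anc_b = [tip_b] + list(tip_b.ancestors())
    in_a = set(id(x) for x in anc_a)
    lca = next(x for x in anc_b if id(x) in in_a)
    path = anc_a[:anc_a.index(lca)] + list(reversed(anc_b[:anc_b.index(lca)]))
    # every node on `path` hangs below the path via its edge to its parent
    best = max(path, key=lambda node: (node.length or 0.0))
    side = _tip_names(best)
    all_tips = _tip_names(tree)
    if la not in side:
        side = all_tips - side
    sampled_labels = [l for l, _ in sampled]
    count_a = sum(1 for l in sampled_labels if l in side)
    count_b = n - count_a
    return CladeRatio(count_a, count_b, count_a / n, count_b / n, n, 0)
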