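"""Circular monomer consensus from read k-mers, and within-cluster contigs.

The monomer of a tandem repeat is reconstructed from the de Bruijn multigraph
of the cluster's (strand-oriented) read k-mers: the repeated unit appears as
a heavy cycle whose length equals the monomer length.  The cycle is found by
a greedy heaviest-successor walk with bounded backtracking; singleton k-mers
(default: count < 2) are pruned first, which removes almost all
sequencing-error k-mers at realistic coverage.  The consensus is reported in
a canonical form — the lexicographically least rotation of the
lexicographically lesser strand — so that reconstructions from any rotation
or strand of the same monomer compare equal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdnagraph._align import encode, revcomp


class ReconstructionFailed(Exception):
    """No sufficiently long cycle exists in the pruned k-mer graph."""


@dataclass(frozen=True)
class ConsensusUnit:
    """A reconstructed circular monomer.

    ``path_weight`` is the fraction of the cluster's k-mer mass (occurrence
    counts over reads) that lies on the consensus cycle; ``seq`` is the
    canonical rotation.
    """

    seq: str
    length: int
    path_weight: float
    k_used: int


def _kmer_ints(seq: str, k: int) -> list[int]:
    codes = encode(seq)
    n = len(seq) - k + 1
    out = []
    mask = (1 << (2 * k)) - 1
    val = 0
    run = 0  # valid-base run length
    for i, c in enumerate(codes):
        if c >= 4:
            run = 0
            val = 0
            continue
        val = ((val << 2) | int(c)) & mask
        run += 1
        if run >= k:
            out.append(val)
    return out


def _decode_kmer(val: int, k: int) -> str:
    return "".join("ACGT"[(val >> (2 * (k - 1 - i))) & 3] for i in range(k))


def kmer_counts(seqs: Iterable[str], k: int) -> Counter:
    """Occurrence counts of all k-mers in the given sequences (one strand)."""
    counts: Counter = Counter()
    for s in seqs:
        counts.update(_kmer_ints(s, k))
    return counts


def cycle_kmer_score(seqs: Sequence[str], consensus: str, k: int) -> float:
    """Fraction of read k-mer occurrences lying on the circular consensus.

    The consensus is treated as circular (wrapped by k-1 bases) and both of
    its strands count as "on the cycle".
    """
    wrapped = consensus + consensus[:k - 1]
    cycle = set(_kmer_ints(wrapped, k))
    cycle |= set(_kmer_ints(revcomp(wrapped), k))
    total = 0
    hit = 0
    for s in seqs:
        for km in _kmer_ints(s, k):
            total += 1
            if km in cycle:
                hit += 1
    if total == 0:
        raise ValueError("no k-mers in input reads")
    return hit / total


def canonical_rotation(seq: str) -> str:
    """Lexicographically least rotation over both strands of a circular seq."""
    best = None
    for s in (seq, revcomp(seq)):
        doubled = s + s
        for i in range(len(s)):
            cand = doubled[i:i + len(s)]
            if best is None or cand < best:
                best = cand
    return best


def reconstruct_monomer(seqs: Sequence[str], k: int = 17, min_count: int = 2,
                        min_monomer: int = 80,
                        max_backtracks: int = 1000) -> ConsensusUnit:
    """Reconstruct the circular monomer of a tandem-repeat read cluster.

    ``seqs`` must be strand-consistent (use the oriented cluster reads).  The
    greedy walk starts at the most frequent k-mer and always extends to the
    heaviest unvisited successor (ties: lexicographically smallest); closing
    back to the start is taken as soon as the path is at least ``min_monomer``
    long and closing ranks best among the remaining choices.  Backtracking is
    bounded, so pathological graphs fail fast with
    :class:`ReconstructionFailed`.
    """
    if not seqs:
        raise ValueError("no input reads")
    if any(len(s) <= k for s in seqs):
        raise ValueError(f"all reads must be longer than k={k}")
    raw = kmer_counts(seqs, k)
    if not raw:
        raise ValueError("no k-mers could be extracted")
    counts = {km: c for km, c in raw.items() if c >= min_count}
    if not counts:
        counts = dict(raw)  # low coverage: fall back to the unpruned graph
    mask = (1 << (2 * k)) - 1

    def successors(node: int) -> list[int]:
        base = (node << 2) & mask
        cands = [base | b for b in range(4) if (base | b) in counts]
        cands.sort(key=lambda x: (-counts[x], x))
        return cands

    start = max(counts, key=lambda x: (counts[x], -x))
    path = [start]
    on_path = {start}
    choice_stack = [successors(start)]
    pointer_stack = [0]
    backtracks = 0
    cycle: list[int] | None = None
    while True:
        cands = choice_stack[-1]
        ptr = pointer_stack[-1]
        advanced = False
        while ptr < len(cands):
            nxt = cands[ptr]
            ptr += 1
            if nxt == start and len(path) >= min_monomer:
                pointer_stack[-1] = ptr
                cycle = list(path)
                break
            if nxt not in on_path:
                pointer_stack[-1] = ptr
                path.append(nxt)
                on_path.add(nxt)
                choice_stack.append(successors(nxt))
                pointer_stack.append(0)
                advanced = True
                break
        if cycle is not None:
            break
        if advanced:
            continue
        # dead end: backtrack
        backtracks += 1
        if backtracks > max_backtracks or len(path) == 1:
            raise ReconstructionFailed(
                f"no cycle of length >= {min_monomer} found "
                f"({backtracks} backtracks)")
        on_path.discard(path.pop())
        choice_stack.pop()
        pointer_stack.pop()

    seq = _decode_kmer(cycle[0], k) + "".join(
        _decode_kmer(node, k)[-1] for node in cycle[1:])
    monomer = seq[:len(cycle)]
    canonical = canonical_rotation(monomer)
    return ConsensusUnit(
        seq=canonical,
        length=len(canonical),
        path_weight=cycle_kmer_score(seqs, canonical, k),
        k_used=k,
    )


@dataclass(frozen=True)
class ClusterContig:
    """A greedy overlap-layout contig built from one cluster's reads."""

    contig_id: str
    seq: str
    n_supporting_reads: int
    read_ids: tuple[str, ...]


def assemble_contigs(oriented_seqs: Mapping[str, str],
                     overlaps: Iterable[tuple[str, str, int]],
                     min_overlap_assembly: int = 40,
                     min_identity: float = 0.95) -> list[ClusterContig]:
    """Greedy chain assembly of oriented cluster reads.

    ``overlaps`` lists directed candidates (a, b, offset) meaning b's oriented
    sequence starts ``offset`` bases into a's (from the oriented cluster
    graph).  A candidate is merged when the implied dovetail overlap is at
    least ``min_overlap_assembly`` bases at ``min_identity`` (ungapped).  Each
    read joins at most one contig; chains never close into cycles, so a
    circular monomer yields a linear contig covering the unit.
    """
    cands = []
    for a, b, offset in overlaps:
        if offset <= 0:
            continue
        sa, sb = oriented_seqs[a], oriented_seqs[b]
        olen = len(sa) - offset
        if olen < min_overlap_assembly:
            continue
        matches = sum(1 for x, y in zip(sa[offset:], sb[:olen]) if x == y)
        if matches < min_identity * olen:
            continue
        cands.append((olen, matches / olen, a, b, offset))
    cands.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))

    succ: dict[str, tuple[str, int]] = {}
    has_pred: set[str] = set()
    parent: dict[str, str] = {}  # union-find over chains

    def find(x: str) -> str:
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    for _, _, a, b, offset in cands:
        if a in succ or b in has_pred:
            continue
        if find(a) == find(b):
            continue  # would close a cycle
        succ[a] = (b, offset)
        has_pred.add(b)
        parent[find(a)] = find(b)

    contigs = []
    heads = [rid for rid in sorted(oriented_seqs) if rid not in has_pred]
    for head in heads:
        seq = oriented_seqs[head]
        members = [head]
        cur = head
        cur_start = 0  # position of cur's first base within the contig
        while cur in succ:
            nxt, offset = succ[cur]
            cur_start += offset
            seq = seq[:cur_start] + oriented_seqs[nxt]
            members.append(nxt)
            cur = nxt
        contigs.append((seq, tuple(members)))
    contigs.sort(key=lambda t: (-len(t[0]), t[1]))
    return [
        ClusterContig(f"contig{i + 1}", seq, len(members), members)
        for i, (seq, members) in enumerate(contigs)
    ]
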