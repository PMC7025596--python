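# Methods

## Overlap criterion and graph construction

Two uniform-length reads are joined by an edge when some ungapped diagonal
segment, on either strand, spans at least
`max(min_overlap, ceil(min_read_coverage × L))` bases at identity at least
`min_identity`. Defaults follow the standard read-clustering thresholds for
repeat discovery: 90% identity over 55% of the read, minimum overlap 55
bases, cluster reporting threshold 0.01% of input reads. Identity is
compared in exact integer arithmetic: a segment of span *s* with *m*
matches scores `w = 10⁶·m − round(10⁶·min_identity)·s`, and the pair is
accepted iff some admissible segment has `w ≥ 0`. This makes the
accept/reject decision bit-reproducible and lets a brute-force enumeration
serve as an exact oracle (`tests/oracle.py`; the acceptance suite verifies
zero edge discrepancies on a mixed pool).

The engine is deliberately **ungapped** (a banded aligner with band width
zero). The simulator produces substitution errors only, and at ≥90%
identity an overlap rescued by an indel would in any case sit at the
decision boundary; an engine is conforming exactly when it matches the
brute-force graph, which this one does by construction.

All-to-all semantics are kept exact at speed by a shared-k-mer *diagonal*
filter inside the numba kernel: a qualifying segment of span ≥55 at ≥90%
identity contains, by pigeonhole over its mismatches, an exact run of at
least 8 bases on its own diagonal, so only diagonals on which the two reads
share an 8-mer are scanned. The bound is recomputed from the configured
thresholds (`lossless_prefilter_k`); if a configuration makes the safe k
smaller than 4, the filter is disabled and every diagonal is scanned.

## Clustering

Clusters are connected groups of frequently overlapping reads. Plain
modularity maximization is unsuitable as-is: Louvain's resolution limit
splits a single dense tandem ring (hundreds of reads, tens of thousands of
edges) into arcs that are not biologically distinct. We therefore treat
connected components as the backbone and use the Louvain partition only to
locate *sparse* bridges: a proposed cut is applied when at most
`bridge_max_edges` (default 2) edges cross it. This separates chimeric or
retroelement appendages attached to the 5S circle by one or two reads while
keeping dense rings and two-loop hybrid graphs whole. Clusters below the
reporting threshold go to the remainder; the rest are numbered from 1 by
decreasing size (ties: smallest read id).

## Orientation and circularity

Strands are assigned by BFS propagation of the per-edge same/opposite
labels from the smallest read id of each component; edges inconsistent with
the final assignment (odd inconsistency cycles, rare at low error rates)
are discarded and counted. Each retained overlap then induces a directed
edge from the read whose oriented sequence starts first to the one that
extends it (both directions for perfectly stacked reads). The connected
component index C is the fraction of cluster reads in the largest strongly
connected component of this digraph: 1.0 for an intact tandem circle,
≪1 for linear (non-tandem) fragments. Clusters with C below
`min_circularity` (default 0.5, far below the values real tandem clusters
reach) are classified *unresolved*.

## Genic annotation, loops, and type classification

A read is genic when either strand aligns to the coding-region reference at
≥80% identity over ≥30 bases (the 5S coding region is conserved across
angiosperms, so a permissive threshold is appropriate). The **junction** is
the genic reads plus their direct graph neighbours: reads carrying less
than 30 bp of gene still carry conserved gene flanks and short conserved
spacer stretches, and connect divergent families — the junction of real
hybrid graphs likewise contains part of the IGS. After junction removal,
only edges with identity ≥ `loop_min_identity` (default 0.95) are kept
among the remaining spacer reads: loop separation must distinguish family
variants whose *local* similarity can exceed the 90% clustering threshold
in conserved stretches even when overall IGS identity is 80%. Connected
components holding at least `min_loop_fraction` (default 5%) of the
cluster's reads are IGS loops. One loop ⇒ type 1, two or more ⇒ type 2,
no circularization ⇒ unresolved.

Measured detection boundary at these defaults (read length 100, 0.5%
error): two equal-abundance families separate into two loops at IGS
divergence ≥ 0.15 and merge into one loop (type 1) at ≤ 0.10 — hybrids
whose progenitor spacers are more than ~90% identical are reported as
diploid-like, which is the known failure mode of the approach. The
acceptance suite pins the endpoints and verifies the transition is
monotone for a fixed seed.

## Circular consensus and the k-mer coverage score

The cluster's oriented reads are decomposed into k-mers (default k = 17,
configurable 11–27; 17 balances specificity against the 100 bp read
length). k-mers with count < 2 are pruned (standard de Bruijn denoising —
at ≥20× coverage true k-mers are never singletons, while nearly all
error k-mers are). The monomer is the cycle found by a greedy
heaviest-successor walk from the most frequent k-mer, with ties broken
lexicographically, closure allowed once the path reaches `min_monomer`
(default 80 bp), and backtracking capped at 1000 steps. The consensus is
reported as the lexicographically least rotation of the lexicographically
lesser strand, so reconstructions from any rotation or strand compare
equal. Correctness is defined behaviourally: across monomer lengths
150–900 bp the reconstructed length is exact at zero error and within
±2 bp at 0.5% error (in practice it is exact there too).

The **k-mer coverage score** of a cluster is the fraction of all k-mer
occurrences in its oriented reads that lie on the consensus cycle (both
strands of the cycle count). It equals 1.0 for a homogeneous error-free
family and decreases as a second diverged family claims k-mer mass the
consensus cannot cover. Because the mutation positions of a derived family
are drawn as a prefix of a seeded permutation, divergence sweeps at a fixed
seed are *nested* — each increment only adds mutations — so the score is
monotone non-increasing along the sweep structurally, not statistically.

## Comparative analysis

Pools from the hybrid and candidate progenitors are merged (provenance
codes must be distinct; codes influence reporting only — clustering is
label-blind, which a test verifies). The 5S cluster is the largest cluster
containing genic reads. Each IGS loop is scored for per-genome composition:
`exclusive_to` a genome when ≥90% of its non-hybrid reads come from that
genome (`exclusivity_threshold`), `hybrid_only` when no non-hybrid reads
are present, else `shared`. A candidate parent **contributes** when one of
its exclusive loops also carries hybrid reads (≥5% of the loop,
`min_cooccupancy`); an exclusive loop without hybrid presence marks the
candidate **absent**; candidates without exclusive loops are **ambiguous**.
Hybrid-only loops are flagged as possible unsampled donors or introgressed
families.

Neighbor joining uses p-distances: global edit distance over length for
equal-length sequences, infix alignment of the shorter in the longer
(reads against a circular monomer reference) otherwise, minimized over
strands. Negative branch lengths are clamped to zero; trees are
deterministic given input order. `clade_ratio` samples 100–500 sequences,
builds an NJ tree with both references, cuts the longest edge on the
inter-reference path and counts leaves per side. Its inputs must cover a
shared homologous window (in real workflows, reads extracted with a
subregion query; in simulations, reads anchored to a spacer phase window
via the ledger) — reads scattered across tandem phases are not mutually
alignable and would cluster by position, not family.

## Mapping-based quantification

Reads are aligned to each reference monomer (doubled head-to-tail so
junction-spanning reads map full length) with a local affine-gap aligner:
match +1, mismatch −2, gap open 3, gap extend 2 — the published
insertion/deletion cost pair is interpreted as open/extend, the only
reading that uses both numbers. A read maps when its best alignment covers
≥50% of the read at ≥90% identity, and counts only for a strictly
best-scoring reference; score ties go to `multi_best` and are excluded from
the ratios (conservative, and flagged when ties outnumber unique
assignments — which is exactly what happens when references are ≥98%
identical, where mapping-based separation is honestly impossible). Copy
number is `round(genome_proportion × genome_size / unit_length)` on the 1C
convention, recorded explicitly since published copy numbers vary by
C-value convention.

## What the simulator emulates, and what it does not

Emulated: conserved coding region shared across families; one or more IGS
families per genome with controlled substitution divergence and length
indels; head-to-tail arrays (linear concatenations of ≥3 copies, so
junction-spanning reads exist; ends are not wrapped); allopolyploids as
unions of parental families with optional skewed copy numbers; i.i.d.
uniform random background; fixed-length single-end reads (paired ends are
consumed as independent reads by the clustering anyway) with i.i.d.
substitution errors at a default 0.5% and uniform random strand; a
ground-truth ledger (source family, position, unit phase, strand) enabling
exact scoring.

Not emulated: indel or quality-decay error profiles, PCR/GC bias, adapters,
real 5S sequence composition, higher-order repeat variants, pseudogenes,
and concerted-evolution gradients within arrays. Consequently, passing
tests demonstrate the method's behaviour under clean tandem-repeat
structure with calibrated divergence; they do not bound its accuracy on
real libraries, where preprocessing quality and repeat pathology add modes
of failure the generator does not represent.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale designs chosen to preserve the
relevant ratios: genomes of 0.06–0.5 Mb with the 5S array at 3–20% of the
genome, pools of 0.4–6 k reads yielding 5S clusters of ~400–700 reads
(matching the cluster sizes real 200 k-read runs produce), arrays of 5–50
copies, and 25–40× array coverage for consensus work. At these scales the
background itself is covered 2–3×, so many small single-copy clusters
appear; pipeline reports analyze the top `analyze_top` (default 5) clusters,
mirroring the focus on the 5S cluster. Seeds fan out from a single run seed
by fixed offsets; identical config + seed reproduces outputs byte for byte.

Known limitations: the type 1/type 2 call operationalizes what was
originally a visual judgement — borderline graphs (partially merged loops,
loops below the 5% size floor) may be classified differently than by eye;
C is computed over reads (no vertex collapsing); the greedy cycle search is
not guaranteed maximum-weight on pathological k-mer graphs (it is validated
behaviourally); and homoeolog ratios from mapping exclude tied reads, which
is unbiased only when ties affect both families symmetrically (true for
gene-region reads, the dominant tie source).
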