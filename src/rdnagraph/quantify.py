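"""Homoeolog quantification by read mapping, and copy-number estimation.

Reads are mapped against candidate monomer references with a local aligner
(match +1, mismatch -2, affine gaps: open 3, extend 2) and assigned to the
best-scoring reference when the alignment covers at least half the read at
90% identity — the standard stringent mapping setting for separating
homoeologous repeat families.  References are doubled head-to-tail before
alignment so that reads spanning the circular unit junction still map full
length.  Ties between references are counted separately (``multi_best``) and
excluded from the ratios; when ties dominate, the references are too similar
for mapping-based separation and the report flags it rather than returning a
misleading ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from rdnagraph._align import revcomp
from rdnagraph.readio import ReadPool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappingParams:
    """Read-mapping acceptance thresholds and alignment costs."""

    length_fraction: float = 0.5
    similarity_fraction: float = 0.9
    gap_open_cost: int = 3
    gap_extend_cost: int = 2
    match_score: int = 1
    mismatch_cost: int = 2

    def __post_init__(self):
        for name in ("length_fraction", "similarity_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    def aligner(self) -> Align.PairwiseAligner:
        return Align.PairwiseAligner(
            mode="local",
            match_score=self.match_score,
            mismatch_score=-self.mismatch_cost,
            open_gap_score=-(self.gap_open_cost + self.gap_extend_cost),
            extend_gap_score=-self.gap_extend_cost,
        )


@dataclass
class HomoeologReport:
    """Mapping-based family quantification.

    ``ratios`` are normalized over uniquely-best mapped reads and are ``None``
    when no read mapped uniquely.  ``flags`` lists quality warnings (e.g.
    reference similarity collapsing unique assignment).
    """

    per_reference_counts: dict[str, int]
    unmapped: int
    multi_best: int
    total_reads: int
    ratios: dict[str, float] | None
    flags: list[str]


def map_reads(pool: ReadPool, references: Sequence[tuple[str, str]],
              params: MappingParams | None = None) -> HomoeologReport:
    """Assign each read to its best-matching reference monomer.

    ``references`` are (id, monomer sequence) pairs; each is treated as
    circular.  A read maps when its best local alignment covers at least
    ``length_fraction`` of the read at ``similarity_fraction`` identity; it
    counts for a reference only when that reference's score is strictly best.
    """
    if params is None:
        params = MappingParams()
    if not references:
        raise ValueError("no references given")
    ids = [rid for rid, _ in references]
    if len(set(ids)) != len(ids):
        raise ValueError("reference ids must be unique")
    aligner = params.aligner()
    doubled = [(rid, seq + seq) for rid, seq in references]
    counts = {rid: 0 for rid in ids}
    unmapped = 0
    multi_best = 0
    L = pool.uniform_length
    for read in pool.reads:
        strands = (read.seq, revcomp(read.seq))
        best_score = None
        best: list[tuple[str, str]] = []  # (ref_id, read strand)
        for rid, ref in doubled:
            for s in strands:
                score = aligner.score(s, ref)
                if best_score is None or score > best_score:
                    best_score = score
                    best = [(rid, s)]
                elif score == best_score:
                    if rid not in {b for b, _ in best}:
                        best.append((rid, s))
        rid, s = best[0]
        ref = dict(doubled)[rid]
        aln = aligner.align(s, ref)[0]
        read_segs = aln.aligned[0]
        covered = read_segs[-1][1] - read_segs[0][0]
        c = aln.counts()
        identity = c.identities / aln.length
        if covered < params.length_fraction * L or \
                identity < params.similarity_fraction:
            unmapped += 1
        elif len(best) > 1:
            multi_best += 1
        else:
            counts[rid] += 1
    unique_total = sum(counts.values())
    flags = []
    if multi_best > unique_total:
        flags.append("references_too_similar: ties outnumber unique "
                     "assignments; ratios unreliable")
    if unique_total == 0:
        ratios = None
        flags.append("no_unique_assignments")
    else:
        ratios = {rid: n / unique_total for rid, n in counts.items()}
    return HomoeologReport(
        per_reference_counts=counts,
        unmapped=unmapped,
        multi_best=multi_best,
        total_reads=len(pool),
        ratios=ratios,
        flags=flags,
    )


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Genomic copy number from cluster genome proportion (1C convention)."""

    genome_proportion: float
    genome_size: int
    unit_length: int
    copies: int
    convention: str = "1C"


def estimate_copy_number(genome_proportion: float, genome_size: int,
                         unit_length: int) -> CopyNumberEstimate:
    """copies = round(genome_proportion * genome_size / unit_length)."""
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if genome_proportion < 0:
        raise ValueError("genome_proportion must be non-negative")
    copies = int(round(genome_proportion * genome_size / unit_length))
    return CopyNumberEstimate(genome_proportion, genome_size, unit_length,
                              copies)
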