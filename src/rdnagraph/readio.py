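"""Reading, trimming, provenance tagging and genome-fraction sampling of reads.

Reads enter the pipeline from FASTA or FASTQ files, are trimmed to a uniform
length (clustering requires equal-length reads), filtered on N content, and —
for comparative multi-genome runs — tagged with a 3-character genome
provenance code carried as a ``CODE_`` prefix of the read id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class TaggedRead:
    """A read with a unique id, sequence, and optional genome provenance code."""

    read_id: str
    seq: str
    genome_code: str | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def genome_code_from_id(read_id: str) -> str | None:
    """Provenance code from a ``CODE_`` id prefix (3 characters), if present."""
    head, sep, _ = read_id.partition("_")
    if sep and len(head) == 3:
        return head
    return None


@dataclass
class ReadPool:
    """A uniform-length collection of tagged reads."""

    reads: list[TaggedRead]
    uniform_length: int

    def __post_init__(self):
        bad = [r.read_id for r in self.reads if len(r) != self.uniform_length]
        if bad:
            raise ValueError(
                f"{len(bad)} reads do not have the pool length "
                f"{self.uniform_length} (first: {bad[0]!r})")
        ids = set()
        for r in self.reads:
            if r.read_id in ids:
                raise ValueError(f"duplicate read id {r.read_id!r}")
            ids.add(r.read_id)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def per_genome_counts(self) -> dict[str | None, int]:
        counts: dict[str | None, int] = {}
        for r in self.reads:
            counts[r.genome_code] = counts.get(r.genome_code, 0) + 1
        return counts

    def subset(self, read_ids: Iterable[str]) -> "ReadPool":
        wanted = set(read_ids)
        return ReadPool([r for r in self.reads if r.read_id in wanted],
                        self.uniform_length)


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            raise ValueError(f"{path}: empty sequence file")
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: not recognizable as FASTA or FASTQ")


def read_records(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (id, uppercase sequence) pairs from a FASTA or FASTQ file."""
    path = Path(path)
    fmt = _sniff_format(path)
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper()


def load_and_trim(paths: Sequence[str | Path], target_length: int = 100,
                  min_acgt_fraction: float = 0.95,
                  infer_codes: bool = True) -> ReadPool:
    """Load reads, keep the 5' prefix of ``target_length`` bases, drop short or
    N-rich reads.

    A read is retained when it has at least ``target_length`` bases and, after
    trimming, its fraction of unambiguous (ACGT) bases is at least
    ``min_acgt_fraction``.  Input order across files is preserved.  Drop
    counts are logged per file.
    """
    reads: list[TaggedRead] = []
    for path in paths:
        n_short = n_ambig = n_kept = 0
        for rid, seq in read_records(path):
            if len(seq) < target_length:
                n_short += 1
                continue
            trimmed = seq[:target_length]
            if any(c not in VALID_BASES for c in trimmed):
                trimmed = "".join(c if c in VALID_BASES else "N" for c in trimmed)
            acgt = sum(1 for c in trimmed if c != "N")
            if acgt < min_acgt_fraction * target_length:
                n_ambig += 1
                continue
            code = genome_code_from_id(rid) if infer_codes else None
            reads.append(TaggedRead(rid, trimmed, code))
            n_kept += 1
        logger.info("%s: kept %d reads, dropped %d short, %d ambiguous",
                    path, n_kept, n_short, n_ambig)
    if not reads:
        raise ValueError("no reads retained after trimming and filtering")
    return ReadPool(reads, target_length)


def sample_standard_fraction(pool: ReadPool, genome_sizes: Mapping[str, int],
                             fraction: float, seed: int) -> ReadPool:
    """Sample, per genome, reads totalling ``fraction`` of that genome's size.

    Interspecific comparisons are biased when genomes contribute unequal
    effective coverage, so each genome contributes
    ``round(fraction * genome_size / read_length)`` reads, sampled uniformly
    without replacement with a fixed seed.
    """
    if not 0 < fraction <= 0.05:
        raise ValueError(f"fraction {fraction} out of the sensible range (0, 0.05]")
    by_code: dict[str | None, list[int]] = {}
    for idx, r in enumerate(pool.reads):
        by_code.setdefault(r.genome_code, []).append(idx)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for code in sorted(by_code, key=str):
        if code not in genome_sizes:
            raise ValueError(f"genome size unknown for provenance code {code!r}")
        want = int(round(fraction * genome_sizes[code] / pool.uniform_length))
        idxs = by_code[code]
        if want > len(idxs):
            achievable = len(idxs) * pool.uniform_length / genome_sizes[code]
            raise ValueError(
                f"genome {code}: requested fraction {fraction} needs {want} reads "
                f"but only {len(idxs)} available (achievable fraction "
                f"{achievable:.2e})")
        chosen.extend(rng.choice(idxs, size=want, replace=False))
    chosen.sort()
    return ReadPool([pool.reads[i] for i in chosen], pool.uniform_length)


def write_fasta(reads: Iterable[TaggedRead], path: str | Path) -> None:
    records = (SeqRecord(Seq(r.seq), id=r.read_id, description="") for r in reads)
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[TaggedRead], path: str | Path,
                quality: int = 40) -> None:
    """FASTQ output with uniform placeholder qualities."""
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(r.seq)
            yield rec
    SeqIO.write(records(), str(path), "fastq")
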