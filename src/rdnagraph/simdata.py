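"""Synthetic 5S rDNA read sets with exact ground truth.

A 5S rDNA unit is modelled as a conserved coding region (~120 bp) followed by
an intergenic spacer (IGS); units are concatenated head-to-tail into tandem
arrays embedded in random background sequence.  Divergent unit families are
derived from a base family by substituting a controlled fraction of positions
(gene and IGS separately) and optionally changing the IGS length, which is how
homoeologous families of an allopolyploid are emulated.  Sequencing is
modelled as fixed-length single-end reads with i.i.d. substitution errors and
random strand; every read's source family, position and strand are recorded in
a ledger so downstream clustering, topology and quantification can be scored
against exact truth.

Mutated positions are drawn as a prefix of a seeded permutation, so for a
fixed seed the mutation set at divergence d1 < d2 is a subset of the set at
d2.  Sweeps over divergence with a fixed seed therefore change only the newly
mutated positions, which makes calibration curves (e.g. k-mer score vs IGS
divergence) smooth and monotone by construction rather than by luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from rdnagraph._align import decode, encode
from rdnagraph.readio import ReadPool, TaggedRead, write_fasta

#: Synthetic stand-in for the conserved ~120 bp 5S coding region.  Generated
#: once from a fixed random draw; it is not a natural 5S sequence, only its
#: length and its conservation across simulated families matter.
DEFAULT_GENE = (
    "TGCGAGGGATTGTCTTGGTTTCTATAATAGGTCGGTTAGTGCAGTGAATGTGCCATTGAG"
    "ATGGGCTCTCGGATGACCCTAAGCCCCAGACGTAAAGTGCTGATTTCGGTTAGAAACCAC"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform random nucleotide string."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


@dataclass(frozen=True)
class UnitFamilySpec:
    """One 5S rDNA unit family: conserved gene + divergent IGS, array size."""

    family_id: str
    gene_seq: str
    igs_seq: str
    copy_number: int

    def __post_init__(self):
        if len(self.gene_seq) < 50:
            raise ValueError("gene_seq must be at least 50 bp")
        if len(self.igs_seq) < 50:
            raise ValueError("igs_seq must be at least 50 bp")
        if self.copy_number < 1:
            raise ValueError("copy_number must be positive")

    @property
    def monomer(self) -> str:
        return self.gene_seq + self.igs_seq

    @property
    def monomer_length(self) -> int:
        return len(self.gene_seq) + len(self.igs_seq)


@dataclass(frozen=True)
class GenomeSpec:
    """A simulated genome: provenance code, unit families, and total size."""

    genome_code: str
    families: tuple[UnitFamilySpec, ...]
    genome_size: int

    def __post_init__(self):
        if len(self.genome_code) != 3 or not self.genome_code.isalnum():
            raise ValueError("genome_code must be a 3-character alphanumeric code")
        fam_ids = [f.family_id for f in self.families]
        if len(set(fam_ids)) != len(fam_ids):
            raise ValueError("family ids must be unique within a genome")
        if self.rdna_length > self.genome_size:
            raise ValueError("total array length exceeds genome size")

    @property
    def rdna_length(self) -> int:
        return sum(f.monomer_length * f.copy_number for f in self.families)

    @property
    def background_fraction(self) -> float:
        return 1.0 - self.rdna_length / self.genome_size


@dataclass(frozen=True)
class ReadSimParams:
    """Read simulation settings (Illumina-like, substitution errors only)."""

    read_length: int = 100
    coverage_or_count: int | float = 3000
    substitution_rate: float = 0.005
    rng_seed: int = 0

    def __post_init__(self):
        if not 100 <= self.read_length <= 150:
            raise ValueError("read_length must lie in 100-150")
        if not 0.0 <= self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must lie in [0, 0.1]")

    def n_reads(self, genome_size: int) -> int:
        if isinstance(self.coverage_or_count, int):
            return self.coverage_or_count
        return int(round(self.coverage_or_count * genome_size / self.read_length))


def make_family(family_id: str, igs_length: int = 250, copy_number: int = 50,
                seed: int = 0, gene_seq: str = DEFAULT_GENE) -> UnitFamilySpec:
    """A fresh unit family with the shared gene and a random IGS."""
    rng = np.random.default_rng(seed)
    return UnitFamilySpec(family_id, gene_seq, random_seq(igs_length, rng),
                          copy_number)


def _mutate_region(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute round(divergence * len) positions, nested across divergences.

    The permutation and the per-position substitution offsets are drawn for
    the whole region regardless of divergence, so a larger divergence with the
    same generator state extends the mutation set of a smaller one.
    """
    codes = encode(seq).copy()
    perm = rng.permutation(len(seq))
    offsets = rng.integers(1, 4, size=len(seq))
    n_mut = int(round(divergence * len(seq)))
    pos = perm[:n_mut]
    codes[pos] = (codes[pos] + offsets[:n_mut]) % 4
    return decode(codes)


def mutate_family(base: UnitFamilySpec, gene_divergence: float,
                  igs_divergence: float, length_indel: int = 0,
                  seed: int = 0, family_id: str | None = None,
                  copy_number: int | None = None) -> UnitFamilySpec:
    """Derive a diverged unit family from ``base``.

    ``gene_divergence`` and ``igs_divergence`` are the fractions of positions
    substituted in the coding region and the spacer; ``length_indel`` inserts
    (positive) or deletes (negative) a contiguous random block in the IGS.
    Deterministic for a fixed seed.
    """
    for name, div in (("gene_divergence", gene_divergence),
                      ("igs_divergence", igs_divergence)):
        if not 0.0 <= div <= 0.5:
            raise ValueError(f"{name}={div} outside the supported range [0, 0.5]")
    if abs(length_indel) >= len(base.igs_seq):
        raise ValueError("length_indel must be smaller than the IGS length")
    gene_rng, igs_rng, indel_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3))
    gene = _mutate_region(base.gene_seq, gene_divergence, gene_rng)
    igs = _mutate_region(base.igs_seq, igs_divergence, igs_rng)
    if length_indel > 0:
        at = int(indel_rng.integers(0, len(igs) + 1))
        igs = igs[:at] + random_seq(length_indel, indel_rng) + igs[at:]
    elif length_indel < 0:
        cut = -length_indel
        at = int(indel_rng.integers(0, len(igs) - cut + 1))
        igs = igs[:at] + igs[at + cut:]
    return UnitFamilySpec(
        family_id if family_id is not None else base.family_id,
        gene, igs,
        copy_number if copy_number is not None else base.copy_number)


def build_array(family: UnitFamilySpec) -> str:
    """Head-to-tail tandem array of the family's monomer."""
    return family.monomer * family.copy_number


@dataclass
class SimulatedReads:
    """A simulated read pool plus its ground-truth ledger.

    Ledger columns: read_id, genome_code, family_id ('bg' for background),
    start (0-based, in genome coordinates), strand ('+'/'-') and unit_phase
    (read start modulo the monomer length, within the source array; -1 for
    background reads).
    """

    pool: ReadPool
    ledger: pd.DataFrame
    genome: GenomeSpec
    params: ReadSimParams
    segments: list[tuple[int, int, str]] = field(default_factory=list)

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.ledger["read_id"], self.ledger["family_id"]))

    def strand_of(self) -> dict[str, str]:
        return dict(zip(self.ledger["read_id"], self.ledger["strand"]))

    def write(self, fasta_path: str | Path, ledger_path: str | Path) -> None:
        write_fasta(self.pool.reads, fasta_path)
        self.ledger.to_csv(ledger_path, sep="\t", index=False)


def build_genome_sequence(genome: GenomeSpec, seed: int) -> tuple[str, list]:
    """Materialize the genome: arrays separated by random background.

    Returns the sequence and a list of (start, end, family_id) array segments
    (0-based half-open).  Background fills the gaps before, between and after
    the arrays in equal parts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB6]))
    arrays = [(f.family_id, build_array(f)) for f in genome.families]
    bg_total = genome.genome_size - sum(len(a) for _, a in arrays)
    n_gaps = len(arrays) + 1
    gap_sizes = [bg_total // n_gaps] * n_gaps
    gap_sizes[-1] += bg_total - sum(gap_sizes)
    parts: list[str] = []
    segments: list[tuple[int, int, str]] = []
    pos = 0
    for gap, (fam_id, arr) in zip(gap_sizes, arrays):
        parts.append(random_seq(gap, rng))
        pos += gap
        parts.append(arr)
        segments.append((pos, pos + len(arr), fam_id))
        pos += len(arr)
    parts.append(random_seq(gap_sizes[-1], rng))
    return "".join(parts), segments


def simulate_reads(genome: GenomeSpec, params: ReadSimParams) -> SimulatedReads:
    """Simulate fixed-length reads with substitution errors and random strand."""
    seq, segments = build_genome_sequence(genome, params.rng_seed)
    L = params.read_length
    for start, end, fam_id in segments:
        if end - start < L:
            raise ValueError(
                f"array {fam_id} ({end - start} bp) shorter than read length {L}")
    if len(seq) < L:
        raise ValueError("genome shorter than read length")
    n = params.n_reads(genome.genome_size)
    rng = np.random.default_rng(np.random.SeedSequence([params.rng_seed, 0x5D]))
    codes = encode(seq)
    starts = rng.integers(0, len(seq) - L + 1, size=n)
    minus = rng.random(n) < 0.5
    err = rng.random((n, L)) < params.substitution_rate
    err_offsets = rng.integers(1, 4, size=(n, L))

    reads: list[TaggedRead] = []
    rows = []
    seg_starts = np.array([s for s, _, _ in segments])
    seg_ends = np.array([e for _, e, _ in segments])
    seg_ids = [f for _, _, f in segments]
    monomer_len = {f.family_id: f.monomer_length for f in genome.families}
    for i in range(n):
        s = int(starts[i])
        r = codes[s:s + L].copy()
        if minus[i]:
            r = np.where(r < 4, 3 - r, np.uint8(4)).astype(np.uint8)[::-1]
        e = err[i]
        r[e] = (r[e] + err_offsets[i, e]) % 4
        rid = f"{genome.genome_code}_{i:06d}"
        j = int(np.searchsorted(seg_starts, s, side="right")) - 1
        fam = seg_ids[j] if j >= 0 and s < seg_ends[j] else "bg"
        phase = (s - int(seg_starts[j])) % monomer_len[fam] if fam != "bg" else -1
        reads.append(TaggedRead(rid, decode(r), genome.genome_code))
        rows.append((rid, genome.genome_code, fam, s,
                     "-" if minus[i] else "+", phase))
    ledger = pd.DataFrame(
        rows, columns=["read_id", "genome_code", "family_id", "start",
                       "strand", "unit_phase"])
    return SimulatedReads(ReadPool(reads, L), ledger, genome, params, segments)


# ---------------------------------------------------------------------------
# Scenario builders: the standard study designs exercised by tests and the
# command-line `simulate` subcommand.
# ---------------------------------------------------------------------------

def diploid_genome(code: str = "DIP", igs_length: int = 180,
                   copy_number: int = 50, genome_size: int = 100_000,
                   seed: int = 0) -> GenomeSpec:
    """A diploid-like genome with a single homogeneous 5S family."""
    fam = make_family(f"{code}.A", igs_length, copy_number, seed)
    return GenomeSpec(code, (fam,), genome_size)


def allotetraploid_genome(code: str = "ALO", base: UnitFamilySpec | None = None,
                          igs_divergence: float = 0.2, skew: float = 1.0,
                          igs_length: int = 250, copy_number: int = 40,
                          genome_size: int = 150_000,
                          seed: int = 0) -> GenomeSpec:
    """An allotetraploid-like genome: two families sharing the gene, with IGS
    diverged by ``igs_divergence`` and copy numbers in ratio ``skew`` : 1."""
    if base is None:
        base = make_family(f"{code}.A", igs_length, copy_number, seed)
    else:
        base = UnitFamilySpec(f"{code}.A", base.gene_seq, base.igs_seq, copy_number)
    fam_b = mutate_family(base, 0.0, igs_divergence, seed=seed + 1,
                          family_id=f"{code}.B",
                          copy_number=max(1, int(round(copy_number / skew))))
    return GenomeSpec(code, (base, fam_b), genome_size)


def triad_genomes(seed: int = 0, igs_divergence: float = 0.2, skew: float = 1.0,
                  igs_length: int = 250, copy_number: int = 40,
                  genome_size: int = 150_000,
                  outgroup: bool = False) -> dict[str, GenomeSpec]:
    """Progenitor/progenitor/hybrid study design for comparative clustering.

    P1 carries family A, P2 carries family B = A diverged by
    ``igs_divergence`` in the IGS, and the hybrid HYB carries both (B at copy
    number reduced by ``skew``).  With ``outgroup`` a genome OUT with an
    unrelated IGS family is added; it shares only the conserved gene.
    """
    fam_a = make_family("famA", igs_length, copy_number, seed)
    fam_b = mutate_family(fam_a, 0.0, igs_divergence, seed=seed + 1,
                          family_id="famB")
    hyb_b = UnitFamilySpec("famB", fam_b.gene_seq, fam_b.igs_seq,
                           max(1, int(round(copy_number / skew))))
    genomes = {
        "P1X": GenomeSpec("P1X", (fam_a,), genome_size),
        "P2X": GenomeSpec("P2X", (fam_b,), genome_size),
        "HYB": GenomeSpec("HYB", (fam_a, hyb_b), genome_size),
    }
    if outgroup:
        fam_o = make_family("famO", igs_length, copy_number, seed + 7)
        genomes["OUT"] = GenomeSpec("OUT", (fam_o,), genome_size)
    return genomes


def hybrid_with_unsampled_donor(seed: int = 0, igs_divergence: float = 0.2,
                                igs_length: int = 250, copy_number: int = 40,
                                genome_size: int = 150_000) -> dict[str, GenomeSpec]:
    """P1, P2 and a hybrid that additionally carries a third family from a
    donor genome absent from the comparison (introgression-like design)."""
    genomes = triad_genomes(seed, igs_divergence, 1.0, igs_length,
                            copy_number, genome_size)
    fam_d = make_family("famD", igs_length, copy_number, seed + 13)
    hyb = genomes["HYB"]
    genomes["HYB"] = GenomeSpec("HYB", hyb.families + (fam_d,),
                                genome_size + fam_d.monomer_length * copy_number)
    return genomes


_SCENARIOS = {
    "diploid": diploid_genome,
    "allotetraploid": allotetraploid_genome,
    "triad": triad_genomes,
    "unsampled_donor": hybrid_with_unsampled_donor,
}


def simulate_from_config(config: Mapping, seed: int | None = None
                         ) -> dict[str, SimulatedReads]:
    """Run a scenario described by a YAML-style mapping.

    Recognized keys: ``scenario`` (diploid | allotetraploid | triad |
    unsampled_donor), ``seed``, ``read_length``, ``substitution_rate``,
    ``reads_per_genome`` (int) or ``genome_fraction`` (float), plus the
    scenario builder's own keyword arguments.
    """
    cfg = dict(config)
    scenario = cfg.pop("scenario", "diploid")
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {sorted(_SCENARIOS)}")
    if seed is None:
        seed = int(cfg.pop("seed", 0))
    else:
        cfg.pop("seed", None)
    if "genome_fraction" in cfg:
        count: int | float = float(cfg.pop("genome_fraction"))
    else:
        count = int(cfg.pop("reads_per_genome", 3000))
    params_kw = {k: cfg.pop(k) for k in ("read_length", "substitution_rate")
                 if k in cfg}
    built = _SCENARIOS[scenario](seed=seed, **cfg)
    if isinstance(built, GenomeSpec):
        built = {built.genome_code: built}
    out = {}
    for i, (code, genome) in enumerate(sorted(built.items())):
        params = ReadSimParams(coverage_or_count=count,
                               rng_seed=seed + 101 * (i + 1), **params_kw)
        out[code] = simulate_reads(genome, params)
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return cfg
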