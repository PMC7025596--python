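"""Shared simulated datasets (session-scoped: graphs are the expensive part)."""

import numpy as np
import pytest

from rdnagraph import simdata
from rdnagraph.cluster_graph import build_overlap_graph, cluster_by_modularity


def tiling_reads(monomer: str, read_length: int = 100, stride: int = 5,
                 prefix: str = "til"):
    """Error-free + strand reads tiling a circular monomer at fixed stride."""
    from rdnagraph.readio import ReadPool, TaggedRead
    doubled = monomer + monomer
    reads = [
        TaggedRead(f"{prefix}_{i:04d}", doubled[p:p + read_length])
        for i, p in enumerate(range(0, len(monomer), stride))
    ]
    return ReadPool(reads, read_length)


@pytest.fixture(scope="session")
def array_sim():
    """Error-free reads of a homogeneous tandem array (300 bp monomer, 50
    copies, ~400 reads): the canonical single-family circle."""
    fam = simdata.make_family("ARR.A", igs_length=180, copy_number=50, seed=3)
    genome = simdata.GenomeSpec("ARR", (fam,), fam.monomer_length * 50)
    params = simdata.ReadSimParams(coverage_or_count=400,
                                   substitution_rate=0.0, rng_seed=5)
    return simdata.simulate_reads(genome, params)


@pytest.fixture(scope="session")
def array_graph(array_sim):
    return build_overlap_graph(array_sim.pool)


@pytest.fixture(scope="session")
def array_cluster(array_graph):
    clusters = cluster_by_modularity(array_graph, seed=0)
    assert clusters, "array simulation must produce a cluster"
    return clusters[0]


@pytest.fixture(scope="session")
def allo_sim():
    """Allotetraploid-like read set: two families sharing the gene, IGS
    diverged 20%, embedded in background, 0.5% sequencing error."""
    genome = simdata.allotetraploid_genome(igs_divergence=0.2, seed=11)
    params = simdata.ReadSimParams(coverage_or_count=3000,
                                   substitution_rate=0.005, rng_seed=11)
    return simdata.simulate_reads(genome, params)


@pytest.fixture(scope="session")
def allo_graph(allo_sim):
    return build_overlap_graph(allo_sim.pool)


@pytest.fixture(scope="session")
def allo_cluster(allo_graph):
    clusters = cluster_by_modularity(allo_graph, seed=0)
    return clusters[0]
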