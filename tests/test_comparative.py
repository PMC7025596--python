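"""Comparative clustering, parentage verdicts, NJ trees, clade ratios."""

import numpy as np
import pytest

from rdnagraph import simdata
from rdnagraph.comparative import (
    CladeRatio,
    LoopComposition,
    clade_ratio,
    comparative_cluster,
    diagnose_parentage,
    merge_pools,
    nj_tree,
    p_distance,
)
from rdnagraph.readio import ReadPool, TaggedRead

GENE = simdata.DEFAULT_GENE


def simulate_triad(seed=5, igs_divergence=0.2, reads_per=1200, outgroup=False,
                   err=0.005):
    genomes = simdata.triad_genomes(seed=seed, igs_divergence=igs_divergence,
                                    outgroup=outgroup)
    pools, sims = [], {}
    for i, (code, genome) in enumerate(sorted(genomes.items())):
        sim = simdata.simulate_reads(
            genome, simdata.ReadSimParams(coverage_or_count=reads_per,
                                          substitution_rate=err,
                                          rng_seed=seed + 11 * i))
        pools.append(sim.pool)
        sims[code] = sim
    return pools, sims


@pytest.fixture(scope="module")
def triad_result():
    pools, sims = simulate_triad()
    res = comparative_cluster(pools, GENE, "HYB", seed=0)
    return res, sims


class TestComparativeCluster:
    def test_two_loops_exclusive_to_parents(self, triad_result):
        res, _ = triad_result
        assert len(res.compositions) == 2
        assert {c.exclusive_to for c in res.compositions} == {"P1X", "P2X"}

    def test_hybrid_occupies_both_loops_and_junction(self, triad_result):
        res, _ = triad_result
        for comp in res.compositions:
            assert comp.per_genome_read_counts.get("HYB", 0) > 0
        assert res.junction_counts.get("HYB", 0) > 0

    def test_composition_counts_conserved(self, triad_result):
        res, _ = triad_result
        in_loops = sum(c.size for c in res.compositions)
        junction = len(res.topology.genic_vertices)
        assert in_loops + junction <= res.rdna_cluster.size
        for comp in res.compositions:
            assert comp.size == sum(comp.per_genome_read_counts.values())

    def test_label_blindness(self, triad_result):
        # stripping provenance codes must not change cluster membership
        res, sims = triad_result
        pools = [s.pool for _, s in sorted(sims.items())]
        merged = merge_pools(pools)
        stripped = ReadPool(
            [TaggedRead(r.read_id, r.seq, None) for r in merged.reads],
            merged.uniform_length)
        from rdnagraph.cluster_graph import (build_overlap_graph,
                                             cluster_by_modularity)
        g1 = build_overlap_graph(merged)
        g2 = build_overlap_graph(stripped)
        c1 = cluster_by_modularity(g1, seed=0)
        c2 = cluster_by_modularity(g2, seed=0)
        assert [c.read_ids for c in c1] == [c.read_ids for c in c2]

    def test_duplicate_codes_rejected(self, triad_result):
        _, sims = triad_result
        pool = sims["P1X"].pool
        with pytest.raises(ValueError, match="duplicate genome codes"):
            merge_pools([pool, pool])


class TestDiagnoseParentage:
    def comp(self, loop_id, counts, exclusive):
        return LoopComposition(loop_id, counts, exclusive)

    def test_both_parents_contribute(self):
        comps = [self.comp(1, {"P1X": 50, "HYB": 40}, "P1X"),
                 self.comp(2, {"P2X": 45, "HYB": 38}, "P2X")]
        v = diagnose_parentage(comps, ["P1X", "P2X"], "HYB")
        assert v.parent_support == {"P1X": "contributes", "P2X": "contributes"}
        assert v.hybrid_reads_span_multiple_loops

    def test_exclusive_loop_without_hybrid_reads_means_absent(self):
        comps = [self.comp(1, {"P1X": 50, "HYB": 40}, "P1X"),
                 self.comp(2, {"OUT": 60}, "OUT")]
        v = diagnose_parentage(comps, ["P1X", "OUT"], "HYB")
        assert v.parent_support["OUT"] == "absent"

    def test_single_mixed_loop_is_ambiguous(self):
        comps = [self.comp(1, {"P1X": 30, "P2X": 30, "HYB": 30}, "shared")]
        v = diagnose_parentage(comps, ["P1X", "P2X"], "HYB")
        assert v.parent_support == {"P1X": "ambiguous", "P2X": "ambiguous"}
        assert not v.hybrid_reads_span_multiple_loops

    def test_hybrid_only_loop_flagged(self):
        comps = [self.comp(1, {"HYB": 80}, "hybrid_only")]
        v = diagnose_parentage(comps, ["P1X"], "HYB")
        assert v.hybrid_only_loops == [1]
        assert any("unsampled donor" in n for n in v.notes)


class TestNJTree:
    def test_recovers_true_four_taxon_split(self):
        # distances satisfy the four-point condition for split ab | cd;
        # the oracle is the condition itself evaluated on all three splits
        rng = np.random.default_rng(3)
        root = "".join("ACGT"[b] for b in rng.integers(0, 4, 200))

        def mutate(seq, n, rng):
            pos = rng.choice(len(seq), size=n, replace=False)
            out = list(seq)
            for p in pos:
                out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
            return "".join(out)

        left = mutate(root, 30, rng)
        right = mutate(root, 30, rng)
        seqs = [("a", mutate(left, 6, rng)), ("b", mutate(left, 8, rng)),
                ("c", mutate(right, 7, rng)), ("d", mutate(right, 5, rng))]
        d = {(x, y): p_distance(sx, sy)
             for x, sx in seqs for y, sy in seqs}
        splits = {
            "ab|cd": d[("a", "b")] + d[("c", "d")],
            "ac|bd": d[("a", "c")] + d[("b", "d")],
            "ad|bc": d[("a", "d")] + d[("b", "c")],
        }
        assert min(splits, key=splits.get) == "ab|cd"
        tree = nj_tree(seqs)
        subsets = {frozenset(t.name for t in node.tips())
                   for node in tree.non_tips(include_self=False)}
        assert frozenset({"a", "b"}) in subsets or \
            frozenset({"c", "d"}) in subsets

    def test_identical_sequences_are_siblings_with_zero_branches(self):
        seqs = [("x1", "ACGT" * 30), ("x2", "ACGT" * 30),
                ("y", "TGCA" * 30), ("z", "GGCA" * 30)]
        tree = nj_tree(seqs)
        t1 = tree.find("x1")
        assert {t.name for t in t1.parent.tips()} >= {"x1", "x2"}
        assert t1.length == pytest.approx(0.0, abs=1e-9)
        assert tree.find("x2").length == pytest.approx(0.0, abs=1e-9)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            nj_tree([("a", "ACGT"), ("b", "ACGT")])


def test_contigs_group_with_their_source_family(allo_sim, allo_graph,
                                                allo_cluster):
    """Contigs assembled from a two-family cluster fall on the side of the
    reference split matching their supporting reads' true family."""
    from rdnagraph.consensus import assemble_contigs
    from rdnagraph.topology import orient_reads

    og = orient_reads(allo_graph, allo_cluster)
    oriented = og.oriented_seqs(allo_sim.pool)
    overlaps = [(u, v, d["offset"])
                for u, v, d in og.digraph.edges(data=True) if d["offset"] > 0]
    contigs = assemble_contigs(oriented, overlaps)
    fams = allo_sim.family_of()
    pure = []
    for c in contigs:
        members = {fams[rid] for rid in c.read_ids}
        if len(members) == 1 and len(c.seq) >= 150 and "bg" not in members:
            pure.append((c, members.pop()))
    # chains crossing the shared gene junction mix families by construction;
    # the single-family contigs must side with their source family
    assert len(pure) >= 1
    fam_a, fam_b = allo_sim.genome.families
    for contig, true_fam in pure:
        da = p_distance(contig.seq, fam_a.monomer * 2)
        db = p_distance(contig.seq, fam_b.monomer * 2)
        closer = fam_a.family_id if da < db else fam_b.family_id
        assert closer == true_fam


class TestCladeRatio:
    def anchored_reads(self, mix=0.7, seed=31, n_reads=30_000):
        fam_a = simdata.make_family("A", igs_length=250,
                                    copy_number=max(1, int(100 * mix)),
                                    seed=21)
        fam_b = simdata.mutate_family(fam_a, 0.0, 0.2, seed=22,
                                      family_id="B",
                                      copy_number=max(1, int(100 * (1 - mix))))
        families = tuple(f for f, cop in ((fam_a, int(100 * mix)),
                                          (fam_b, int(100 * (1 - mix))))
                         if cop > 0)
        genome = simdata.GenomeSpec("MIX", families, 300_000)
        sim = simdata.simulate_reads(
            genome, simdata.ReadSimParams(coverage_or_count=n_reads,
                                          substitution_rate=0.005,
                                          rng_seed=seed))
        led = sim.ledger
        sel = led[(led.family_id != "bg") & led.unit_phase.between(160, 170)]
        by_id = {r.read_id: r.seq for r in sim.pool.reads}
        seqs = [(rid, by_id[rid]) for rid in sel.read_id]
        truth = (sel.family_id == "A").mean()
        return seqs, truth, fam_a, fam_b

    def test_pure_mixture_gives_all_or_nothing(self):
        seqs, _, fam_a, fam_b = self.anchored_reads(mix=1.0)
        cr = clade_ratio(seqs, ("refA", fam_a.monomer),
                         ("refB", fam_b.monomer), sample_size=100, seed=1)
        assert cr.frac_a == 1.0 and cr.frac_b == 0.0

    def test_identical_references_rejected(self):
        seqs, _, fam_a, _ = self.anchored_reads()
        with pytest.raises(ValueError, match="not separable"):
            clade_ratio(seqs, ("refA", fam_a.monomer),
                        ("refB", fam_a.monomer))

    def test_mixture_recovered_within_binomial_interval(self):
        seqs, truth, fam_a, fam_b = self.anchored_reads(mix=0.7)
        n = min(150, len(seqs))
        cr = clade_ratio(seqs, ("refA", fam_a.monomer),
                         ("refB", fam_b.monomer), sample_size=n, seed=2)
        se = np.sqrt(truth * (1 - truth) / cr.n_sampled)
        assert abs(cr.frac_a - truth) <= 1.96 * se + 1e-9
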