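import numpy as np
import pytest

from replicomp.paralog_families import (
    ParalogFamily,
    build_similarity_graph,
    family_stats,
    find_paralog_families,
    flag_multidomain,
    mask_low_complexity,
    shannon_entropy,
    symmetrify_and_close,
)
from replicomp.synthetic_data import ProteomeSimSpec, mutate_to_identity, simulate_proteomes

from conftest import make_records, random_protein


class TestMaskLowComplexity:
    def test_homopolymer_fully_masked(self):
        assert mask_low_complexity("Q" * 12) == "X" * 12

    def test_random_sequence_unchanged(self, rng):
        seq = random_protein(rng, 300)
        assert mask_low_complexity(seq, entropy_threshold=2.0) == seq

    def test_idempotent(self, rng):
        seq = random_protein(rng, 50) + "S" * 20 + random_protein(rng, 50)
        once = mask_low_complexity(seq)
        assert mask_low_complexity(once) == once

    def test_short_sequence_untouched(self):
        assert mask_low_complexity("QQQ") == "QQQ"

    def test_entropy_of_uniform_window_exceeds_threshold(self, rng):
        # a uniform random 12-mer has expected entropy well above 2.2 bits
        vals = [shannon_entropy(random_protein(np.random.default_rng(s), 12))
                for s in range(200)]
        assert np.mean(vals) > 2.2


class TestSimilarityGraph:
    def test_only_identical_pair_connected(self, rng):
        seq = random_protein(rng, 120)
        recs = make_records({"a": seq, "b": seq, "c": random_protein(rng, 120)})
        sim = build_similarity_graph(recs)
        assert set(sim.graph.edges) == {("a", "b"), ("b", "a")}

    def test_threshold_above_everything_gives_empty_graph(self, rng):
        seq = random_protein(rng, 100)
        recs = make_records({"a": seq, "b": mutate_to_identity(seq, 60, seed=1)})
        sim = build_similarity_graph(recs, min_identity=99.0)
        assert sim.graph.number_of_edges() == 0

    def test_edges_match_exhaustive_alignment_oracle(self, rng):
        """Graph edges equal thresholding a direct all-pairs alignment."""
        from replicomp.alignment_orthology import local_align

        base = [random_protein(rng, 100) for _ in range(5)]
        seqs = {}
        for i, s in enumerate(base):
            seqs[f"p{i}a"] = s
            seqs[f"p{i}b"] = mutate_to_identity(s, 70, seed=i)
        recs = make_records(seqs)
        sim = build_similarity_graph(recs, min_shared_kmers=0, mask=False)
        expected = set()
        for q in recs:
            for s in recs:
                if q.id == s.id:
                    continue
                aln = local_align(q, s)
                if aln and aln.identity_pct >= 30 and aln.coverage_smaller >= 0.5:
                    expected.add((q.id, s.id))
        assert set(sim.graph.edges) == expected


class TestSymmetrifyAndClose:
    def test_chain_closes_transitively(self, rng):
        anchor = random_protein(rng, 200)
        # a-b and b-c pass the threshold; a-c may not: one family regardless
        recs = make_records({
            "a": anchor,
            "b": mutate_to_identity(anchor, 60, seed=1),
            "c": mutate_to_identity(mutate_to_identity(anchor, 60, seed=1), 60, seed=2),
        })
        fams, singles, _ = find_paralog_families(recs, min_identity=40.0)
        assert len(fams) == 1 and fams[0].members == frozenset("abc")
        assert singles == []

    def test_unrelated_proteins_all_singletons(self, rng):
        recs = make_records({f"p{i}": random_protein(rng, 150) for i in range(5)})
        fams, singles, excluded = find_paralog_families(recs)
        assert fams == [] and len(singles) == 5 and excluded == []

    def test_planted_families_recovered_exactly(self):
        for seed in (1, 2, 3):
            spec = ProteomeSimSpec(
                species=["A"], genes_per_species=6, core_fraction=1.0,
                pairwise_identity=100.0,
                paralog_families=[(3, 70.0), (5, 70.0), (12, 70.0)], seed=seed,
            )
            prot, truth = simulate_proteomes(spec)
            fams, singles, _ = find_paralog_families(prot["A"])
            assert {f.members for f in fams} == set(truth.paralog_families_truth)
            assert len(singles) == 6

    def test_asymmetric_edge_recheck_keeps_true_pairs(self, rng):
        seq = random_protein(rng, 150)
        recs = make_records({"a": seq, "b": mutate_to_identity(seq, 80, seed=3)})
        sim = build_similarity_graph(recs)
        # force asymmetry: drop one direction, the re-check must restore it
        if sim.graph.has_edge("b", "a"):
            sim.graph.remove_edge("b", "a")
        fams, _, _ = symmetrify_and_close(sim, recs)
        assert fams and fams[0].members == frozenset("ab")


class TestFlagMultidomain:
    def test_fusion_protein_flagged(self, rng):
        x = random_protein(rng, 150)
        y = random_protein(rng, 150)
        recs = make_records({
            "fusion": x + y,
            "partner_x": x,
            "partner_y": y,
        })
        sim = build_similarity_graph(recs, min_coverage=0.5)
        by_id = {r.id: r for r in recs}
        assert flag_multidomain("fusion", sim, by_id)

    def test_same_span_partners_not_flagged(self, rng):
        seq = random_protein(rng, 200)
        recs = make_records({
            "p": seq,
            "q": mutate_to_identity(seq, 80, seed=1),
            "r": mutate_to_identity(seq, 75, seed=2),
        })
        sim = build_similarity_graph(recs)
        by_id = {r.id: r for r in recs}
        assert not flag_multidomain("p", sim, by_id)

    def test_single_neighbour_never_flagged(self, rng):
        seq = random_protein(rng, 150)
        recs = make_records({"p": seq, "q": mutate_to_identity(seq, 85, seed=1)})
        sim = build_similarity_graph(recs)
        assert not flag_multidomain("p", sim, {r.id: r for r in recs})

    def test_fusion_excluded_from_families(self, rng):
        x = random_protein(rng, 150)
        y = random_protein(rng, 150)
        recs = make_records({
            "fusion": x + y,
            "x1": x,
            "x2": mutate_to_identity(x, 85, seed=1),
            "y1": y,
            "y2": mutate_to_identity(y, 85, seed=2),
        })
        fams, singles, excluded = find_paralog_families(recs)
        assert excluded == ["fusion"]
        assert {f.members for f in fams} == {frozenset({"x1", "x2"}), frozenset({"y1", "y2"})}


class TestFamilyStats:
    def test_forced_example(self):
        fams = [ParalogFamily(frozenset("AB")), ParalogFamily(frozenset("CDE"))]
        stats = family_stats(fams, ["F"], [])
        assert stats.n_with_paralog == 5
        assert stats.n_singletons == 1
        assert stats.pct_with_paralog == 83

    def test_partition_overlap_rejected(self):
        fams = [ParalogFamily(frozenset("AB"))]
        with pytest.raises(ValueError):
            family_stats(fams, ["A"], [])

    def test_published_partition_percentages(self):
        """The printed proteome partition (3,311 with a paralog / 3,008
        singletons; 1,358 in 43 clusters of >= 10) yields 52%, 48%, 21%."""
        from replicomp.datasets import ch34_paralogy_partition

        sizes, n_singletons = ch34_paralogy_partition()
        fams = []
        k = 0
        for s in sizes:
            fams.append(ParalogFamily(frozenset(f"p{k + j}" for j in range(s))))
            k += s
        singles = [f"s{i}" for i in range(n_singletons)]
        stats = family_stats(fams, singles, [])
        assert stats.denominator == 6319
        assert stats.pct_with_paralog == 52
        assert stats.pct_singletons == 48
        assert stats.n_large_clusters == 43
        assert stats.n_in_large_clusters == 1358
        assert stats.pct_in_large_clusters == 21

    def test_counts_conserve_under_exclusion(self, rng):
        spec = ProteomeSimSpec(
            species=["A"], genes_per_species=8, core_fraction=1.0,
            pairwise_identity=100.0, paralog_families=[(4, 75.0)], seed=4,
        )
        prot, _ = simulate_proteomes(spec)
        fams, singles, excluded = find_paralog_families(prot["A"])
        stats = family_stats(fams, singles, excluded)
        assert stats.n_with_paralog + stats.n_singletons + stats.n_multidomain_excluded \
            == len(prot["A"])

    def test_membership_invariant_under_input_order(self, rng):
        spec = ProteomeSimSpec(
            species=["A"], genes_per_species=5, core_fraction=1.0,
            pairwise_identity=100.0, paralog_families=[(3, 70.0)], seed=5,
        )
        prot, _ = simulate_proteomes(spec)
        fams1, s1, _ = find_paralog_families(prot["A"])
        fams2, s2, _ = find_paralog_families(list(reversed(prot["A"])))
        assert {f.members for f in fams1} == {f.members for f in fams2}
        assert sorted(s1) == sorted(s2)
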