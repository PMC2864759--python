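import numpy as np
import pytest
from Bio.Align import substitution_matrices

from replicomp.alignment_orthology import (
    OrthologPair,
    all_vs_all,
    build_ortholog_groups,
    call_orthologs,
    find_syntons,
    local_align,
    venn_partition,
)
from replicomp.synthetic_data import ProteomeSimSpec, mutate_to_identity, simulate_proteomes

from conftest import make_records, random_protein

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_score(a: str, b: str, gap_open=11, gap_extend=1) -> float:
    """Fixed-start enumeration: best affine local alignment score.

    For every start pair (i, j) run an independent forward DP over
    alignments that begin by pairing a[i] with b[j]; the local optimum is
    the maximum over all starts and ends (a local alignment never starts
    or ends with a gap).
    """
    n, m = len(a), len(b)
    best = 0.0
    NEG = float("-inf")
    for i in range(n):
        for j in range(m):
            rows = n - i
            cols = m - j
            M = [[NEG] * cols for _ in range(rows)]
            X = [[NEG] * cols for _ in range(rows)]
            Y = [[NEG] * cols for _ in range(rows)]
            M[0][0] = float(BLOSUM62[a[i]][b[j]])
            for k in range(rows):
                for l in range(cols):
                    if k == 0 and l == 0:
                        continue
                    sub = float(BLOSUM62[a[i + k]][b[j + l]])
                    if k > 0 and l > 0:
                        M[k][l] = sub + max(M[k - 1][l - 1], X[k - 1][l - 1], Y[k - 1][l - 1])
                    if k > 0:
                        X[k][l] = max(M[k - 1][l] - gap_open, X[k - 1][l] - gap_extend)
                    if l > 0:
                        Y[k][l] = max(M[k][l - 1] - gap_open, Y[k][l - 1] - gap_extend)
            local_best = max(max(row) for row in M)
            best = max(best, local_best)
    return best


class TestLocalAlign:
    def test_identical_sequences(self, rng):
        seq = random_protein(rng, 50)
        aln = local_align(("a", seq), ("b", seq))
        assert aln.identity_pct == 100.0
        assert aln.coverage_smaller == 1.0
        assert aln.aligned_columns == 50

    def test_unalignable_pair_reports_none(self):
        assert local_align(("a", "AAAA"), ("b", "CCCC")) is None

    def test_unknown_matrix(self):
        with pytest.raises(ValueError):
            local_align(("a", "MKVL"), ("b", "MKVL"), matrix="NOSUCH")

    def test_score_matches_bruteforce_oracle(self, rng):
        """Aligner score equals the fixed-start enumeration on short pairs."""
        for _ in range(8):
            a = random_protein(rng, int(rng.integers(5, 25)))
            b = random_protein(rng, int(rng.integers(5, 25)))
            expected = brute_force_local_score(a, b)
            aln = local_align(("a", a), ("b", b))
            got = aln.score if aln else 0.0
            assert got == pytest.approx(expected)

    def test_identity_denominator_is_aligned_columns(self):
        # one substitution inside an otherwise identical stretch
        a = "MKVLAWTERY"
        b = "MKVLAGTERY"
        aln = local_align(("a", a), ("b", b))
        assert aln.identity_pct == pytest.approx(90.0)


class TestAllVsAll:
    def test_identical_query_finds_itself(self, rng):
        seqs = {f"p{i}": random_protein(rng, 80) for i in range(5)}
        subjects = make_records(seqs, "B")
        queries = make_records({"q": seqs["p3"]}, "A")
        best = all_vs_all(queries, subjects)
        assert best["q"].subject_id == "p3"
        assert best["q"].identity_pct == 100.0

    def test_prefilter_off_equals_exhaustive(self, rng):
        """With the k-mer screen disabled the result equals a direct
        all-pairs best-score search (lexicographic tie-break)."""
        qs = make_records({f"q{i}": random_protein(rng, 60) for i in range(15)}, "A")
        ss = make_records({f"s{i}": random_protein(rng, 60) for i in range(15)}, "B")
        got = all_vs_all(qs, ss, min_shared_kmers=0)
        for q in qs:
            best_id, best_score = None, 0.0
            for s in sorted(ss, key=lambda r: r.id):
                aln = local_align(q, s)
                if aln is not None and aln.score > best_score:
                    best_id, best_score = s.id, aln.score
            if best_id is None:
                assert q.id not in got
            else:
                assert got[q.id].subject_id == best_id
                assert got[q.id].score == best_score

    def test_tie_breaks_to_smaller_id(self, rng):
        seq = random_protein(rng, 50)
        subjects = make_records({"pB": seq, "pA": seq}, "B")
        best = all_vs_all(make_records({"q": seq}, "A"), subjects)
        assert best["q"].subject_id == "pA"


class TestCallOrthologs:
    def test_planted_pair_reported(self, rng):
        seq = random_protein(rng, 200)
        a = make_records({"a1": seq}, "A")
        b = make_records({"b1": mutate_to_identity(seq, 90, seed=1)}, "B")
        pairs = call_orthologs(a, b)
        assert len(pairs) == 1
        assert pairs[0].identity_pct >= 88

    def test_low_identity_pair_rejected(self, rng):
        seq = random_protein(rng, 200)
        a = make_records({"a1": seq}, "A")
        b = make_records({"b1": mutate_to_identity(seq, 30, seed=2)}, "B")
        assert call_orthologs(a, b) == []

    def test_non_reciprocal_hit_rejected(self, rng):
        seq = random_protein(rng, 200)
        better = mutate_to_identity(seq, 95, seed=3)
        worse = mutate_to_identity(seq, 80, seed=4)
        a = make_records({"a1": worse, "a2": better}, "A")
        b = make_records({"b1": seq}, "B")
        pairs = call_orthologs(a, b)
        # b1's best is a2, so (a1, b1) must not be reported
        assert [(p.protein_a, p.protein_b) for p in pairs] == [("a2", "b1")]

    def test_symmetric_in_argument_order(self, rng):
        spec = ProteomeSimSpec(species=["A", "B"], genes_per_species=12,
                               core_fraction=0.5, pairwise_identity=75.0, seed=9)
        prot, _ = simulate_proteomes(spec)
        ab = {(p.protein_a, p.protein_b) for p in call_orthologs(prot["A"], prot["B"])}
        ba = {(p.protein_b, p.protein_a) for p in call_orthologs(prot["B"], prot["A"])}
        assert ab == ba

    def test_raising_thresholds_never_adds_pairs(self, rng):
        spec = ProteomeSimSpec(species=["A", "B"], genes_per_species=15,
                               core_fraction=0.8, pairwise_identity=60.0, seed=10)
        prot, _ = simulate_proteomes(spec)
        loose = {(p.protein_a, p.protein_b)
                 for p in call_orthologs(prot["A"], prot["B"], 35, 0.5)}
        tight = {(p.protein_a, p.protein_b)
                 for p in call_orthologs(prot["A"], prot["B"], 50, 0.9)}
        assert tight <= loose

    def test_substitution_only_pairs_have_full_coverage(self, rng):
        spec = ProteomeSimSpec(species=["A", "B"], genes_per_species=10,
                               core_fraction=1.0, pairwise_identity=80.0, seed=11)
        prot, _ = simulate_proteomes(spec)
        pairs = call_orthologs(prot["A"], prot["B"])
        # local alignment may clip a negative-scoring substituted terminus,
        # so coverage is full-length up to a residue or two at each end
        assert len(pairs) == 10
        assert all(p.coverage_smaller >= 0.97 for p in pairs)

    def test_same_species_rejected(self, rng):
        a = make_records({"x": random_protein(rng, 50)}, "A")
        with pytest.raises(ValueError):
            call_orthologs(a, a)


class TestGroupsAndVenn:
    @staticmethod
    def pair(a, b):
        return OrthologPair(a, b, 90.0, 1.0, 100.0)

    def test_transitive_group(self):
        groups = build_ortholog_groups(
            {("A", "B"): [self.pair("a1", "b1")], ("B", "C"): [self.pair("b1", "c1")]},
            {"a1": "A", "b1": "B", "c1": "C"},
        )
        assert len(groups) == 1
        assert groups[0]["members"] == ["a1", "b1", "c1"]
        assert groups[0]["species"] == frozenset("ABC")

    def test_no_pairs_no_groups(self):
        assert build_ortholog_groups({}, {}) == []

    def test_two_species_all_core(self):
        groups = [{"members": [f"a{i}", f"b{i}"], "species": frozenset("AB")}
                  for i in range(3)]
        regions = venn_partition(
            groups, {"A": [f"a{i}" for i in range(3)], "B": [f"b{i}" for i in range(3)]}
        )
        assert regions[frozenset("AB")]["n_groups"] == 3
        assert regions[frozenset("A")]["n_groups"] == 0
        assert regions[frozenset("B")]["n_groups"] == 0

    def test_region_counts_partition_everything(self, rng):
        spec = ProteomeSimSpec(species=["A", "B", "C"], genes_per_species=10,
                               core_fraction=0.6, pairwise_identity=85.0, seed=12)
        prot, truth = simulate_proteomes(spec)
        pairs = {}
        for x, y in (("A", "B"), ("A", "C"), ("B", "C")):
            pairs[(x, y)] = call_orthologs(prot[x], prot[y])
        protein_species = {r.id: sp for sp, recs in prot.items() for r in recs}
        groups = build_ortholog_groups(pairs, protein_species)
        regions = venn_partition(groups, {sp: [r.id for r in rs] for sp, rs in prot.items()})
        n_multi = sum(v["n_groups"] for k, v in regions.items() if len(k) > 1)
        n_private = sum(v["n_groups"] for k, v in regions.items() if len(k) == 1)
        grouped = sum(v["n_proteins"] for k, v in regions.items() if len(k) > 1)
        total_proteins = sum(len(rs) for rs in prot.values())
        assert n_multi == len([g for g in groups if len(g["species"]) > 1])
        assert grouped + n_private == total_proteins

    def test_planted_core_recovered_in_venn(self):
        spec = ProteomeSimSpec(species=["A", "B", "C", "D"], genes_per_species=20,
                               core_fraction=0.6, pairwise_identity=90.0, seed=13)
        prot, truth = simulate_proteomes(spec)
        pairs = {}
        for i, x in enumerate("ABCD"):
            for y in "ABCD"[i + 1:]:
                pairs[(x, y)] = call_orthologs(prot[x], prot[y])
        protein_species = {r.id: sp for sp, recs in prot.items() for r in recs}
        groups = build_ortholog_groups(pairs, protein_species)
        regions = venn_partition(groups, {sp: [r.id for r in rs] for sp, rs in prot.items()})
        assert regions[frozenset("ABCD")]["n_groups"] == len(truth.ortholog_groups) == 12


class TestSyntons:
    @staticmethod
    def pairs_from(mapping):
        return [OrthologPair(a, b, 90.0, 1.0, 50.0) for a, b in mapping]

    def test_collinear_map_single_synton(self):
        mapping = [(f"a{i}", f"b{i}") for i in range(10)]
        order_a = {f"a{i}": i for i in range(10)}
        order_b = {f"b{i}": i for i in range(10)}
        syntons = find_syntons(self.pairs_from(mapping), order_a, order_b)
        assert len(syntons) == 1
        assert syntons[0].size == 10 and syntons[0].orientation == "same"

    def test_reversed_order_inverted_synton(self):
        mapping = [(f"a{i}", f"b{i}") for i in range(10)]
        order_a = {f"a{i}": i for i in range(10)}
        order_b = {f"b{i}": 9 - i for i in range(10)}
        syntons = find_syntons(self.pairs_from(mapping), order_a, order_b)
        assert len(syntons) == 1
        assert syntons[0].size == 10 and syntons[0].orientation == "inverted"

    def test_short_runs_discarded(self):
        mapping = [("a0", "b0"), ("a1", "b1")]
        syntons = find_syntons(
            self.pairs_from(mapping), {"a0": 0, "a1": 1}, {"b0": 0, "b1": 1},
            min_synton_size=3,
        )
        assert syntons == []

    def test_transposed_gene_with_gap_tolerance(self):
        """One displaced gene inside a collinear run, max_gap=1: the run
        survives as a single block (the transposed pair is skipped), which
        matches exhaustive enumeration of maximal co-monotone runs."""
        order_a = {f"a{i}": i for i in range(8)}
        order_b = {f"b{i}": i for i in range(8)}
        mapping = [(f"a{i}", f"b{i}") for i in range(8)]
        # transpose gene 4 on B far away
        order_b["b4"] = 100
        syntons = find_syntons(self.pairs_from(mapping), order_a, order_b,
                               min_synton_size=3, max_gap=1)
        assert len(syntons) == 1
        assert [p[0] for p in syntons[0].blocks] == ["a0", "a1", "a2", "a3", "a5", "a6", "a7"]

    def test_blocks_match_exhaustive_enumeration(self):
        """Greedy blocks equal the longest co-monotone runs by brute force."""
        from itertools import combinations

        order_a = {f"a{i}": i for i in range(8)}
        perm = [0, 1, 2, 5, 4, 3, 6, 7]
        order_b = {f"b{i}": perm[i] for i in range(8)}
        mapping = [(f"a{i}", f"b{i}") for i in range(8)]

        def comonotone(run):  # run = list of (ia, ib)
            for gap in (1,):
                ok_same = all(
                    0 < run[k + 1][0] - run[k][0] <= gap + 1
                    and 0 < run[k + 1][1] - run[k][1] <= gap + 1
                    for k in range(len(run) - 1)
                )
                ok_inv = all(
                    0 < run[k + 1][0] - run[k][0] <= gap + 1
                    and 0 < run[k][1] - run[k + 1][1] <= gap + 1
                    for k in range(len(run) - 1)
                )
            return ok_same or ok_inv

        anchors = sorted((order_a[a], order_b[b]) for a, b in mapping)
        best = 0
        for r in range(3, 9):
            for combo in combinations(anchors, r):
                if comonotone(list(combo)):
                    best = max(best, r)
        syntons = find_syntons(self.pairs_from(mapping), order_a, order_b,
                               min_synton_size=3, max_gap=1)
        assert max(s.size for s in syntons) == best
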