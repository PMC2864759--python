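"""Protein alignment, reciprocal-best-hit orthology, and synteny blocks.

Orthologs between two species are called by three criteria that together
form the operative filter: (i) percent identity of at least 35 over the
aligned columns, (ii) the two proteins are each other's best-scoring hit
(reciprocal best hit, RBH), and (iii) the alignment covers at least 80% of
the smaller protein. Local alignment is Smith-Waterman with affine gaps
(BLOSUM62, gap open 11, extend 1). The all-vs-all search uses a k-mer
prefilter (shared-word screen) before full alignment; disabling the
prefilter gives the exhaustive reference behaviour.

Cross-species ortholog groups are connected components of the RBH graph,
and syntons are maximal co-monotone runs of ortholog pairs along two
replicons' gene orders.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import ProteinRecord

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_IDENTITY = 35.0  # percent, over aligned columns
DEFAULT_MIN_COVERAGE = 0.8  # fraction of the smaller protein
DEFAULT_KMER = 4
DEFAULT_MIN_SHARED_KMERS = 2


@dataclass
class Alignment:
    """A local alignment with the statistics the ortholog criteria need."""

    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    aligned_span_query: tuple[int, int]
    aligned_span_subject: tuple[int, int]
    coverage_smaller: float
    aligned_columns: int


@dataclass
class OrthologPair:
    """A reciprocal best hit passing the identity and coverage criteria."""

    protein_a: str
    protein_b: str
    identity_pct: float
    coverage_smaller: float
    score: float


@dataclass
class Synton:
    """A conserved gene-order block: a co-monotone run of ortholog pairs."""

    blocks: list[tuple[str, str]]
    orientation: str  # "same" or "inverted"

    @property
    def size(self) -> int:
        return len(self.blocks)


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    try:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def local_align(
    a: ProteinRecord | tuple[str, str],
    b: ProteinRecord | tuple[str, str],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment | None:
    """Optimal affine-gap local alignment of two proteins.

    Returns None when no positive-scoring local alignment exists. Identity
    is 100 * identical columns / aligned columns (gap columns excluded from
    the identical count but kept in the denominator of coverage); coverage
    is aligned columns on the shorter protein over its length.
    """
    id_a, seq_a = (a.id, a.seq) if isinstance(a, ProteinRecord) else a
    id_b, seq_b = (b.id, b.seq) if isinstance(b, ProteinRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("empty protein sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return None
    aln = aligner.align(seq_a, seq_b)[0]  # deterministic first optimal traceback
    return _alignment_stats(id_a, seq_a, id_b, seq_b, aln)


def _alignment_stats(id_a, seq_a, id_b, seq_b, aln) -> Alignment:
    qa, qb = aln[0], aln[1]  # gapped strings of the local region
    identical = sum(1 for x, y in zip(qa, qb) if x == y and x != "-")
    columns = len(qa)
    q_blocks, s_blocks = aln.aligned
    span_q = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    span_s = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    shorter = min(len(seq_a), len(seq_b))
    aligned_on_shorter = (
        span_q[1] - span_q[0] if len(seq_a) <= len(seq_b) else span_s[1] - span_s[0]
    )
    return Alignment(
        query_id=id_a,
        subject_id=id_b,
        score=float(aln.score),
        identity_pct=100.0 * identical / columns if columns else 0.0,
        aligned_span_query=span_q,
        aligned_span_subject=span_s,
        coverage_smaller=aligned_on_shorter / shorter,
        aligned_columns=columns,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(
    query_set: list[ProteinRecord],
    subject_set: list[ProteinRecord],
    prefilter_kmer: int = DEFAULT_KMER,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    exclude_self: bool = False,
) -> dict[str, Alignment]:
    """Best subject hit per query by Smith-Waterman score.

    Candidates are screened by shared k-mers (``min_shared_kmers=0``
    disables the screen and reproduces the exhaustive search). Score ties
    break toward the lexicographically smaller subject id. Queries with no
    positive-scoring candidate are absent from the result.
    """
    if not query_set or not subject_set:
        raise ValueError("empty proteome")
    aligner = _aligner(matrix, gap_open, gap_extend)

    index: dict[str, set[str]] | None = None
    if min_shared_kmers > 0:
        index = defaultdict(set)
        for rec in subject_set:
            for kmer in _kmer_set(rec.seq, prefilter_kmer):
                index[kmer].add(rec.id)
    subjects = {rec.id: rec for rec in subject_set}

    best: dict[str, Alignment] = {}
    for q in query_set:
        if index is not None:
            shared: dict[str, int] = defaultdict(int)
            for kmer in _kmer_set(q.seq, prefilter_kmer):
                for sid in index.get(kmer, ()):
                    shared[sid] += 1
            candidates = sorted(s for s, n in shared.items() if n >= min_shared_kmers)
        else:
            candidates = sorted(subjects)
        best_score, best_id = 0.0, None
        for sid in candidates:
            if exclude_self and sid == q.id:
                continue
            score = aligner.score(q.seq, subjects[sid].seq)
            if score > best_score:  # candidates sorted: ties keep smaller id
                best_score, best_id = score, sid
        if best_id is not None:
            aln = aligner.align(q.seq, subjects[best_id].seq)[0]
            best[q.id] = _alignment_stats(q.id, q.seq, best_id, subjects[best_id].seq, aln)
    return best


def call_orthologs(
    proteome_a: list[ProteinRecord],
    proteome_b: list[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    prefilter_kmer: int = DEFAULT_KMER,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
    **align_kwargs,
) -> list[OrthologPair]:
    """Reciprocal-best-hit orthologs between two species' proteomes.

    A pair (a, b) is reported iff best(a -> B) = b, best(b -> A) = a,
    identity >= *min_identity* percent, and the alignment spans at least
    *min_coverage* of the smaller protein. Output is sorted by protein_a
    and symmetric in the argument order.
    """
    species_a = {r.species for r in proteome_a}
    species_b = {r.species for r in proteome_b}
    if species_a & species_b:
        raise ValueError("proteomes must come from disjoint species")
    fwd = all_vs_all(proteome_a, proteome_b, prefilter_kmer, min_shared_kmers, **align_kwargs)
    rev = all_vs_all(proteome_b, proteome_a, prefilter_kmer, min_shared_kmers, **align_kwargs)
    pairs = []
    for a_id, aln in fwd.items():
        b_id = aln.subject_id
        back = rev.get(b_id)
        if back is None or back.subject_id != a_id:
            continue
        if aln.identity_pct < min_identity or aln.coverage_smaller < min_coverage:
            continue
        pairs.append(
            OrthologPair(a_id, b_id, aln.identity_pct, aln.coverage_smaller, aln.score)
        )
    pairs.sort(key=lambda p: p.protein_a)
    return pairs


def build_ortholog_groups(
    pairs_by_species_pair: dict[tuple[str, str], list[OrthologPair]],
    protein_species: dict[str, str],
) -> list[dict]:
    """Connected components of the RBH graph across all species pairs.

    Each group carries its member protein ids and the set of species they
    come from.
    """
    graph = nx.Graph()
    for pair_list in pairs_by_species_pair.values():
        for p in pair_list:
            graph.add_edge(p.protein_a, p.protein_b)
    groups = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        groups.append(
            {
                "members": members,
                "species": frozenset(protein_species[m] for m in members),
            }
        )
    groups.sort(key=lambda g: g["members"][0])
    return groups


def venn_partition(
    groups: list[dict],
    species_proteins: dict[str, list[str]],
) -> dict[frozenset, dict]:
    """Counts per non-empty species subset (the Venn regions).

    Multi-species regions count the ortholog groups whose species set
    equals the subset (``n_groups``) as well as the proteins they contain
    (``n_proteins``); singleton regions count the proteins of that species
    that belong to no multi-species group.
    """
    species_list = sorted(species_proteins)
    if not 2 <= len(species_list) <= 4:
        raise ValueError("venn partition defined for 2-4 species")
    regions: dict[frozenset, dict] = {}
    for r in range(1, len(species_list) + 1):
        for subset in combinations(species_list, r):
            regions[frozenset(subset)] = {"n_groups": 0, "n_proteins": 0}
    grouped_proteins: set[str] = set()
    for g in groups:
        if len(g["species"]) < 2:
            continue
        key = frozenset(g["species"])
        regions[key]["n_groups"] += 1
        regions[key]["n_proteins"] += len(g["members"])
        grouped_proteins.update(g["members"])
    for sp, prots in species_proteins.items():
        private = [p for p in prots if p not in grouped_proteins]
        key = frozenset([sp])
        regions[key]["n_groups"] = len(private)
        regions[key]["n_proteins"] = len(private)
    return regions


def find_syntons(
    pairs: list[OrthologPair],
    order_a: dict[str, int],
    order_b: dict[str, int],
    min_synton_size: int = 3,
    max_gap: int = 1,
) -> list[Synton]:
    """Maximal co-monotone runs of ortholog pairs along two gene orders.

    Pairs are walked in order of their position on replicon A; a run
    extends while the partner position on B moves strictly in one
    direction (same or inverted orientation) and the index jump on either
    replicon leaves at most *max_gap* unmatched genes. Runs shorter than
    *min_synton_size* are discarded.
    """
    anchored = sorted(
        ((order_a[p.protein_a], order_b[p.protein_b], p) for p in pairs
         if p.protein_a in order_a and p.protein_b in order_b)
    )
    syntons: list[Synton] = []
    i = 0
    n = len(anchored)
    while i < n:
        best_run = [anchored[i]]
        best_dir = 0
        for direction in (1, -1):
            run = [anchored[i]]
            j = i
            while j + 1 < n:
                ia, ib, _ = run[-1]
                na, nb, np_ = anchored[j + 1]
                gap_a = na - ia - 1
                gap_b = direction * (nb - ib) - 1
                if gap_a <= max_gap and 0 <= gap_b <= max_gap:
                    run.append(anchored[j + 1])
                    j += 1
                elif na - ia - 1 > max_gap:
                    break
                else:
                    j += 1  # pair breaks monotonicity: treat as gap and look on
                    if na - run[-1][0] - 1 > max_gap:
                        break
            if len(run) > len(best_run):
                best_run, best_dir = run, direction
        if len(best_run) >= min_synton_size:
            syntons.append(
                Synton(
                    blocks=[(p.protein_a, p.protein_b) for _, _, p in best_run],
                    orientation="same" if best_dir >= 0 else "inverted",
                )
            )
            i += len(best_run)
        else:
            i += 1
    return syntons
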