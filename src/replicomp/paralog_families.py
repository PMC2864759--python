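"""Within-proteome paralog family construction.

The procedure mirrors the classic similarity-matrix family builders: mask
low-complexity segments, run an all-vs-all similarity search to build a
directed hit graph, re-check asymmetric edges with a fresh full
Smith-Waterman alignment, drop putative multi-domain proteins (whose
neighbours align to disjoint, mutually unrelated regions and would
otherwise glue unrelated families together), and take the connected
components of the symmetrified graph as families. Proteins in no family
are singletons. Because no alignment E-value statistics are computed, the
edge threshold is an identity/coverage criterion (defaults: identity >= 30
percent over >= 50 percent of the smaller protein), a deliberate proxy for
an E-value cutoff.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx

from .alignment_orthology import (
    Alignment,
    all_vs_all,
    local_align,
)
from .sequence_io import ProteinRecord

DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_ENTROPY_WINDOW = 12
DEFAULT_ENTROPY_THRESHOLD = 2.2  # bits; uniform windows of 12 residues carry ~3.4
MULTIDOMAIN_OVERLAP_FRACTION = 0.2


@dataclass
class SimilarityGraph:
    """Directed above-threshold hit graph from the all-vs-all search."""

    graph: nx.DiGraph
    min_identity: float
    min_coverage: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class ParalogFamily:
    members: frozenset

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if len(self.members) < 2:
            raise ValueError("a family has at least two members")

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class FamilyStats:
    n_with_paralog: int
    n_singletons: int
    n_multidomain_excluded: int
    pct_with_paralog: int
    pct_singletons: int
    n_in_large_clusters: int
    n_large_clusters: int
    pct_in_large_clusters: int
    denominator: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def shannon_entropy(window: str) -> float:
    """Residue Shannon entropy of a window, in bits."""
    counts = Counter(window)
    n = len(window)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def mask_low_complexity(
    seq: str,
    window: int = DEFAULT_ENTROPY_WINDOW,
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD,
) -> str:
    """Replace low-entropy windows by X runs (sliding-window Shannon mask).

    Windows already containing X are not evaluated, so the mask is a
    fixpoint: ``mask(mask(s)) == mask(s)``. Sequences shorter than the
    window are returned unchanged.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(seq) < window:
        return seq
    to_mask = [False] * len(seq)
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        if "X" in w:
            continue
        if shannon_entropy(w) < entropy_threshold:
            for j in range(i, i + window):
                to_mask[j] = True
    return "".join("X" if m else c for c, m in zip(seq, to_mask))


def build_similarity_graph(
    proteome: list[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    mask: bool = True,
    prefilter_kmer: int = 4,
    min_shared_kmers: int = 2,
    **align_kwargs,
) -> SimilarityGraph:
    """All-vs-all above-threshold hit graph within one proteome.

    Every query is aligned against all candidate subjects (not just the
    best hit); a directed edge u -> v records that v scored above the
    identity/coverage threshold against u. Self-hits are excluded.
    """
    records = proteome
    if mask:
        records = [
            ProteinRecord(r.id, r.species, r.replicon, r.order_index,
                          mask_low_complexity(r.seq))
            for r in proteome
        ]
    g = nx.DiGraph()
    g.add_nodes_from(r.id for r in records)
    by_id = {r.id: r for r in records}

    # candidate generation identical to all_vs_all's k-mer screen
    from .alignment_orthology import _kmer_set

    index: dict[str, set[str]] = defaultdict(set)
    if min_shared_kmers > 0:
        for rec in records:
            for kmer in _kmer_set(rec.seq, prefilter_kmer):
                index[kmer].add(rec.id)
    for q in records:
        if min_shared_kmers > 0:
            shared: dict[str, int] = defaultdict(int)
            for kmer in _kmer_set(q.seq, prefilter_kmer):
                for sid in index.get(kmer, ()):
                    shared[sid] += 1
            candidates = sorted(s for s, c in shared.items() if c >= min_shared_kmers)
        else:
            candidates = sorted(by_id)
        for sid in candidates:
            if sid == q.id:
                continue
            aln = local_align(q, by_id[sid], **align_kwargs)
            if aln is None:
                continue
            if aln.identity_pct >= min_identity and aln.coverage_smaller >= min_coverage:
                g.add_edge(q.id, sid, alignment=aln)
    return SimilarityGraph(g, min_identity, min_coverage)


def flag_multidomain(
    protein_id: str, sim: SimilarityGraph, proteome_by_id: dict[str, ProteinRecord]
) -> bool:
    """True iff the protein looks like a fusion of unrelated domains.

    Two neighbours vote for a fusion when their aligned spans on this
    protein overlap by less than 20 percent of the shorter span and the
    neighbours themselves share no edge. Proteins with fewer than two
    neighbours are never flagged.
    """
    g = sim.graph
    neighbours = sorted(set(g.successors(protein_id)) | set(g.predecessors(protein_id)))
    if len(neighbours) < 2:
        return False
    spans = {}
    for nb in neighbours:
        if g.has_edge(protein_id, nb):
            aln: Alignment = g.edges[protein_id, nb]["alignment"]
            spans[nb] = aln.aligned_span_query
        elif g.has_edge(nb, protein_id):
            aln = g.edges[nb, protein_id]["alignment"]
            spans[nb] = aln.aligned_span_subject
    for i, a in enumerate(neighbours):
        for b in neighbours[i + 1 :]:
            if a not in spans or b not in spans:
                continue
            s1, e1 = spans[a]
            s2, e2 = spans[b]
            overlap = max(0, min(e1, e2) - max(s1, s2))
            shorter = min(e1 - s1, e2 - s2)
            if shorter <= 0:
                continue
            connected = g.has_edge(a, b) or g.has_edge(b, a)
            if overlap < MULTIDOMAIN_OVERLAP_FRACTION * shorter and not connected:
                return True
    return False


def symmetrify_and_close(
    sim: SimilarityGraph,
    proteome: list[ProteinRecord],
    exclude_multidomain: bool = True,
    **align_kwargs,
) -> tuple[list[ParalogFamily], list[str], list[str]]:
    """Symmetry check, multi-domain exclusion, and transitive closure.

    Asymmetric edges (u -> v without v -> u) are re-checked by a fresh full
    Smith-Waterman alignment (no prefilter) and kept only if they pass the
    graph's threshold. Families are the connected components (size >= 2) of
    the symmetrified undirected graph after removing flagged multi-domain
    proteins. Returns (families, singletons, excluded), each sorted.
    """
    by_id = {r.id: r for r in proteome}
    g = sim.graph.copy()
    for u, v in list(g.edges):
        if g.has_edge(v, u):
            continue
        aln = local_align(by_id[u], by_id[v], **align_kwargs)
        ok = (
            aln is not None
            and aln.identity_pct >= sim.min_identity
            and aln.coverage_smaller >= sim.min_coverage
        )
        if ok:
            g.add_edge(v, u, alignment=aln)
        else:
            g.remove_edge(u, v)

    checked = SimilarityGraph(g, sim.min_identity, sim.min_coverage)
    excluded: list[str] = []
    if exclude_multidomain:
        excluded = sorted(
            p for p in g.nodes if flag_multidomain(p, checked, by_id)
        )
        g.remove_nodes_from(excluded)

    undirected = g.to_undirected()
    families = []
    singles = []
    for comp in nx.connected_components(undirected):
        if len(comp) >= 2:
            families.append(ParalogFamily(frozenset(comp)))
        else:
            singles.extend(comp)
    families.sort(key=lambda f: sorted(f.members)[0])
    return families, sorted(singles), excluded


def find_paralog_families(
    proteome: list[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    **kwargs,
) -> tuple[list[ParalogFamily], list[str], list[str]]:
    """Convenience wrapper: graph build + symmetrify + closure."""
    sim = build_similarity_graph(proteome, min_identity, min_coverage, **kwargs)
    return symmetrify_and_close(sim, proteome)


def family_stats(
    families: list[ParalogFamily],
    singletons: list[str],
    excluded: list[str],
    large_threshold: int = 10,
) -> FamilyStats:
    """Counts and round-half-up percentages over the analysed proteins.

    The percentage denominator is the number of analysed (non-excluded)
    proteins: family members plus singletons.
    """
    members = [m for f in families for m in f.members]
    all_ids = members + list(singletons) + list(excluded)
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("families/singletons/excluded overlap")
    n_with = len(members)
    n_single = len(singletons)
    denom = n_with + n_single
    large = [f for f in families if f.n >= large_threshold]
    n_in_large = sum(f.n for f in large)
    return FamilyStats(
        n_with_paralog=n_with,
        n_singletons=n_single,
        n_multidomain_excluded=len(excluded),
        pct_with_paralog=_round_half_up(100.0 * n_with / denom) if denom else 0,
        pct_singletons=_round_half_up(100.0 * n_single / denom) if denom else 0,
        n_in_large_clusters=n_in_large,
        n_large_clusters=len(large),
        pct_in_large_clusters=_round_half_up(100.0 * n_in_large / denom) if denom else 0,
        denominator=denom,
    )
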