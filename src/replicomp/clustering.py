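"""Replicon and protein distance matrices with single-linkage trees.

Two distances are in play. Replicons are compared through their shared
ortholog count, normalised by the protein count of the smaller replicon:
d = 1 - n_orthologs / min(size_a, size_b), in [0, 1]. Individual proteins
(for example the RpoD sigma-factor survey) are compared by pairwise local
alignment: d = 100 - percent identity (a flag switches to BLOSUM-positive
percent similarity), in [0, 100]. Both feed a deterministic single-linkage
agglomeration exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_orthology import call_orthologs, local_align
from .sequence_io import ProteinRecord


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.values < 0):
            raise ValueError("negative distance")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class Merge:
    """One agglomeration step: the two cluster labels joined and the height."""

    left: str
    right: str
    height: float


@dataclass
class Dendrogram:
    """Single-linkage merge tree; heights are non-decreasing leaf-to-root."""

    leaves: list[str]
    merges: list[Merge]
    newick: str = field(init=False)

    def __post_init__(self) -> None:
        self.newick = _to_newick(self.leaves, self.merges)

    @property
    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


def replicon_distance(n_orthologs: int, size_a: int, size_b: int) -> float:
    """d = 1 - n_orthologs / min(size_a, size_b) (protein counts)."""
    if size_a <= 0 or size_b <= 0:
        raise ValueError("replicon sizes must be positive")
    smallest = min(size_a, size_b)
    if n_orthologs > smallest:
        raise ValueError(
            f"{n_orthologs} orthologs exceed the smaller proteome ({smallest})"
        )
    return 1.0 - n_orthologs / smallest


def build_distance_matrix(
    proteomes: dict[str, list[ProteinRecord]], **ortholog_kwargs
) -> DistanceMatrix:
    """Pairwise RBH ortholog counts turned into replicon distances."""
    labels = sorted(proteomes)
    if len(labels) < 2:
        raise ValueError("need at least two proteomes")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = call_orthologs(proteomes[labels[i]], proteomes[labels[j]], **ortholog_kwargs)
            d = replicon_distance(
                len(pairs), len(proteomes[labels[i]]), len(proteomes[labels[j]])
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def protein_similarity_distance(
    records: list[ProteinRecord], measure: str = "identity", **align_kwargs
) -> DistanceMatrix:
    """d = 100 - percent identity (or percent BLOSUM-positive similarity).

    The percentage is taken over the length of the shorter protein, not
    over the aligned columns: this is a whole-protein distance, so a short
    spurious local hit between unrelated proteins must not look similar.
    Argument order is canonicalised (sorted ids) so the matrix is symmetric
    by construction; unalignable pairs get the maximal distance 100.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    if measure not in ("identity", "similarity"):
        raise ValueError(f"unknown measure {measure!r}")
    ordered = sorted(records, key=lambda r: r.id)
    labels = [r.id for r in ordered]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(ordered[i], ordered[j], **align_kwargs)
            shorter = min(len(ordered[i].seq), len(ordered[j].seq))
            if aln is None:
                pct = 0.0
            elif measure == "identity":
                identical = aln.identity_pct * aln.aligned_columns / 100.0
                pct = 100.0 * identical / shorter
            else:
                positives = _positive_count(ordered[i].seq, ordered[j].seq, aln,
                                            **align_kwargs)
                pct = 100.0 * positives / shorter
            values[i, j] = values[j, i] = max(0.0, 100.0 - pct)
    return DistanceMatrix(labels, values)


def _positive_count(seq_a, seq_b, aln, matrix: str = "BLOSUM62", **_):
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(matrix)
    qa = seq_a[aln.aligned_span_query[0] : aln.aligned_span_query[1]]
    qb = seq_b[aln.aligned_span_subject[0] : aln.aligned_span_subject[1]]
    # positive-scoring columns of the (gap-free portions of the) alignment
    return sum(1 for x, y in zip(qa, qb) if mat[x][y] > 0)


def single_linkage(matrix: DistanceMatrix) -> Dendrogram:
    """Single-linkage agglomeration with deterministic tie-breaking.

    At each step the minimum inter-cluster distance is merged; equal
    distances break toward the lexicographically smallest (left, right)
    label pair, where a cluster is labelled by its smallest leaf.
    """
    labels = list(matrix.labels)
    d = {
        frozenset((a, b)): matrix.values[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    clusters: dict[str, list[str]] = {l: [l] for l in labels}
    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = min(d[frozenset((x, y))] for x in clusters[a] for y in clusters[b])
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        merges.append(Merge(a, b, dist))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return Dendrogram(labels, merges)


def _to_newick(leaves: list[str], merges: list[Merge]) -> str:
    """Newick with ultrametric branch lengths from merge heights."""
    node: dict[str, str] = {l: l for l in leaves}
    height: dict[str, float] = {l: 0.0 for l in leaves}
    # a cluster merged at height h sits h/2 above the leaves (ultrametric:
    # cophenetic distance between leaves of sibling clusters equals h)
    for m in merges:
        bl_left = (m.height - height[m.left]) / 2.0
        bl_right = (m.height - height[m.right]) / 2.0
        node[m.left] = f"({node[m.left]}:{bl_left:.9g},{node[m.right]}:{bl_right:.9g})"
        height[m.left] = m.height
        del node[m.right]
    (root,) = node.values()
    return root + ";"
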