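"""Degenerate consensus motif scanning on circular DNA.

A motif is an ordered list of allowed-nucleotide sets, parsed from plain
bases, parenthesized alternation ``(A/T)`` or IUPAC one-letter codes. The
scanner counts, at each start position and on each strand, how many motif
positions are violated, and reports windows within a mismatch budget.
Mismatch counting convention: a base that is any member of a degenerate
position costs 0; an N in the subject never matches (costs 1). Hits are
clustered into box regions by single-linkage on start-position gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import Replicon

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

#: DnaA-binding box consensus of beta-proteobacteria
DNAA_BOX = "TTATCCACA"
#: 17-nt repeat consensus of plasmid-type RepA binding sites
REPA_REPEAT = "CGCAGAA(A/T)(C/T)(A/G)GGTACG(C/T)"


@dataclass
class Motif:
    """A degenerate consensus: one allowed-base set per position."""

    name: str
    positions: list[frozenset]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.positions):
            s = frozenset(s)
            if not s or not s <= set("ACGT"):
                raise ValueError(f"motif {self.name!r}: bad position {i}: {sorted(s)}")
            self.positions[i] = s

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def n_expansions(self) -> int:
        """Number of concrete words matching the consensus exactly."""
        n = 1
        for s in self.positions:
            n *= len(s)
        return n

    def reverse_complement(self) -> "Motif":
        rc = [frozenset(_COMPLEMENT[b] for b in s) for s in reversed(self.positions)]
        return Motif(self.name, rc)


@dataclass
class MotifHit:
    """A scan hit in forward-strand coordinates (0-based start)."""

    start: int
    strand: str
    mismatches: int
    motif_name: str
    length: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class BoxCluster:
    """A run of motif hits whose consecutive start gaps stay within max_gap."""

    hits: list[MotifHit]
    span_start: int
    span_end: int
    n_perfect: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_perfect = sum(1 for h in self.hits if h.mismatches == 0)

    @property
    def midpoint(self) -> int:
        return (self.span_start + self.span_end) // 2

    @property
    def size(self) -> int:
        return len(self.hits)


def parse_consensus(text: str, name: str = "motif") -> Motif:
    """Parse a consensus string with IUPAC codes and ``(X/Y/...)`` alternation.

    ``"TTATCCACA"`` gives nine singleton positions (one expansion);
    ``"CGCAGAA(A/T)(C/T)(A/G)GGTACG(C/T)"`` gives 17 positions and
    2**4 = 16 expansions.
    """
    positions: list[frozenset] = []
    i = 0
    text = text.strip().upper()
    while i < len(text):
        ch = text[i]
        if ch == "(":
            end = text.find(")", i)
            if end == -1:
                raise ValueError(f"unbalanced parenthesis at offset {i} in {text!r}")
            alts = text[i + 1 : end].split("/")
            allowed: set[str] = set()
            for alt in alts:
                if alt not in IUPAC:
                    raise ValueError(f"illegal alternative {alt!r} in {text!r}")
                allowed |= set(IUPAC[alt])
            positions.append(frozenset(allowed))
            i = end + 1
        elif ch == ")":
            raise ValueError(f"unbalanced parenthesis at offset {i} in {text!r}")
        elif ch in IUPAC:
            positions.append(frozenset(IUPAC[ch]))
            i += 1
        else:
            raise ValueError(f"illegal character {ch!r} at offset {i} in {text!r}")
    if not positions:
        raise ValueError("empty consensus")
    return Motif(name, positions)


def _mismatch_counts(encoded: np.ndarray, motif: Motif, n_starts: int) -> np.ndarray:
    """Mismatch count at each of the first *n_starts* start positions."""
    m = motif.length
    counts = np.zeros(n_starts, dtype=np.int32)
    for j, allowed in enumerate(motif.positions):
        # lookup[b] == False for N (index 4): subject N never matches
        lookup = np.zeros(5, dtype=bool)
        for b in allowed:
            lookup[_BASE_INDEX[b]] = True
        counts += ~lookup[encoded[j : j + n_starts]]
    return counts


def scan(
    rep: Replicon,
    motif: Motif,
    max_mismatches: int = 0,
    strands: str = "both",
    circular: bool | None = None,
) -> list[MotifHit]:
    """Scan a replicon for a degenerate motif within a mismatch budget.

    Minus-strand hits are matches of the reverse-complemented motif,
    reported at their forward-strand start coordinate. Circular scans wrap
    across the origin. Output is sorted by (start, strand).
    """
    if motif.length > rep.length:
        raise ValueError("motif longer than replicon")
    if max_mismatches >= motif.length:
        raise ValueError(
            f"mismatch budget {max_mismatches} >= motif length {motif.length}: "
            "degenerate query"
        )
    if strands not in ("+", "-", "both"):
        raise ValueError(f"bad strands {strands!r}")
    if circular is None:
        circular = rep.circular

    m = motif.length
    seq = rep.seq + (rep.seq[: m - 1] if circular and m > 1 else "")
    encoded = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    encoded = lut[encoded]
    n_starts = rep.length if circular else rep.length - m + 1

    hits: list[MotifHit] = []
    strand_motifs = []
    if strands in ("+", "both"):
        strand_motifs.append(("+", motif))
    if strands in ("-", "both"):
        strand_motifs.append(("-", motif.reverse_complement()))
    for strand, mo in strand_motifs:
        counts = _mismatch_counts(encoded, mo, n_starts)
        for start in np.nonzero(counts <= max_mismatches)[0]:
            hits.append(MotifHit(int(start), strand, int(counts[start]), motif.name, m))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def cluster_hits(
    hits: list[MotifHit], max_gap: int, replicon_length: int | None = None
) -> list[BoxCluster]:
    """Single-linkage 1-D clustering of hits by start-position gap.

    Consecutive hits whose start gap is <= max_gap join one cluster. If
    *replicon_length* is given, the first and last clusters merge when they
    are within max_gap across the circular origin.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.start, h.strand))
    groups: list[list[MotifHit]] = [[ordered[0]]]
    for h in ordered[1:]:
        if h.start - groups[-1][-1].start <= max_gap:
            groups[-1].append(h)
        else:
            groups.append([h])
    if (
        replicon_length is not None
        and len(groups) > 1
        and (groups[0][0].start + replicon_length - groups[-1][-1].start) <= max_gap
    ):
        groups[0] = groups.pop() + groups[0]
    clusters = [
        BoxCluster(g, g[0].start, max(h.start + h.length for h in g)) for g in groups
    ]
    clusters.sort(key=lambda c: c.span_start)
    return clusters
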