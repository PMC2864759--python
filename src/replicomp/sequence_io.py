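"""Readers and writers for the formats the pipeline touches.

FASTA (via Biopython), the annotation TSV dialect, BED6 for motif hits and
Newick text. All coordinates are 0-based half-open internally and in BED;
1-based coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: the 25 one-letter COG functional class codes
COG_CLASSES = set("JAKLBDYVTMNZWUOCGEFHIPQRS") | {"X"}

ANNOTATION_CATEGORIES = {
    "assigned",
    "conserved_hypothetical",
    "hypothetical",
    # CDS carried in none of the three narrative classes (e.g. doubtful or
    # partial genes); finished-genome tables routinely leave such a remainder
    "unclassified",
}
FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "IS_element", "transposon", "other"}
ANNOTATION_COLUMNS = [
    "gene_id",
    "replicon",
    "category",
    "cog_classes",
    "feature_type",
    "element_name",
]


class SequenceFormatError(ValueError):
    """Raised on malformed or invalid sequence/table input."""


@dataclass
class Replicon:
    """A circular (by default) DNA molecule: chromosome or plasmid."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceFormatError(f"replicon {self.id!r}: empty sequence")
        bad = set(self.seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"replicon {self.id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A protein with its source species/replicon and gene-order index."""

    id: str
    species: str
    replicon: str
    order_index: int
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceFormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"protein {self.id!r}: illegal characters {sorted(bad)}"
            )
        if self.order_index < 0:
            raise SequenceFormatError(f"protein {self.id!r}: negative order_index")


@dataclass
class AnnotationRow:
    """One annotated gene/feature, the single annotation dialect of the core."""

    gene_id: str
    replicon: str
    category: str
    cog_classes: frozenset = field(default_factory=frozenset)
    feature_type: str = "CDS"
    element_name: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ANNOTATION_CATEGORIES:
            raise SequenceFormatError(
                f"gene {self.gene_id!r}: unknown category {self.category!r}"
            )
        if self.feature_type not in FEATURE_TYPES:
            raise SequenceFormatError(
                f"gene {self.gene_id!r}: unknown feature_type {self.feature_type!r}"
            )
        self.cog_classes = frozenset(self.cog_classes)
        bad = self.cog_classes - COG_CLASSES
        if bad:
            raise SequenceFormatError(
                f"gene {self.gene_id!r}: unknown COG classes {sorted(bad)}"
            )


def _validate_seq(rec_id: str, seq: str, allowed: set, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceFormatError(f"record {rec_id!r}: empty sequence")
    for off, ch in enumerate(seq):
        if ch not in allowed:
            raise SequenceFormatError(
                f"record {rec_id!r}: illegal {what} character {ch!r} at offset {off}"
            )
    return seq


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[tuple[str, str]]:
    """Read a FASTA file, validating every record against *alphabet*.

    Parameters
    ----------
    path:
        FASTA file (plain text).
    alphabet:
        ``"nucleotide"`` (A/C/G/T/N, U rejected: DNA-only scope) or
        ``"protein"`` (20 residues plus X).

    Returns ``(id, seq)`` pairs in file order, sequences uppercased.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, _validate_seq(rec.id, str(rec.seq), allowed, alphabet)))
    if not records:
        raise SequenceFormatError(f"{path}: empty or non-FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write ``(id, seq)`` pairs as FASTA wrapped at *width* columns."""
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_annotation_table(path: str | Path) -> list[AnnotationRow]:
    """Read the annotation TSV (header: gene_id, replicon, category,
    cog_classes, feature_type, element_name).

    ``cog_classes`` is a string of one-letter codes (empty allowed);
    ``element_name`` may be empty. Enum violations report the line number.
    """
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in ANNOTATION_COLUMNS if c not in header]
        if missing:
            raise SequenceFormatError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in ANNOTATION_COLUMNS}
        rows: list[AnnotationRow] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                fields += [""] * (len(header) - len(fields))
            try:
                rows.append(
                    AnnotationRow(
                        gene_id=fields[idx["gene_id"]],
                        replicon=fields[idx["replicon"]],
                        category=fields[idx["category"]],
                        cog_classes=frozenset(fields[idx["cog_classes"]]),
                        feature_type=fields[idx["feature_type"]],
                        element_name=fields[idx["element_name"]] or None,
                    )
                )
            except SequenceFormatError as exc:
                raise SequenceFormatError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_annotation_table(rows: Sequence[AnnotationRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        r.replicon,
                        r.category,
                        "".join(sorted(r.cog_classes)),
                        r.feature_type,
                        r.element_name or "",
                    ]
                )
                + "\n"
            )


def write_bed(hits, replicon_id: str, path: str | Path) -> None:
    """Write motif hits as BED6 (0-based half-open; score = mismatch count).

    *hits* must be sorted by start position.
    """
    starts = [h.start for h in hits]
    if starts != sorted(starts):
        raise ValueError("BED output requires hits sorted by start")
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{replicon_id}\t{h.start}\t{h.start + h.length}\t"
                f"{h.motif_name}\t{h.mismatches}\t{h.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    """Read BED6 back as (chrom, start, end, name, score, strand) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out


def write_newick(newick: str, path: str | Path) -> None:
    """Write a Newick string (terminal semicolon and newline enforced)."""
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")
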