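"""Annotation summary tables, COG distribution ratios, mobile-element tallies.

The summary reproduces the classic "general features" table of a finished
bacterial genome: per-replicon CDS counts split into assigned /
conserved-hypothetical / hypothetical, RNA genes, IS elements and
transposons, with derived percentages. The COG ratio compares how a
functional class is spread over two replicons:

    r = (n2 / N2) / (n1 / N1)

with n the class count and N the replicon's reference CDS count; r = 1
means the class is distributed proportionally, r > 1 enrichment on
replicon 2. By default r is oriented second-replicon-over-first (for a
chromosome-1/chromosome-2 comparison values above 1 flag the smaller,
adaptive replicon) and N counts COG-assigned CDS; both choices are flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .sequence_io import AnnotationRow

CATEGORY_COLUMNS = ["assigned", "conserved_hypothetical", "hypothetical", "unclassified"]


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10**decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass
class GenomeSummary:
    """Per-replicon and total annotation counts with derived percentages."""

    table: pd.DataFrame  # index: replicons + "total"

    @property
    def total_cds(self) -> int:
        return int(self.table.loc["total", "cds"])

    @property
    def total_size_bp(self) -> int:
        return int(self.table.loc["total", "size_bp"])

    @property
    def pct_assigned(self) -> float:
        return float(self.table.loc["total", "pct_assigned"])

    @property
    def pct_hypothetical(self) -> float:
        return float(self.table.loc["total", "pct_hypothetical"])


@dataclass
class CogRatio:
    cog_class: str
    ratio: float
    n_replicon_1: int
    n_replicon_2: int
    infinite: bool = False


def summarize_annotation(
    rows: list[AnnotationRow], replicon_meta: dict[str, dict]
) -> GenomeSummary:
    """Aggregate annotation rows into a general-features table.

    *replicon_meta* maps replicon id to {"size_bp": int, "gc_pct": float}.
    Percentages are round-half-up to one decimal so printed values such as
    9.1 are reproduced exactly from the counts.
    """
    if not rows:
        warnings.warn("empty annotation: all-zero summary")
    for r in rows:
        if r.replicon not in replicon_meta:
            raise ValueError(f"row {r.gene_id!r}: unknown replicon {r.replicon!r}")

    replicons = list(replicon_meta)
    data = []
    for rep in replicons:
        rep_rows = [r for r in rows if r.replicon == rep]
        cds = [r for r in rep_rows if r.feature_type == "CDS"]
        counts = {
            "size_bp": replicon_meta[rep].get("size_bp", 0),
            "gc_pct": replicon_meta[rep].get("gc_pct", float("nan")),
            "cds": len(cds),
            "assigned": sum(1 for r in cds if r.category == "assigned"),
            "conserved_hypothetical": sum(
                1 for r in cds if r.category == "conserved_hypothetical"
            ),
            "hypothetical": sum(1 for r in cds if r.category == "hypothetical"),
            "unclassified": sum(1 for r in cds if r.category == "unclassified"),
            "cog_assigned": sum(1 for r in cds if r.cog_classes),
            "trna": sum(1 for r in rep_rows if r.feature_type == "tRNA"),
            "rrna": sum(1 for r in rep_rows if r.feature_type == "rRNA"),
            "is_elements": sum(1 for r in rep_rows if r.feature_type == "IS_element"),
            "transposons": sum(1 for r in rep_rows if r.feature_type == "transposon"),
        }
        data.append(counts)
    table = pd.DataFrame(data, index=replicons)
    total = table.sum(numeric_only=True)
    total["gc_pct"] = float("nan")
    table.loc["total"] = total

    def pct(col: str) -> pd.Series:
        cds = table["cds"]
        return pd.Series(
            [
                _round_half_up(100.0 * n / c) if c else 0.0
                for n, c in zip(table[col], cds)
            ],
            index=table.index,
        )

    table["pct_assigned"] = pct("assigned")
    table["pct_hypothetical"] = pct("hypothetical")
    for rep in replicons:
        s = sum(int(table.loc[rep, c]) for c in CATEGORY_COLUMNS)
        if s != int(table.loc[rep, "cds"]):
            raise ValueError(
                f"replicon {rep}: categories sum to {s} but CDS count is "
                f"{int(table.loc[rep, 'cds'])}"
            )
    return GenomeSummary(table)


def cog_normalized_ratio(
    rows: list[AnnotationRow],
    replicon_1: str,
    replicon_2: str,
    denominator: str = "cog_assigned",
) -> list[CogRatio]:
    """Normalised per-class CDS ratio r = (n2/N2)/(n1/N1) between replicons.

    *denominator* chooses N: ``"cog_assigned"`` (CDS with at least one COG
    class) or ``"total_cds"``. Classes absent from replicon 1 but present
    on replicon 2 get an infinite, flagged ratio.
    """
    if denominator not in ("cog_assigned", "total_cds"):
        raise ValueError(f"unknown denominator {denominator!r}")

    def class_counts(rep: str):
        cds = [r for r in rows if r.replicon == rep and r.feature_type == "CDS"]
        per_class: dict[str, int] = {}
        for r in cds:
            for c in r.cog_classes:
                per_class[c] = per_class.get(c, 0) + 1
        n_ref = len(cds) if denominator == "total_cds" else sum(
            1 for r in cds if r.cog_classes
        )
        return per_class, n_ref

    c1, n1_ref = class_counts(replicon_1)
    c2, n2_ref = class_counts(replicon_2)
    if n1_ref == 0 or n2_ref == 0:
        raise ValueError("a replicon has no reference CDS for the ratio")
    out = []
    for cls in sorted(set(c1) | set(c2)):
        n1, n2 = c1.get(cls, 0), c2.get(cls, 0)
        if n1 + n2 == 0:
            continue
        if n1 == 0:
            out.append(CogRatio(cls, float("inf"), n1, n2, infinite=True))
        else:
            r = (n2 / n2_ref) / (n1 / n1_ref)
            out.append(CogRatio(cls, round(r, 3), n1, n2))
    return out


def tally_mobile_elements(rows: list[AnnotationRow]) -> pd.DataFrame:
    """Contingency table element_name x replicon with row/column totals."""
    mobile = [r for r in rows if r.feature_type in ("IS_element", "transposon")]
    for r in mobile:
        if not r.element_name:
            raise ValueError(f"mobile element row {r.gene_id!r} lacks element_name")
    if not mobile:
        return pd.DataFrame()
    table = pd.crosstab(
        [r.element_name for r in mobile],
        [r.replicon for r in mobile],
        margins=True,
        margins_name="total",
    )
    table.index.name = "element"
    table.columns.name = "replicon"
    return table
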