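"""Published summary tables for the C. metallidurans CH34 genome.

These are the printed per-replicon counts for the four CH34 replicons
(chromosome 1, chromosome 2, megaplasmids pMOL28 and pMOL30): general
genome features, the transposon census, the IS-element census, and the
published paralogy partition of the proteome. They serve as reference
inputs for the aggregation routines, which recompute the derived totals
and percentages from the raw counts.
"""

from __future__ import annotations

import pandas as pd

from .sequence_io import AnnotationRow

REPLICONS = ["CHR1", "CHR2", "pMOL28", "pMOL30"]

# general features, one row per replicon (columns ordered as REPLICONS)
_TABLE1 = {
    "size_bp": [3_928_089, 2_580_084, 171_459, 233_720],
    "gc_pct": [63.82, 63.60, 60.50, 60.13],
    "trna": [54, 8, 0, 0],
    "rrna_operons": [2, 2, 0, 0],
    "is_elements": [30, 19, 3, 5],
    "transposons": [8, 7, 2, 2],
    "cds": [3766, 2493, 175, 283],
    "assigned": [2784, 1468, 100, 166],
    "conserved_hypothetical": [690, 478, 54, 52],
    "hypothetical": [250, 292, 15, 54],
    "cog_assigned": [3045, 1888, 77, 123],
    "transport": [433, 288, 5, 16],
}

# transposon census: element -> copies per replicon
_TRANSPOSONS = {
    "Tn4378": [0, 0, 1, 0],
    "Tn4380": [0, 0, 0, 1],
    "Tn6048": [1, 2, 0, 0],
    "Tn6049": [7, 3, 1, 1],
    "Tn6050": [0, 2, 0, 0],
}

# IS-element census: element -> copies per replicon
_IS_ELEMENTS = {
    "IS1071": [3, 0, 0, 0],
    "IS1086": [1, 1, 1, 0],
    "IS1087": [2, 0, 0, 0],
    "IS1088": [3, 6, 0, 0],
    "IS1090": [4, 0, 0, 0],
    "ISRme1": [2, 2, 0, 0],
    "ISRme3": [3, 5, 0, 2],
    "ISRme4": [2, 0, 0, 0],
    "ISRme5": [3, 1, 0, 0],
    "ISRme6": [1, 0, 0, 0],
    "ISRme7": [2, 0, 0, 0],
    "ISRme8": [1, 1, 0, 0],
    "ISRme9": [0, 0, 1, 0],
    "ISRme10": [0, 0, 0, 1],
    "ISRme11": [0, 2, 0, 0],
    "ISRme12": [1, 0, 0, 0],
    "ISRme15": [0, 1, 0, 1],
    "ISRme17": [1, 0, 0, 0],
    "ISRme18": [0, 0, 1, 0],
    "ISRme19": [0, 0, 0, 1],
    "ISRme20": [1, 0, 0, 0],
}

# published proteome paralogy census: 43 clusters of >= 10 members hold
# 1,358 proteins (the four largest: 138, 123, 121 and 110 members); 656
# small clusters of 2-6 members hold 1,724 proteins; 3,311 proteins have a
# paralog in total and 3,008 are singletons.
PARALOGY_N_WITH_PARALOG = 3311
PARALOGY_N_SINGLETONS = 3008
PARALOGY_N_LARGE_CLUSTERS = 43
PARALOGY_N_IN_LARGE = 1358
PARALOGY_LARGEST_SIZES = [138, 123, 121, 110]
PARALOGY_N_SMALL_CLUSTERS = 656
PARALOGY_N_IN_SMALL = 1724


def ch34_general_features() -> pd.DataFrame:
    """General genome features, one row per replicon."""
    return pd.DataFrame(_TABLE1, index=REPLICONS)


def ch34_transposons() -> pd.DataFrame:
    return pd.DataFrame(_TRANSPOSONS, index=REPLICONS).T


def ch34_is_elements() -> pd.DataFrame:
    return pd.DataFrame(_IS_ELEMENTS, index=REPLICONS).T


def ch34_replicon_meta() -> dict[str, dict]:
    t = ch34_general_features()
    return {
        rep: {"size_bp": int(t.loc[rep, "size_bp"]), "gc_pct": float(t.loc[rep, "gc_pct"])}
        for rep in REPLICONS
    }


def ch34_annotation_rows() -> list[AnnotationRow]:
    """Expand the published counts into individual annotation rows.

    One row per CDS (with its functional category), tRNA gene, IS element
    and transposon copy. COG membership is represented minimally but
    consistently with the counts: transport genes carry class P, the other
    COG-assigned CDS carry class R, the rest none. Gene ids are synthetic
    placeholders; only the counts are data.
    """
    t = ch34_general_features()
    rows: list[AnnotationRow] = []
    k = 0

    def next_id() -> str:
        nonlocal k
        k += 1
        return f"Rmet_{k:04d}"

    for rep in REPLICONS:
        n_transport = int(t.loc[rep, "transport"])
        n_cog = int(t.loc[rep, "cog_assigned"])
        n_unclassified = int(
            t.loc[rep, "cds"]
            - t.loc[rep, "assigned"]
            - t.loc[rep, "conserved_hypothetical"]
            - t.loc[rep, "hypothetical"]
        )
        cds_categories = (
            ["assigned"] * int(t.loc[rep, "assigned"])
            + ["conserved_hypothetical"] * int(t.loc[rep, "conserved_hypothetical"])
            + ["hypothetical"] * int(t.loc[rep, "hypothetical"])
            + ["unclassified"] * n_unclassified
        )
        for i, cat in enumerate(cds_categories):
            if i < n_transport:
                cogs = frozenset("P")
            elif i < n_cog:
                cogs = frozenset("R")
            else:
                cogs = frozenset()
            rows.append(AnnotationRow(next_id(), rep, cat, cogs, "CDS"))
        for _ in range(int(t.loc[rep, "trna"])):
            rows.append(AnnotationRow(next_id(), rep, "assigned", frozenset(), "tRNA"))
    for element, counts in _IS_ELEMENTS.items():
        for rep, n in zip(REPLICONS, counts):
            for _ in range(n):
                rows.append(
                    AnnotationRow(next_id(), rep, "assigned", frozenset(),
                                  "IS_element", element)
                )
    for element, counts in _TRANSPOSONS.items():
        for rep, n in zip(REPLICONS, counts):
            for _ in range(n):
                rows.append(
                    AnnotationRow(next_id(), rep, "assigned", frozenset(),
                                  "transposon", element)
                )
    return rows


def ch34_paralogy_partition() -> tuple[list[int], int]:
    """Family sizes and singleton count reconstructing the printed census.

    The printed census fixes the totals (43 large clusters with 1,358
    members led by sizes 138/123/121/110; 656 small clusters with 1,724
    members; 3,311 proteins with a paralog; 3,008 singletons) but not
    every individual size, so intermediate sizes are filled
    deterministically to honour all totals.
    """
    sizes = list(PARALOGY_LARGEST_SIZES)
    remaining_large = PARALOGY_N_IN_LARGE - sum(sizes)  # 866 over 39 clusters
    n_rest = PARALOGY_N_LARGE_CLUSTERS - len(sizes)
    base = remaining_large // n_rest
    extra = remaining_large - base * n_rest
    sizes += [base + 1] * extra + [base] * (n_rest - extra)
    assert sum(sizes) == PARALOGY_N_IN_LARGE and len(sizes) == PARALOGY_N_LARGE_CLUSTERS
    assert min(sizes) >= 10

    # small clusters (2-6 members): 656 clusters totalling 1,724
    n3 = PARALOGY_N_IN_SMALL - 2 * PARALOGY_N_SMALL_CLUSTERS  # clusters of 3
    small = [3] * n3 + [2] * (PARALOGY_N_SMALL_CLUSTERS - n3)
    assert sum(small) == PARALOGY_N_IN_SMALL

    # intermediate clusters (7-9 members) absorb the remaining members
    middle_total = PARALOGY_N_WITH_PARALOG - PARALOGY_N_IN_LARGE - PARALOGY_N_IN_SMALL
    middle = []
    while middle_total > 0:
        s = min(9, middle_total)
        if middle_total - s == 1:  # avoid leaving an impossible singleton
            s -= 1
        middle.append(s)
        middle_total -= s
    all_sizes = sizes + middle + small
    assert sum(all_sizes) == PARALOGY_N_WITH_PARALOG
    return all_sizes, PARALOGY_N_SINGLETONS
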