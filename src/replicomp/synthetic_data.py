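"""Synthetic replicons and proteomes with planted, exactly-known truth.

The generator emulates the signals the downstream stages detect:

* circular replicons whose G/C composition is biased toward G on one
  replichore and toward C on the other, so the GC skew changes sign at the
  planted ori and ter (the strand-asymmetry signature of bidirectional
  replication);
* degenerate motif copies (perfect or with a chosen number of mismatches,
  either strand) overwriting the background at chosen positions;
* multi-species proteomes in which core genes descend from a common
  ancestral sequence by substitution-only divergence (so percent identity
  and coverage are analytically controlled), accessory genes are
  species-private random sequences, and paralog families arise by
  duplication followed by divergence within one species.

Divergence is substitution-only by design: planted identity is exact and
full-length local alignments make the coverage criterion exactly
checkable. Every operation is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motif_scan import MotifHit, parse_consensus
from .sequence_io import ProteinRecord, Replicon, write_fasta

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# sub-seed offsets: one independent stream per concern
_SEED_REPLICON = 11
_SEED_ANCESTORS = 23
_SEED_DIVERGENCE = 37
_SEED_ACCESSORY = 53
_SEED_PARALOGS = 71
_SEED_ORDER = 89


@dataclass
class RepliconSimSpec:
    """Parameters of one simulated circular replicon.

    skew_delta is the excess per-base probability of G over C on the
    leading strand; it must leave both probabilities inside [0, 1].
    """

    length: int
    gc_fraction: float = 0.637  # beta-proteobacterial chromosome-like
    ori_pos: int = 0
    ter_pos: int | None = None
    skew_delta: float = 0.2
    planted_motifs: list[tuple[str, int, str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ter_pos is None:
            self.ter_pos = self.length // 2
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0,1)")
        if self.ori_pos == self.ter_pos:
            raise ValueError("ori_pos must differ from ter_pos")
        if not (0 <= self.ori_pos < self.length and 0 <= self.ter_pos < self.length):
            raise ValueError("ori/ter outside replicon")
        if self.skew_delta >= min(self.gc_fraction, 1 - self.gc_fraction):
            raise ValueError("skew_delta too large for gc_fraction")
        if self.skew_delta < 0:
            raise ValueError("skew_delta must be non-negative")


@dataclass
class ProteomeSimSpec:
    """Parameters of a multi-species proteome simulation.

    pairwise_identity is either one target percent identity applied to all
    species pairs or a map {(speciesA, speciesB): percent}. Core genes are
    shared by all species; the default core fraction follows the
    chromosome-1 compartment of a four-species Cupriavidus-style
    comparison (62 percent). paralog_families lists (size,
    within-family percent identity) tuples planted in the first species.
    order_conservation is the fraction of core genes keeping ancestral
    order in every species (the synteny signal).
    """

    species: list[str]
    genes_per_species: int = 150
    core_fraction: float = 0.62
    pairwise_identity: float | dict = 80.0
    paralog_families: list[tuple[int, float]] = field(default_factory=list)
    protein_length_mean: float = 300.0
    protein_length_sd: float = 60.0
    min_protein_length: int = 60
    order_conservation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 1 or len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique and non-empty")
        if not 0 <= self.core_fraction <= 1:
            raise ValueError("core_fraction in [0,1]")
        if self.genes_per_species < 1:
            raise ValueError("need at least one gene per species")
        if 0 < self.core_fraction and round(self.core_fraction * self.genes_per_species) < 1:
            raise ValueError("core_fraction * genes_per_species must be >= 1")
        for t in self._identity_targets().values():
            if not 20 <= t <= 100:
                raise ValueError(
                    f"target identity {t} outside [20,100] "
                    "(below 20% is indistinguishable from random)"
                )
        for size, ident in self.paralog_families:
            if size < 2:
                raise ValueError("paralog family size must be >= 2")
            if not 20 <= ident <= 100:
                raise ValueError("within-family identity outside [20,100]")

    def _identity_targets(self) -> dict[tuple[str, str], float]:
        pairs = [
            (a, b)
            for i, a in enumerate(self.species)
            for b in self.species[i + 1 :]
        ]
        if isinstance(self.pairwise_identity, dict):
            out = {}
            for a, b in pairs:
                t = self.pairwise_identity.get((a, b), self.pairwise_identity.get((b, a)))
                if t is None:
                    raise ValueError(f"no identity target for pair ({a},{b})")
                out[(a, b)] = float(t)
            return out
        return {p: float(self.pairwise_identity) for p in pairs}


@dataclass
class TruthTables:
    """Planted ground truth emitted alongside the synthetic data."""

    ortholog_groups: list[frozenset] = field(default_factory=list)
    paralog_families_truth: list[frozenset] = field(default_factory=list)
    motif_truth: list[MotifHit] = field(default_factory=list)
    ori_truth: int | None = None
    ter_truth: int | None = None


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), offset])


def simulate_replicon(spec: RepliconSimSpec) -> tuple[Replicon, TruthTables]:
    """Draw a circular sequence with a planted skew switch and motifs.

    Clockwise from ori to ter each base is G with probability
    gc/2 + delta/2 and C with probability gc/2 - delta/2; the bias is
    reversed on the other replichore. Planted motif instances overwrite
    the background (reverse-complemented for minus-strand placements);
    overlapping placements are an error.
    """
    rng = _rng(spec.seed, _SEED_REPLICON)
    L = spec.length
    gc, delta = spec.gc_fraction, spec.skew_delta
    at = 1 - gc
    p_lead = [at / 2, (gc - delta) / 2, (gc + delta) / 2, at / 2]  # A C G T
    p_lag = [at / 2, (gc + delta) / 2, (gc - delta) / 2, at / 2]

    on_lead = np.zeros(L, dtype=bool)
    if spec.ori_pos < spec.ter_pos:
        on_lead[spec.ori_pos : spec.ter_pos] = True
    else:
        on_lead[spec.ori_pos :] = True
        on_lead[: spec.ter_pos] = True

    bases = np.array(list("ACGT"))
    draw_lead = rng.choice(4, size=L, p=p_lead)
    draw_lag = rng.choice(4, size=L, p=p_lag)
    seq = np.where(on_lead, bases[draw_lead], bases[draw_lag])

    truth = TruthTables(ori_truth=spec.ori_pos, ter_truth=spec.ter_pos)
    occupied: list[tuple[int, int]] = []
    for consensus, pos, strand, n_mm in spec.planted_motifs:
        motif = parse_consensus(consensus, consensus)
        word = _motif_instance(motif, n_mm, rng)
        if strand == "-":
            word = word.translate(_COMPLEMENT)[::-1]
        elif strand != "+":
            raise ValueError(f"bad strand {strand!r}")
        start, end = pos, pos + motif.length
        if end > L:
            raise ValueError("planted motif runs off the replicon")
        for s, e in occupied:
            if start < e and s < end:
                raise ValueError(f"planted motif at {pos} overlaps another at {s}")
        occupied.append((start, end))
        seq[start:end] = list(word)
        truth.motif_truth.append(MotifHit(pos, strand, n_mm, consensus, motif.length))
    return Replicon(id=f"sim_{spec.seed}", seq="".join(seq)), truth


def _motif_instance(motif, n_mismatches: int, rng: np.random.Generator) -> str:
    """A concrete word matching the consensus except at n planted mismatches."""
    if n_mismatches >= motif.length:
        raise ValueError("cannot plant more mismatches than motif positions")
    word = [sorted(s)[rng.integers(len(s))] for s in motif.positions]
    mm_pos = rng.choice(motif.length, size=n_mismatches, replace=False)
    for i in sorted(int(x) for x in mm_pos):
        disallowed = sorted(set("ACGT") - motif.positions[i])
        if not disallowed:
            raise ValueError(f"position {i} allows all bases: cannot plant a mismatch")
        word[i] = disallowed[rng.integers(len(disallowed))]
    return "".join(word)


def mutate_to_identity(seq: str, target_identity: float, seed: int) -> str:
    """Substitute exactly round((100-target)/100 * len) positions.

    Positions are drawn uniformly without replacement and each replacement
    residue differs from the original; no indels, so the realized identity
    (direct per-position recount) equals the target to within rounding.
    """
    if not 20 <= target_identity <= 100:
        raise ValueError("target identity outside [20,100]")
    rng = _rng(seed, _SEED_DIVERGENCE)
    n = len(seq)
    n_sub = round(n * (100.0 - target_identity) / 100.0)
    if n_sub == 0:
        return seq
    positions = rng.choice(n, size=n_sub, replace=False)
    out = list(seq)
    for i in positions:
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _random_protein(rng: np.random.Generator, mean: float, sd: float, minimum: int) -> str:
    length = max(minimum, int(round(rng.normal(mean, sd))))
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


def _star_divergences(spec: ProteomeSimSpec) -> dict[str, float]:
    """Per-species divergence (percent) fitted to the pairwise targets.

    On a star tree the expected pairwise divergence of two tips is the sum
    of their branch divergences; the per-species values are the
    least-squares non-negative solution of d_a + d_b = 100 - t_ab.
    """
    targets = spec._identity_targets()
    species = spec.species
    if len(species) == 1:
        return {species[0]: 0.0}
    import scipy.optimize

    rows, rhs = [], []
    for (a, b), t in targets.items():
        row = [0.0] * len(species)
        row[species.index(a)] = 1.0
        row[species.index(b)] = 1.0
        rows.append(row)
        rhs.append(100.0 - t)
    sol, _ = scipy.optimize.nnls(np.array(rows), np.array(rhs))
    return dict(zip(species, sol))


def simulate_proteomes(
    spec: ProteomeSimSpec,
) -> tuple[dict[str, list[ProteinRecord]], TruthTables]:
    """Multi-species proteomes with planted orthologs, paralogs and order.

    Core genes are per-species mutants of a common ancestor; accessory
    genes are private random sequences; paralog families are diverged
    duplicates planted in the first species. Gene ids are
    ``<species>_g<k>``; order_index follows ancestral order for the
    conserved fraction of core genes.
    """
    n_core = round(spec.core_fraction * spec.genes_per_species)
    n_acc = spec.genes_per_species - n_core
    anc_rng = _rng(spec.seed, _SEED_ANCESTORS)
    ancestors = [
        _random_protein(anc_rng, spec.protein_length_mean, spec.protein_length_sd,
                        spec.min_protein_length)
        for _ in range(n_core)
    ]
    divergence = _star_divergences(spec)

    truth = TruthTables()
    proteomes: dict[str, list[ProteinRecord]] = {}
    groups: list[set[str]] = [set() for _ in range(n_core)]

    for s_idx, sp in enumerate(spec.species):
        genes: list[tuple[str, str]] = []  # (gene id, seq) in ancestral order
        target = max(20.0, 100.0 - divergence[sp])
        for g_idx, anc in enumerate(ancestors):
            gid = f"{sp}_g{g_idx:04d}"
            seq = (
                anc
                if divergence[sp] == 0
                else mutate_to_identity(anc, target, spec.seed * 1009 + s_idx * 101 + g_idx)
            )
            genes.append((gid, seq))
            groups[g_idx].add(gid)
        acc_rng = _rng(spec.seed, _SEED_ACCESSORY + s_idx)
        for a_idx in range(n_acc):
            gid = f"{sp}_g{n_core + a_idx:04d}"
            genes.append(
                (gid, _random_protein(acc_rng, spec.protein_length_mean,
                                      spec.protein_length_sd, spec.min_protein_length))
            )
        proteomes[sp] = genes  # placeholder; order assigned below

    # paralog families planted in the first species
    host = spec.species[0]
    par_rng = _rng(spec.seed, _SEED_PARALOGS)
    next_idx = spec.genes_per_species
    for f_idx, (size, ident) in enumerate(spec.paralog_families):
        seed_seq = _random_protein(par_rng, spec.protein_length_mean,
                                   spec.protein_length_sd, spec.min_protein_length)
        fam = set()
        for c in range(size):
            gid = f"{host}_g{next_idx:04d}"
            next_idx += 1
            seq = seed_seq if c == 0 else mutate_to_identity(
                seed_seq, ident, spec.seed * 2003 + f_idx * 211 + c
            )
            proteomes[host].append((gid, seq))
            fam.add(gid)
        truth.paralog_families_truth.append(frozenset(fam))

    truth.ortholog_groups = [frozenset(g) for g in groups if len(g) > 1]

    # gene order: conserved core genes keep ancestral order, the rest are
    # reinserted at random positions (per species)
    records: dict[str, list[ProteinRecord]] = {}
    for s_idx, sp in enumerate(spec.species):
        order_rng = _rng(spec.seed, _SEED_ORDER + s_idx)
        genes = proteomes[sp]
        n_genes = len(genes)
        core_ids = list(range(min(n_core, n_genes)))
        n_keep = round(spec.order_conservation * len(core_ids))
        shuffled = [i for i in range(n_genes) if i >= n_core]
        if n_keep < len(core_ids):
            moved = sorted(
                int(x) for x in order_rng.choice(len(core_ids),
                                                 size=len(core_ids) - n_keep,
                                                 replace=False)
            )
            shuffled += moved
            core_ids = [i for i in core_ids if i not in set(moved)]
        order = list(core_ids)
        for idx in shuffled:
            order.insert(int(order_rng.integers(len(order) + 1)), idx)
        records[sp] = [
            ProteinRecord(genes[g][0], sp, f"{sp}_CHR1", pos, genes[g][1])
            for pos, g in enumerate(order)
        ]
    return records, truth


def write_simulation(
    proteomes: dict[str, list[ProteinRecord]],
    truth: TruthTables,
    out_dir: str | Path,
    replicons: list[tuple[Replicon, TruthTables]] | None = None,
) -> None:
    """Write per-species FASTA plus truth tables (TSV/BED) to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, recs in proteomes.items():
        ordered = sorted(recs, key=lambda r: r.order_index)
        write_fasta([(r.id, r.seq) for r in ordered], out / f"{sp}.faa")
        with open(out / f"{sp}.order.tsv", "w") as fh:
            fh.write("protein_id\treplicon\torder_index\n")
            for r in ordered:
                fh.write(f"{r.id}\t{r.replicon}\t{r.order_index}\n")
    with open(out / "ortholog_groups.tsv", "w") as fh:
        fh.write("group_id\tmembers\n")
        for i, g in enumerate(truth.ortholog_groups):
            fh.write(f"og{i:05d}\t{','.join(sorted(g))}\n")
    with open(out / "paralogs.tsv", "w") as fh:
        fh.write("family_id\tmembers\n")
        for i, g in enumerate(truth.paralog_families_truth):
            fh.write(f"pf{i:05d}\t{','.join(sorted(g))}\n")
    if replicons:
        write_fasta([(r.id, r.seq) for r, _ in replicons], out / "replicons.fna")
        with open(out / "ori_ter.tsv", "w") as fh:
            fh.write("replicon\tori\tter\n")
            for r, t in replicons:
                fh.write(f"{r.id}\t{t.ori_truth}\t{t.ter_truth}\n")
        with open(out / "motifs.bed", "w") as fh:
            for r, t in replicons:
                for h in sorted(t.motif_truth, key=lambda h: h.start):
                    fh.write(
                        f"{r.id}\t{h.start}\t{h.start + h.length}\t"
                        f"{h.motif_name}\t{h.mismatches}\t{h.strand}\n"
                    )
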