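"""End-to-end pipeline: simulate -> skew/scan -> orthologs -> cluster -> paralogs.

A single YAML config drives every stage; all randomness flows from the
config seed and a manifest records inputs, effective parameters and
output checksums so a rerun of a seeded config is verifiably identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import yaml

from . import clustering, motif_scan, sequence_io, skew_analysis, synthetic_data
from .alignment_orthology import build_ortholog_groups, call_orthologs, venn_partition
from .paralog_families import family_stats, find_paralog_families

logger = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "replicomp_out",
    "simulate": {
        "replicon": {
            "length": 100_000,
            "gc_fraction": 0.637,
            "ori_pos": 0,
            "ter_pos": None,
            "skew_delta": 0.2,
            "planted_motifs": [],
        },
        "proteomes": {
            "species": ["A", "B", "C", "D"],
            "genes_per_species": 150,
            "core_fraction": 0.62,
            "pairwise_identity": 80.0,
            "paralog_families": [],
            "order_conservation": 1.0,
        },
    },
    "skew": {"window": 2000, "step": None},
    "motifs": {"consensus": motif_scan.DNAA_BOX, "max_mismatches": 2, "cluster_gap": 500},
    "orthologs": {
        "min_identity": 35.0,
        "min_coverage": 0.8,
        "prefilter_kmer": 4,
        "min_shared_kmers": 2,
    },
    "paralogs": {"min_identity": 30.0, "min_coverage": 0.5},
}

_RANGES = {
    ("skew", "window"): (1, 10_000_000),
    ("motifs", "max_mismatches"): (0, 8),
    ("orthologs", "min_identity"): (0, 100),
    ("orthologs", "min_coverage"): (0, 1),
    ("paralogs", "min_identity"): (0, 100),
    ("paralogs", "min_coverage"): (0, 1),
}


@dataclass
class PipelineConfig:
    params: dict

    def __getitem__(self, key):
        return self.params[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.params, sort_keys=True)


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load, default-fill, type- and range-check a pipeline config.

    *source* may be a YAML path or an already-parsed mapping. Unknown keys
    and out-of-range values are rejected with the offending name.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            given = yaml.safe_load(fh) or {}
    else:
        given = source
    if not isinstance(given, dict):
        raise ValueError("config must be a mapping")
    params = _merge(DEFAULTS, given)
    for (section, key), (lo, hi) in _RANGES.items():
        value = params[section][key]
        if value is None:
            continue
        if not (lo <= value <= hi):
            raise ValueError(f"{section}.{key}={value} outside [{lo}, {hi}]")
    logger.info("effective config:\n%s", yaml.safe_dump(params, sort_keys=True))
    return PipelineConfig(params)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    p = config.params
    out = Path(p["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(p["seed"])

    # --- simulate ---------------------------------------------------------
    rep_spec = synthetic_data.RepliconSimSpec(seed=seed, **p["simulate"]["replicon"])
    replicon, rep_truth = synthetic_data.simulate_replicon(rep_spec)
    prot_spec = synthetic_data.ProteomeSimSpec(seed=seed, **{
        k: (tuple(map(tuple, v)) if k == "paralog_families" else v)
        for k, v in p["simulate"]["proteomes"].items()
    })
    proteomes, prot_truth = synthetic_data.simulate_proteomes(prot_spec)
    sim_dir = out / "simulated"
    synthetic_data.write_simulation(proteomes, prot_truth, sim_dir,
                                    replicons=[(replicon, rep_truth)])

    # --- skew + ori/ter ---------------------------------------------------
    window = p["skew"]["window"]
    step = p["skew"]["step"] or window
    content = skew_analysis.gc_content_windows(replicon, window, step)
    skew = skew_analysis.gc_skew_windows(replicon, window, step)
    with open(out / "skew.tsv", "w") as fh:
        fh.write("start\tgc_content\tgc_skew\n")
        for s, gcv, skv in zip(content.positions, content.values, skew.values):
            fh.write(f"{s}\t{gcv:.6f}\t{skv:.6f}\n")

    # --- motif scan -------------------------------------------------------
    motif = motif_scan.parse_consensus(p["motifs"]["consensus"], "dnaA_box")
    hits = motif_scan.scan(replicon, motif, p["motifs"]["max_mismatches"])
    sequence_io.write_bed(hits, replicon.id, out / "motif_hits.bed")
    clusters = motif_scan.cluster_hits(hits, p["motifs"]["cluster_gap"], replicon.length)
    call = skew_analysis.predict_ori_ter(replicon, clusters)
    with open(out / "ori_ter.tsv", "w") as fh:
        fh.write("ori\tter\treplichore_1\treplichore_2\tasymmetry\trefined_by_boxes\n")
        fh.write(
            f"{call.ori}\t{call.ter}\t{call.replichore_lengths[0]}\t"
            f"{call.replichore_lengths[1]}\t{call.asymmetry:.3f}\t{call.refined_by_boxes}\n"
        )

    # --- orthologs, groups, venn, clustering ------------------------------
    ortho_kwargs = dict(p["orthologs"])
    species = sorted(proteomes)
    pairs_by_pair = {}
    for a, b in combinations(species, 2):
        pairs_by_pair[(a, b)] = call_orthologs(proteomes[a], proteomes[b], **ortho_kwargs)
    with open(out / "ortholog_pairs.tsv", "w") as fh:
        fh.write("species_a\tspecies_b\tprotein_a\tprotein_b\tidentity_pct\t"
                 "coverage_smaller\tscore\n")
        for (a, b), pairs in sorted(pairs_by_pair.items()):
            for pr in pairs:
                fh.write(f"{a}\t{b}\t{pr.protein_a}\t{pr.protein_b}\t"
                         f"{pr.identity_pct:.2f}\t{pr.coverage_smaller:.3f}\t{pr.score:.1f}\n")
    protein_species = {r.id: sp for sp, recs in proteomes.items() for r in recs}
    groups = build_ortholog_groups(pairs_by_pair, protein_species)
    with open(out / "ortholog_groups.tsv", "w") as fh:
        fh.write("group_id\tspecies\tmembers\n")
        for i, g in enumerate(groups):
            fh.write(f"og{i:05d}\t{','.join(sorted(g['species']))}\t"
                     f"{','.join(g['members'])}\n")
    if 2 <= len(species) <= 4:
        regions = venn_partition(
            groups, {sp: [r.id for r in recs] for sp, recs in proteomes.items()}
        )
        with open(out / "venn.tsv", "w") as fh:
            fh.write("species_subset\tn_groups\tn_proteins\n")
            for key in sorted(regions, key=lambda k: (len(k), sorted(k))):
                fh.write(f"{'+'.join(sorted(key))}\t{regions[key]['n_groups']}\t"
                         f"{regions[key]['n_proteins']}\n")
    matrix = clustering.DistanceMatrix(
        species,
        [
            [
                0.0 if a == b else clustering.replicon_distance(
                    len(pairs_by_pair[tuple(sorted((a, b)))]),
                    len(proteomes[a]),
                    len(proteomes[b]),
                )
                for b in species
            ]
            for a in species
        ],
    )
    with open(out / "distance_matrix.tsv", "w") as fh:
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    tree = clustering.single_linkage(matrix)
    sequence_io.write_newick(tree.newick, out / "replicons.nwk")

    # --- paralogs on the first species ------------------------------------
    host = species[0]
    families, singletons, excluded = find_paralog_families(
        proteomes[host], **p["paralogs"]
    )
    stats = family_stats(families, singletons, excluded)
    with open(out / "paralog_families.tsv", "w") as fh:
        fh.write("family_id\tmembers\n")
        for i, fam in enumerate(families):
            fh.write(f"pf{i:05d}\t{','.join(sorted(fam.members))}\n")
    with open(out / "paralog_stats.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in vars(stats).items():
            fh.write(f"{key}\t{value}\n")

    # --- manifest ---------------------------------------------------------
    outputs = sorted(
        str(f.relative_to(out)) for f in out.rglob("*") if f.is_file()
        and f.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "parameters": p,
        "outputs": {name: _checksum(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
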