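"""End-to-end orchestration: simulate (or load) inputs, assign reads,
estimate damage, run the filter cascade, and write all artifacts.

Every output table starts with comment headers recording the tool version,
a hash of the configuration and the seed, so runs are auditable and
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .damage import AuthThresholds, fit_all_nodes, fits_to_frame, tally_mismatches
from .filters import FilterConfig, apply_filters, normalize_proportions
from .lca import AssignConfig, assign_and_profile, assign_reads, read_hit_table, write_hit_table
from .simulate import (
    DamageParams,
    SimulationConfig,
    make_taxonomy_and_refs,
    simulate_hit_table,
    simulate_reads,
    write_fastq,
)
from .taxonomy import load_taxonomy, write_taxonomy


class PipelineError(RuntimeError):
    """Configuration or input problem that should abort the run."""


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, config: dict, seed: int) -> None:
    """TSV with a provenance header (version, config hash, seed)."""
    with open(path, "w") as fh:
        fh.write(f"# sedadna {__version__}\n")
        fh.write(f"# config_hash={config_hash(config)}\n")
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config must be a mapping: {path}")
    return cfg


def run_end_to_end(config: dict, output_dir) -> Path:
    """Run simulate -> assign -> damage -> filter -> normalize.

    The ``simulate`` block generates all inputs; alternatively a ``paths``
    block points at existing hit-table and taxonomy files. Artifacts
    (taxonomy dumps, reads, hit table, profile, damage fits, filter log,
    proportions, summary JSON) land in *output_dir*, which is returned.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "simulate" in config:
        sim = dict(config["simulate"])
        taxonomy, refs = make_taxonomy_and_refs(
            n_genera=sim.get("n_genera", 4),
            species_per_genus=sim.get("species_per_genus", 2),
            ref_length=sim.get("ref_length", 5000),
            seed=seed,
            sibling_divergence=sim.get("sibling_divergence", 0.03),
        )
        sim_config = SimulationConfig(
            taxon_abundances=sim.get("taxon_abundances") or {sp: 1.0 for sp in refs},
            damage=DamageParams(**sim.get("damage", {})),
            contamination_fraction=sim.get("contamination_fraction", 0.0),
            contaminant_abundances=sim.get("contaminant_abundances"),
            n_reads=sim.get("n_reads", 10_000),
            n_replicates=sim.get("n_replicates", 1),
            n_sites=sim.get("n_sites", 1),
            n_units=sim.get("n_units", 1),
            fragment_mean=sim.get("fragment_mean", 50.0),
            seed=seed,
        )
        reads, truth, metadata = simulate_reads(refs, sim_config)
        hits = simulate_hit_table(
            reads, truth, refs, taxonomy,
            identity_noise=sim.get("identity_noise", 0.0), seed=seed,
        )
        with open(outdir / "nodes.dmp", "w") as nf, open(outdir / "names.dmp", "w") as mf:
            write_taxonomy(taxonomy, nf, mf)
        write_fastq(reads, outdir / "reads.fastq")
        write_table(truth, outdir / "truth.tsv", config, seed)
        write_hit_table(hits, outdir / "hits.tsv")
    elif "paths" in config:
        paths = config["paths"]
        for key in ("hits", "taxonomy_nodes", "taxonomy_names"):
            if key not in paths:
                raise PipelineError(f"paths block missing required entry: {key}")
            if not Path(paths[key]).exists():
                raise PipelineError(f"input path does not exist: {paths[key]}")
        with open(paths["taxonomy_nodes"]) as nf, open(paths["taxonomy_names"]) as mf:
            taxonomy = load_taxonomy(nf, mf)
        hits = read_hit_table(paths["hits"])
        reads = {}
        if "reads" in paths:
            from .simulate import read_fastq

            reads = read_fastq(paths["reads"])
        metadata = {}
    else:
        raise PipelineError("config needs either a 'simulate' or a 'paths' block")

    assign_cfg = AssignConfig(**config.get("assign", {}))
    profile = assign_and_profile(hits, taxonomy, assign_cfg, metadata)
    profile.write(outdir / "profile.tsv", taxonomy)

    fits = {}
    if reads:
        assignments = assign_reads(hits, taxonomy, assign_cfg)
        matrix = tally_mismatches(hits, reads, assignments, taxonomy)
        fits = fit_all_nodes(matrix, min_reads=int(config.get("damage_min_reads", 50)))
        write_table(fits_to_frame(fits, taxonomy), outdir / "damage_fits.tsv", config, seed)

    filter_cfg = FilterConfig(**config.get("filter", {}))
    filtered, log = apply_filters(profile, fits if reads else None, filter_cfg)
    write_table(log, outdir / "filter_log.tsv", config, seed)
    filtered.write(outdir / "profile_filtered.tsv", taxonomy)
    if len(filtered.counts):
        write_table(
            normalize_proportions(filtered), outdir / "proportions.tsv", config, seed
        )

    summary = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "n_reads_assigned": int(profile.counts["count"].sum()),
        "n_reads_unassigned": int(sum(profile.unassigned.values())),
        "n_taxa_profiled": int(profile.counts["node"].nunique()),
        "n_taxa_retained": int(filtered.counts["node"].nunique()),
        "n_samples_retained": int(filtered.counts["sample"].nunique()),
        "filter_config": asdict(filter_cfg),
        "assign_config": asdict(assign_cfg),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return outdir


def synthetic_cohort_metrics(
    seed: int,
    n_truth_genera: int = 5,
    n_contaminant_genera: int = 3,
    n_reads: int = 8_000,
    n_replicates: int = 4,
    contamination_fraction: float = 0.25,
) -> dict:
    """Run the full cascade on a synthetic cohort and score it against truth.

    The ancient community occupies ``n_truth_genera`` genera (damaged reads);
    contaminant reads are undamaged and drawn from separate genera. Returns
    recall of truth genera and leakage of contaminant genera after filtering.
    """
    n_genera = n_truth_genera + n_contaminant_genera
    taxonomy, refs = make_taxonomy_and_refs(
        n_genera=n_genera, species_per_genus=2, ref_length=4000, seed=seed
    )
    genera = sorted({taxonomy.parent[sp] for sp in refs})
    truth_genera = set(genera[:n_truth_genera])
    cont_genera = set(genera[n_truth_genera:])
    truth_species = {sp: 1.0 for sp in refs if taxonomy.parent[sp] in truth_genera}
    cont_species = {sp: 1.0 for sp in refs if taxonomy.parent[sp] in cont_genera}

    config = SimulationConfig(
        taxon_abundances=truth_species,
        contaminant_abundances=cont_species,
        contamination_fraction=contamination_fraction,
        n_reads=n_reads,
        n_replicates=n_replicates,
        seed=seed,
    )
    reads, truth, metadata = simulate_reads(refs, config)
    hits = simulate_hit_table(reads, truth, refs, taxonomy, seed=seed)

    assign_cfg = AssignConfig()
    assignments = assign_reads(hits, taxonomy, assign_cfg)
    profile = assign_and_profile(hits, taxonomy, assign_cfg, metadata)
    matrix = tally_mismatches(hits, reads, assignments, taxonomy)
    fits = fit_all_nodes(matrix, min_reads=50)
    filtered, _ = apply_filters(profile, fits, FilterConfig())

    retained_nodes = set(filtered.counts["node"].unique())

    def genus_of(node: int) -> int | None:
        for g in genera:
            if taxonomy.is_ancestor(g, node):
                return g
        return None

    retained_genera = {genus_of(n) for n in retained_nodes} - {None}
    recall = len(retained_genera & truth_genera) / len(truth_genera)
    leakage = len(retained_genera & cont_genera)
    return {
        "recall": recall,
        "leaked_contaminant_genera": leakage,
        "n_retained_taxa": len(retained_nodes),
    }
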