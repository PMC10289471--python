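"""End-to-end pipeline: simulate -> sample -> gene trees -> diagnostics.

A TOML config drives the run; every random draw descends from one seed
recorded in the manifest, and re-running a manifest reproduces the
simulator archive byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import os
import time

import numpy as np
import pandas as pd

from . import genealogy as G
from . import io as sio
from . import sfs as S
from . import treestats as T
from .spatial_sim import (
    PedigreeArchive,
    SimulationConfig,
    Schedule,
    comb_peripatry_schedule,
    comb_vicariance_schedule,
    run_simulation,
    sample_individuals,
    six_taxon_comb_times,
)

__all__ = [
    "validate_config",
    "load_config",
    "build_simulation",
    "run_pipeline",
    "rerun_simulation_from_manifest",
    "export_for_external_tools",
    "quartet_concordance_factors",
]

TOOL_VERSION = "0.1.0"

_ALLOWED = {
    "simulation": {
        "range_width",
        "range_height",
        "n_generations",
        "seed",
        "preset",
        "target_density",
        "sigma_I",
        "sigma_D",
        "sigma_M",
        "fecundity_rate",
        "boundary",
    },
    "speciation": {"mode", "divergence_times", "expansion_lag", "axis"},
    "sampling": {"scheme", "n", "edge", "haplotypes"},
    "genetrees": {"n_loci", "recapitate", "ne_ancestral"},
    "mutations": {"mu", "locus_length"},
    "analysis": {"census", "skew", "sfs", "treespace", "n_trees_embedded"},
    "export": {"external_tools", "pseudogene_block_size", "pseudogene_blocks"},
}


def validate_config(config: dict) -> None:
    """Reject unknown sections or keys, naming the offender."""
    for section, content in config.items():
        if section not in _ALLOWED:
            raise ValueError(f"unknown config section {section!r}")
        for key in content:
            if key not in _ALLOWED[section]:
                raise ValueError(
                    f"unknown key {key!r} in config section {section!r}"
                )
    if "simulation" not in config:
        raise ValueError("config requires a [simulation] section")


def load_config(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        config = tomllib.load(fh)
    validate_config(config)
    return config


def build_simulation(
    config: dict, seed: int | None = None
) -> tuple[SimulationConfig, Schedule]:
    sim = dict(config["simulation"])
    if seed is not None:
        sim["seed"] = seed
    sim_config = SimulationConfig(**sim)
    spec = config.get("speciation", {})
    times = spec.get("divergence_times", [])
    if times == "six_taxon_comb":
        times = six_taxon_comb_times()
    if not times:
        schedule = Schedule()
    elif spec.get("mode", "vicariance") == "vicariance":
        schedule = comb_vicariance_schedule(
            sim_config, list(times), axis=spec.get("axis", "x")
        )
    else:
        schedule = comb_peripatry_schedule(
            sim_config,
            list(times),
            expansion_lag=spec.get("expansion_lag"),
            axis=spec.get("axis", "x"),
        )
    return sim_config, schedule


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the configured pipeline, returning (and writing) the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    os.makedirs(out_dir, exist_ok=True)
    sim_config, schedule = build_simulation(config, seed)
    seed = sim_config.seed
    manifest = {
        "tool_version": TOOL_VERSION,
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "status": "running",
    }

    def stage(name: str, **info):
        manifest["stages"][name] = info

    try:
        archive = run_simulation(sim_config, schedule)
        arc_dir = os.path.join(out_dir, "archive")
        archive.save(arc_dir)
        stage(
            "simulate",
            out=arc_dir,
            checksum=archive.checksum(),
            status=archive.status,
            final_census=archive.census()[-1].item(),
        )
        if archive.status != "completed":
            raise RuntimeError("simulation went extinct; partial archive kept")

        samp = config.get("sampling", {})
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        samples = pd.concat(
            [
                sample_individuals(
                    archive,
                    sp,
                    samp.get("scheme", "random"),
                    samp.get("n", 2),
                    rng,
                    edge=samp.get("edge", "left"),
                )
                for sp in sorted(archive.species_at_final())
            ],
            ignore_index=True,
        )
        samples_path = os.path.join(out_dir, "samples.tsv")
        sio.write_sample_table(samples, samples_path)
        stage("sample", out=samples_path, n=len(samples))

        gt = config.get("genetrees", {})
        n_loci = gt.get("n_loci", 100)
        haps = samp.get("haplotypes", "both")
        trees = G.extract_gene_trees(
            archive, samples, n_loci, seed, haplotypes=haps
        )
        if gt.get("recapitate", True):
            ne_anc = gt.get("ne_ancestral", archive.founding_count)
            trees = [
                G.recapitate(
                    t,
                    ne_anc,
                    np.random.default_rng(
                        np.random.SeedSequence([seed, t.locus, 1])
                    ),
                )
                for t in trees
            ]
        trees_path = os.path.join(out_dir, "gene_trees.nwk")
        sio.write_newick_trees(trees, trees_path)
        stage("genetrees", out=trees_path, n_loci=n_loci)

        mut = config.get("mutations", {})
        variants = None
        if mut:
            mrng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
            variants = G.VariantTable.concat(
                [
                    G.overlay_mutations(
                        t, mut.get("mu", 1e-8), mut.get("locus_length", 1000),
                        mrng,
                    )
                    for t in trees
                ]
            )
            var_path = os.path.join(out_dir, "variants.tsv")
            sio.write_variants_tsv(variants, var_path)
            sio.write_vcf(variants, os.path.join(out_dir, "variants.vcf"))
            stage("mutations", out=var_path, n_sites=variants.n_sites)

        ana = config.get("analysis", {})
        taxa = tuple(sorted(archive.species_at_final()))
        if ana.get("census", True):
            crng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
            census = T.census_topologies(
                trees, taxa, outgroup=taxa[-1], rng=crng
            )
            census_path = os.path.join(out_dir, "census.tsv")
            census.as_dataframe().to_csv(census_path, sep="\t", index=False)
            stage("census", out=census_path, n_classes=len(census.counts))
            if ana.get("skew", len(taxa) == 3) and len(taxa) == 3:
                skew = T.slatkin_skew_test(
                    census,
                    f"(({taxa[1]}{taxa[2]}){taxa[0]})",
                    f"(({taxa[0]}{taxa[2]}){taxa[1]})",
                )
                skew_path = os.path.join(out_dir, "skew.tsv")
                pd.DataFrame([dataclasses.asdict(skew)]).to_csv(
                    skew_path, sep="\t", index=False
                )
                stage("skew", out=skew_path, skew=skew.skew, p=skew.pvalue)
        if ana.get("sfs", False) and variants is not None:
            spec = S.compute_sfs(variants)
            sfs_path = os.path.join(out_dir, "sfs.tsv")
            pd.DataFrame(
                {
                    "derived_count": np.arange(1, spec.n),
                    "n_sites": spec.counts,
                }
            ).to_csv(sfs_path, sep="\t", index=False)
            stage("sfs", out=sfs_path, n_segregating=spec.n_segregating)
        if ana.get("treespace", False):
            k = min(ana.get("n_trees_embedded", 100), len(trees))
            D = T.rf_distance_matrix(trees[:k])
            emb = T.nmds_embed(
                D, seed=seed, n_init=4, max_iter=300, eps=1e-6
            )
            emb_path = os.path.join(out_dir, "treespace.tsv")
            pd.DataFrame(
                {"locus": [t.locus for t in trees[:k]],
                 "nmds1": emb.coords[:, 0], "nmds2": emb.coords[:, 1]}
            ).to_csv(emb_path, sep="\t", index=False)
            stage("treespace", out=emb_path, stress=emb.stress)

        exp = config.get("export", {})
        if exp.get("external_tools", False) and variants is not None:
            alns = G.make_pseudogenes(
                variants,
                block_size=exp.get("pseudogene_block_size", 500),
                n_blocks=exp.get("pseudogene_blocks", 5),
            )
            export_dir = os.path.join(out_dir, "exports")
            export_for_external_tools(
                trees, alns, samples, export_dir, seed=seed
            )
            stage("export", out=export_dir)
        manifest["status"] = "completed"
    except Exception as err:
        manifest["status"] = f"failed: {err}"
        _write_manifest(manifest, out_dir)
        raise
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def rerun_simulation_from_manifest(manifest_path) -> PedigreeArchive:
    """Re-run the simulate stage recorded in a manifest (for replication)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    sim_config, schedule = build_simulation(
        manifest["config"], manifest["seed"]
    )
    return run_simulation(sim_config, schedule)


# ---------------------------------------------------------------------------
# exporters for external inference tools
# ---------------------------------------------------------------------------


def quartet_concordance_factors(
    trees, taxa, rng: np.random.Generator
) -> pd.DataFrame:
    """Gene-tree concordance factors for every quartet of taxa.

    Rows carry the three resolutions of each quartet; the three CFs sum
    to 1. Input for pseudolikelihood network methods.
    """
    taxa = tuple(taxa)
    rows = []
    for quartet in itertools.combinations(taxa, 4):
        counts = {0: 0, 1: 0, 2: 0}
        splits = [
            ((quartet[0], quartet[1]), (quartet[2], quartet[3])),
            ((quartet[0], quartet[2]), (quartet[1], quartet[3])),
            ((quartet[0], quartet[3]), (quartet[1], quartet[2])),
        ]
        for tree in trees:
            label = T.classify_topology(tree, quartet, rng)
            struct = T.parse_topology_label(label)

            def cherry(node):
                if isinstance(node, str):
                    return None
                kids = list(node)
                if all(isinstance(k, str) for k in kids) and len(kids) == 2:
                    return tuple(sorted(kids))
                for k in kids:
                    c = cherry(k)
                    if c is not None:
                        return c
                return None

            pair = cherry(struct)
            for idx, (a, b) in enumerate(splits):
                if pair in (tuple(sorted(a)), tuple(sorted(b))):
                    counts[idx] += 1
                    break
        total = max(sum(counts.values()), 1)
        rows.append(
            {
                "taxon1": quartet[0],
                "taxon2": quartet[1],
                "taxon3": quartet[2],
                "taxon4": quartet[3],
                "cf_12_34": counts[0] / total,
                "cf_13_24": counts[1] / total,
                "cf_14_23": counts[2] / total,
                "n_trees": sum(counts.values()),
            }
        )
    return pd.DataFrame(rows)


def export_for_external_tools(
    trees, alignments, samples: pd.DataFrame, out_dir, seed: int = 0
) -> dict:
    """Write inputs for network/species-tree/delimitation tools.

    Gene trees as a Newick list plus a quartet concordance-factor table;
    pseudo-gene alignments as NEXUS and as a BPP-style multi-locus
    sequence file with its Imap; sample coordinates as TSV.
    """
    os.makedirs(out_dir, exist_ok=True)
    tipsets = {frozenset(t.tip_labels) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("gene trees have mixed tip sets; cannot export")
    out = {}
    trees_path = os.path.join(out_dir, "gene_trees.nwk")
    sio.write_newick_trees(trees, trees_path)
    out["gene_trees"] = trees_path

    taxa = sorted({l.rsplit("_", 2)[0] for l in trees[0].tip_labels})
    if len(taxa) >= 4:
        cf = quartet_concordance_factors(
            trees, taxa, np.random.default_rng(seed)
        )
        cf_path = os.path.join(out_dir, "quartet_cf.tsv")
        cf.to_csv(cf_path, sep="\t", index=False)
        out["quartet_cf"] = cf_path

    for b, aln in enumerate(alignments):
        nex = os.path.join(out_dir, f"pseudogene_{b}.nex")
        sio.write_nexus(aln, nex)
        out[f"nexus_{b}"] = nex

    imap_path = os.path.join(out_dir, "bpp_imap.txt")
    with open(imap_path, "w") as fh:
        for hap in sorted(alignments[0]):
            fh.write(f"{hap}\t{hap.rsplit('_', 2)[0]}\n")
    out["bpp_imap"] = imap_path
    seq_path = os.path.join(out_dir, "bpp_seqs.txt")
    with open(seq_path, "w") as fh:
        for aln in alignments:
            names = sorted(aln)
            fh.write(f"{len(names)} {len(aln[names[0]])}\n")
            for n in names:
                fh.write(f"^{n}  {aln[n]}\n")
            fh.write("\n")
    out["bpp_seqs"] = seq_path

    coords_path = os.path.join(out_dir, "coordinates.tsv")
    sio.write_sample_table(samples, coords_path)
    out["coordinates"] = coords_path
    return out
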