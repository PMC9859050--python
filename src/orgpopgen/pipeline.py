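"""End-to-end pipeline: simulate -> call -> annotate -> summarize -> network -> tree.

One :class:`PipelineConfig` drives every stage; a single base seed is split
deterministically into independent per-stage streams (simulation, network
tie-breaking, bootstrap), so re-running with the same config and seed
reproduces every output byte for byte, and changing the seed never alters
the variant calls made on a fixed alignment.  A manifest with SHA-256
checksums of every written file is emitted for reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import annotate as ann
from . import haplonet, phylo, popstats
from .io import Alignment, AnnotatedGenome, write_variant_table
from .simulate import (
    SimulationConfig,
    build_reference,
    concat_alignments,
    simulate_population,
    simulate_regions,
    write_simulation,
)
from .variants import call_variants, trim_second_ir

logger = logging.getLogger("orgpopgen")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    kind: str = "plastome"  # "plastome" | "mitogenome"
    seed: int = 1
    out_dir: str = "pipeline_out"
    scale: float = 1.0
    total_snps: float | None = None  # default: 64 plastome / 8 mitogenome
    total_indels: float | None = None  # default: 96 plastome / 16 mitogenome
    min_alt_count: int = 1
    trim_ir: bool = True
    network_iterations: int = 200
    bootstrap_reps: int = 1000
    outgroup: str | None = None
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @property
    def genetic_code(self) -> str:
        return "plastid" if self.kind == "plastome" else "mito"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _prefixed_inventory(inv: ann.RegionInventory, prefix: str) -> ann.RegionInventory:
    return ann.RegionInventory(
        [
            ann.Region(f"{prefix}:{r.name}", r.rclass, r.start, r.end)
            for r in inv
        ],
        inv.reference_length,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on one synthetic dataset and write a report directory.

    Emits: the simulation artefacts (alignments, annotations, truth tables,
    population map), ``variants/`` per-molecule annotated variant tables,
    ``summary/`` (spectrum.tsv, regions.tsv, populations.tsv, circos.tsv,
    totals.json), ``network/`` (nodes.tsv, edges.tsv, network.gml),
    ``tree/`` (tree.nwk with bootstrap supports, model_selection.tsv), the
    echoed config, and ``manifest.json`` with per-file checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "pipeline_config.json")

    # ---- simulate ---------------------------------------------------------
    @_stage("simulate")
    def do_simulate():
        ref = build_reference(config.kind, seed=config.seed, scale=config.scale)
        genomes = [ref] if isinstance(ref, AnnotatedGenome) else ref
        defaults = (64.0, 96.0) if config.kind == "plastome" else (8.0, 16.0)
        sim_cfg = SimulationConfig.calibrated(
            ref if isinstance(ref, AnnotatedGenome) else genomes,
            total_snps=config.total_snps or defaults[0],
            total_indels=config.total_indels or defaults[1],
            seed=config.seed,
            **config.simulation,
        )
        if isinstance(ref, AnnotatedGenome):
            truths = {ref.name: simulate_population(ref, sim_cfg)}
        else:
            truths = simulate_regions(genomes, sim_cfg)
        write_simulation(out / "simulation", genomes, truths, sim_cfg)
        return genomes, truths, sim_cfg

    genomes, truths, sim_cfg = do_simulate()
    popmap = sim_cfg.population_map

    # ---- call + annotate ---------------------------------------------------
    @_stage("call")
    def do_call():
        per_molecule = {}
        (out / "variants").mkdir(exist_ok=True)
        for g in genomes:
            truth = truths[g.name]
            aln = truth.alignment
            if config.kind == "plastome" and config.trim_ir:
                aln = trim_second_ir(
                    aln, g.features_of_type("IR"), truth.reference_id
                )
            variants = call_variants(
                aln, truth.reference_id, min_alt_count=config.min_alt_count
            )
            per_molecule[g.name] = (aln, variants)
        return per_molecule

    per_molecule = do_call()

    @_stage("annotate")
    def do_annotate():
        inventories = []
        for g in genomes:
            inv = ann.build_region_inventory(
                [f for f in g.features if f.ftype != "IR"],
                len(g),
                circular=g.circular,
            )
            if len(genomes) > 1:
                inv = _prefixed_inventory(inv, g.name)
            aln, variants = per_molecule[g.name]
            ann.annotate_variants(
                variants, g, inventory=inv, code=config.genetic_code
            )
            write_variant_table(
                out / "variants" / f"{g.name}.variants.tsv",
                variants,
                samples=list(aln.ids),
            )
            inventories.append(inv)
        return inventories

    inventories = do_annotate()
    all_variants = [v for g in genomes for v in per_molecule[g.name][1]]

    # ---- summarize ----------------------------------------------------------
    @_stage("summarize")
    def do_summarize():
        sdir = out / "summary"
        sdir.mkdir(exist_ok=True)
        spectrum = popstats.tstv_breakdown(all_variants)
        spectrum.as_frame().to_csv(sdir / "spectrum.tsv", sep="\t", index=False)
        regions = popstats.per_region_summary(all_variants, inventories)
        regions.to_csv(sdir / "regions.tsv", sep="\t", index=False)
        pops = popstats.per_population_counts(all_variants, popmap)
        pops.to_csv(sdir / "populations.tsv", sep="\t", index=False)
        # Circos-ready long table: one row per variant x population
        rows = []
        for v in all_variants:
            for pop in sorted(set(popmap.values())):
                members = [s for s, p in popmap.items() if p == pop]
                states = {v.alleles[m] for m in members if v.alleles.get(m, ".") != "."}
                rows.append(
                    {
                        "region": v.region_name,
                        "region_class": v.region_type,
                        "position": v.ref_position,
                        "mutation_type": v.vtype,
                        "population": pop,
                        "polymorphic": len(states) >= 2,
                    }
                )
        pd.DataFrame(rows).to_csv(sdir / "circos.tsv", sep="\t", index=False)
        total_len = sum(len(g) for g in genomes)
        totals = {
            "snps": sum(1 for v in all_variants if v.vtype == "SNP"),
            "indels": sum(1 for v in all_variants if v.vtype == "InDel"),
            "mutations": len(all_variants),
            "reference_length": total_len,
            "changes_per_bp": popstats.changes_per_bp(len(all_variants), total_len),
            "transitions": spectrum.transitions,
            "transversions": spectrum.transversions,
        }
        (sdir / "totals.json").write_text(json.dumps(totals, indent=2))
        return totals

    totals = do_summarize()

    # ---- haplotype network ---------------------------------------------------
    @_stage("network")
    def do_network():
        ndir = out / "network"
        ndir.mkdir(exist_ok=True)
        samples = list(per_molecule[genomes[0].name][0].ids)
        chars = haplonet.character_matrix(all_variants, samples)
        haps = haplonet.collapse_haplotypes(chars)
        dmat = haplonet.distance_matrix(
            {h.label: chars[h.label] for h in haps},
            metric=haplonet.character_distance,
        )
        graph = haplonet.rmst_network(
            dmat,
            iterations=config.network_iterations,
            seed=config.seed + 1,
            haplotypes=haps,
            popmap=popmap,
        )
        nodes = pd.DataFrame(
            [
                {
                    "haplotype": n,
                    "size": d["size"],
                    "members": ",".join(d["members"]),
                    "populations": ";".join(
                        f"{k}:{v}" for k, v in sorted(d["populations"].items())
                    ),
                }
                for n, d in graph.nodes(data=True)
            ]
        )
        nodes.to_csv(ndir / "nodes.tsv", sep="\t", index=False)
        edges = pd.DataFrame(
            [
                {
                    "from": u,
                    "to": v,
                    "distance": d["weight"],
                    "support": d["support"],
                    "alternative": d["alternative"],
                }
                for u, v, d in graph.edges(data=True)
            ]
        )
        edges.to_csv(ndir / "edges.tsv", sep="\t", index=False)
        flat = graph.copy()
        for _, d in flat.nodes(data=True):
            d["members"] = ",".join(d["members"])
            d["populations"] = ";".join(
                f"{k}:{v}" for k, v in sorted(d["populations"].items())
            )
        nx.write_gml(flat, ndir / "network.gml")
        return graph

    graph = do_network()

    # ---- tree -----------------------------------------------------------------
    @_stage("tree")
    def do_tree():
        tdir = out / "tree"
        tdir.mkdir(exist_ok=True)
        alns = [per_molecule[g.name][0] for g in genomes]
        aln = alns[0] if len(alns) == 1 else concat_alignments(alns)
        nj = phylo.nj_tree(phylo.alignment_distance_matrix(aln, model="JC"))
        selection = phylo.select_model(aln, tree=nj)
        pd.DataFrame(
            [
                {
                    "model": name,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "kappa": fit.model.kappa,
                    "selected": name == selection.name,
                }
                for name, fit in selection.fits.items()
            ]
        ).to_csv(tdir / "model_selection.tsv", sep="\t", index=False)
        dist_model = "HKY" if selection.name == "HKY" else "JC"
        tree, supports = phylo.bootstrap_support(
            aln,
            n_reps=config.bootstrap_reps,
            model=dist_model,
            seed=config.seed + 2,
        )
        if config.outgroup:
            phylo.root_with_outgroup(tree, config.outgroup)
        from .io import write_newick

        write_newick(tree, tdir / "tree.nwk")
        return tree

    do_tree()

    # ---- manifest --------------------------------------------------------------
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "totals": totals,
        "n_haplotypes": graph.number_of_nodes(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
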