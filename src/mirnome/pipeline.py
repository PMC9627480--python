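"""End-to-end orchestration: build -> topology -> hubs -> enrich -> phenotype.

``run_all`` drives the five stages over the four input tables, writes every
artifact into the output directory and finishes with a run manifest
(config echo, input checksums, package version, per-stage status) so a run
is auditable even though the upstream databases it emulates are moving
targets. Defaults reproduce the study parameterization: target score
filter strictly >90, interaction confidence >=0.700, hubs on the main
component with population standard deviation and a strict threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .data_io import (
    read_annotation_table,
    read_interaction_table,
    read_phenotype_table,
    read_target_table,
    write_network,
    write_report,
)
from .enrichment import ENRICHMENT_COLUMNS, enrich
from .hubs import hub_table, identify_hubs
from .network_build import assemble_network, main_component
from .phenotype import (
    PHENOTYPE_JOIN_COLUMNS,
    classify_phenotype_terms,
    join_hubs_phenotypes,
    load_keywords,
)
from .topology import assess_hierarchy, degree_distribution, fit_power_law, topology_report

logger = logging.getLogger("mirnome")


@dataclass
class PipelineConfig:
    targets_path: str
    interactions_path: str
    annotations_path: str | None = None
    phenotypes_path: str | None = None
    outdir: str = "mirnome_out"
    min_score: float = 90.0
    min_confidence: float = 0.700
    confidence_strict: bool = False
    sample_sd: bool = False
    inclusive_hubs: bool = False
    hubs_on_full_network: bool = False
    universe: str = "network"  # "network" | "annotated" | path to a gene list
    alpha: float = 0.05
    min_term_size: int = 2
    keywords_path: str | None = None
    allow_missing_phenotypes: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        loaded.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**loaded)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk).

    Any stage failure is recorded in the manifest (``status: failed``) and
    re-raised after partial artifacts are kept; the CLI maps that to a
    nonzero exit.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mirnome",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "artifacts": [],
    }
    for key in ("targets_path", "interactions_path", "annotations_path", "phenotypes_path"):
        p = getattr(config, key)
        if p and Path(p).exists():
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    def emit(name: str) -> Path:
        path = outdir / name
        manifest["artifacts"].append(name)
        return path

    def finish(stage: str, err: Exception | None = None):
        manifest["stages"][stage] = {"status": "failed" if err else "ok"}
        if err:
            manifest["stages"][stage]["error"] = str(err)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
            raise err

    # stage 1: build ------------------------------------------------------
    try:
        targets = read_target_table(config.targets_path, min_score=config.min_score)
        interactions = read_interaction_table(
            config.interactions_path,
            min_confidence=config.min_confidence,
            strict=config.confidence_strict,
        )
        network = assemble_network(targets, interactions, label="MiRNome")
        mc, fraction = main_component(network)
        logger.info(
            "network: %d nodes, %d edges; MC: %d nodes (%.1f%%)",
            network.n_nodes, network.n_edges, mc.n_nodes, fraction,
        )
        write_network(network, emit("network_full.tsv"), format="edge_list")
        write_network(network, emit("network_full.graphml"), format="graphml")
        write_network(mc, emit("network_mc.tsv"), format="edge_list")
        finish("build")
    except Exception as err:  # noqa: BLE001 - manifest records any failure
        finish("build", err)

    # stage 2: topology ---------------------------------------------------
    try:
        report_full = topology_report(network)
        report_mc = topology_report(mc)
        write_report(report_full, emit("topology_full.json"), format="json")
        write_report(report_mc, emit("topology_mc.json"), format="json")
        fit = fit_power_law(degree_distribution(mc))
        hierarchy = assess_hierarchy(mc)
        write_report(
            {
                "gamma": fit.gamma, "r": fit.r, "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "hierarchy_slope": hierarchy.slope,
                "hierarchy_r_squared": hierarchy.r_squared,
                "hierarchical": hierarchy.verdict,
                "mc_fraction_pct": fraction,
            },
            emit("powerlaw_mc.json"),
            format="json",
        )
        finish("topology")
    except Exception as err:  # noqa: BLE001
        finish("topology", err)

    # stage 3: hubs -------------------------------------------------------
    try:
        hub_network = network if config.hubs_on_full_network else mc
        hubset = identify_hubs(
            hub_network, sample_sd=config.sample_sd, inclusive=config.inclusive_hubs
        )
        table = hub_table(hubset, network.provenance)
        table.insert(2, "mu", hubset.mu)
        table.insert(3, "sigma", hubset.sigma)
        table.insert(4, "threshold", hubset.threshold)
        table.to_csv(emit("hubs.tsv"), sep="\t", index=False)
        finish("hubs")
    except Exception as err:  # noqa: BLE001
        finish("hubs", err)

    # stage 4: enrichment -------------------------------------------------
    if config.annotations_path:
        try:
            annotations = read_annotation_table(config.annotations_path)
            if config.universe == "network":
                universe = annotations.genes() & hub_network.nodes
            elif config.universe == "annotated":
                universe = set(annotations.genes())
            else:
                universe = {
                    ln.strip() for ln in Path(config.universe).read_text().splitlines()
                    if ln.strip()
                }
            rows = enrich(
                hubset.genes, annotations, universe,
                alpha=config.alpha, min_term_size=config.min_term_size,
            )
            write_report(rows, emit("enrichment.tsv"), format="tsv",
                         columns=ENRICHMENT_COLUMNS)
            finish("enrich")
        except Exception as err:  # noqa: BLE001
            finish("enrich", err)
    else:
        manifest["stages"]["enrich"] = {"status": "skipped"}

    # stage 5: phenotype --------------------------------------------------
    if config.phenotypes_path and Path(config.phenotypes_path).exists():
        try:
            records = read_phenotype_table(config.phenotypes_path)
            keywords = load_keywords(config.keywords_path)
            records = classify_phenotype_terms(records, keywords)
            repro, embryo, both = join_hubs_phenotypes(hubset, records)
            write_report(repro, emit("phenotype_reproductive.tsv"), format="tsv",
                         columns=PHENOTYPE_JOIN_COLUMNS)
            write_report(embryo, emit("phenotype_embryo.tsv"), format="tsv",
                         columns=PHENOTYPE_JOIN_COLUMNS)
            manifest["stages"]["phenotype"] = {
                "status": "ok",
                "n_reproductive": len(repro),
                "n_embryo": len(embryo),
                "both": sorted(both),
            }
        except Exception as err:  # noqa: BLE001
            finish("phenotype", err)
    elif config.allow_missing_phenotypes or not config.phenotypes_path:
        logger.warning("phenotype table missing; stage skipped")
        manifest["stages"]["phenotype"] = {"status": "skipped"}
    else:
        finish("phenotype", FileNotFoundError(config.phenotypes_path))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
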