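"""End-to-end analysis: upload -> convert -> filter -> DE -> ORA -> subnetwork -> token.

This is the one-call composition of the individual modules, mirroring the
interactive workflow: read the expression table and design, detect and
annotate identifiers, filter by missingness, run moderated-t differential
expression for one contrast, test the significant proteins for pathway
over-representation, induce their interaction subnetwork, and emit a
reproducibility token covering every outcome-affecting setting.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

from . import diffexp, identifiers, io, network, pathways, qc, session
from .containers import ExpressionMatrix, SampleDesign


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    design: SampleDesign
    filter_report: qc.FilterReport
    de: diffexp.DEResult
    query: list[str]
    enrichment: pathways.EnrichmentResult
    subnetwork: network.InteractionNetwork
    token: str
    settings: dict
    warnings: list[str] = field(default_factory=list)


def run_pipeline(
    expression_path,
    design_path,
    annotations_path,
    relations_path,
    interactions_path,
    mapping_path=None,
    *,
    contrast_a: str = "A",
    contrast_b: str = "B",
    paired: bool = False,
    missing_cutoff: float = 0.34,
    missing_scope: str = "overall",
    query_threshold: float = 0.05,
    query_direction: str = "both",
    background_mode: str = "universe",
    min_pathway_size: int = 3,
    max_pathway_size: int = 500,
    network_score_cutoff: float = 400.0,
    id_policy: str = "first",
    species: str = "Homo sapiens",
    seed: int = 0,
    db_versions: Optional[dict[str, str]] = None,
) -> PipelineResult:
    """Run the full analysis from input files to token.

    ``background_mode`` chooses the ORA background: ``"universe"`` (all
    annotated proteins of the species) or ``"quantified"`` (proteins present
    in the filtered matrix, intersected with the universe).
    """
    warnings: list[str] = []

    dataset = io.DatasetFile.from_path(expression_path)
    matrix = io.read_expression_table(expression_path)
    design = io.read_design_table(design_path)
    if matrix.duplicates:
        warnings.append(
            f"duplicate protein identifiers kept with suffixes: "
            f"{sorted(matrix.duplicates)}"
        )

    ns, confidence = identifiers.detect_namespace(matrix.protein_ids)
    matrix.namespace = ns
    if confidence < 1.0:
        warnings.append(
            f"namespace {ns} detected with confidence {confidence:.2f}"
        )
    if mapping_path is not None:
        table = identifiers.MappingTable.from_tsv(mapping_path)
        matrix = identifiers.annotate_matrix(matrix, table, policy=id_policy)

    matrix, filter_report = qc.filter_missing(
        matrix, cutoff=missing_cutoff, scope=missing_scope,
        design=design if missing_scope == "per_group" else None,
    )

    contrast = diffexp.ContrastSpec(contrast_a, contrast_b, paired=paired)
    de = diffexp.run_differential_expression(matrix, design, contrast)
    query = diffexp.significant_proteins(
        de, threshold=query_threshold, direction=query_direction
    )

    annot = io.read_pathway_annotations(annotations_path, species=species)
    relations = io.read_pathway_relations(relations_path)
    db = pathways.PathwayDB.from_records(annot.records, relations=relations)
    background = None if background_mode == "universe" else matrix.protein_ids
    enrichment = pathways.run_ora(
        query, db, background=background,
        min_size=min_pathway_size, max_size=max_pathway_size,
    )
    warnings.extend(enrichment.warnings)

    interactions = io.read_interactions(interactions_path, score_cutoff=0.0)
    subnet = network.build_network(
        query, interactions, score_cutoff=network_score_cutoff
    )
    subnet = network.label_by_pathway(subnet, db)

    settings = session.fill_settings(
        {
            "missing_cutoff": missing_cutoff,
            "missing_scope": missing_scope,
            "contrast_a": contrast_a,
            "contrast_b": contrast_b,
            "paired": paired,
            "query_threshold": query_threshold,
            "query_direction": query_direction,
            "background_mode": background_mode,
            "min_pathway_size": min_pathway_size,
            "max_pathway_size": max_pathway_size,
            "network_score_cutoff": network_score_cutoff,
            "id_policy": id_policy,
            "seed": seed,
        }
    )
    versions = db_versions or {"pathway": db.version_tag, "interaction": "local"}
    token = session.encode_token(settings, versions, dataset.digest)

    return PipelineResult(
        matrix=matrix,
        design=design,
        filter_report=filter_report,
        de=de,
        query=query,
        enrichment=enrichment,
        subnetwork=subnet,
        token=token,
        settings=settings,
        warnings=warnings,
    )


def write_outputs(result: PipelineResult, outdir) -> dict[str, str]:
    """Write the standard output set: DE table, enrichment table, network
    files, node attributes, token and a JSON run report."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "de": os.path.join(outdir, "differential_expression.tsv"),
        "enrichment": os.path.join(outdir, "enrichment.tsv"),
        "graphml": os.path.join(outdir, "subnetwork.graphml"),
        "edges": os.path.join(outdir, "subnetwork_edges.tsv"),
        "nodes": os.path.join(outdir, "subnetwork_nodes.tsv"),
        "token": os.path.join(outdir, "session_token.txt"),
        "report": os.path.join(outdir, "report.json"),
    }
    result.de.table.to_csv(paths["de"], sep="\t", index=False)
    result.enrichment.table.to_csv(paths["enrichment"], sep="\t", index=False)
    result.subnetwork.to_graphml(paths["graphml"])
    result.subnetwork.to_edgelist_tsv(paths["edges"])
    result.subnetwork.node_table().to_csv(paths["nodes"], sep="\t", index=False)
    with open(paths["token"], "w") as fh:
        fh.write(result.token + "\n")
    stats = network.network_stats(result.subnetwork)
    report = {
        "n_proteins_kept": result.filter_report.n_kept,
        "n_proteins_removed": result.filter_report.n_removed,
        "de_prior_df": result.de.d0,
        "de_prior_variance": result.de.s0_2,
        "n_significant": len(result.query),
        "n_pathways_tested": int(len(result.enrichment.table)),
        "network_nodes": stats["n_nodes"],
        "network_edges": stats["n_edges"],
        "warnings": result.warnings,
        "settings": result.settings,
    }
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return paths
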