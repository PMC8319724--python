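"""End-to-end orchestration: counterpart mapping, phenotype enrichment,
connectivity, cross-study correlation, and synteny blocks from one config.

Every report is a TSV preceded by a commented header recording the package
version, the master seed, and the config hash, so a rerun of the same config
byte-reproduces every output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .connectivity import (
    StudyPoint,
    assess_connectivity,
    conservation_connectivity_correlation,
)
from .counterparts import assign_counterparts, read_homology_hits, tally_conservation
from .enrichment import chi_square_gof, enrichment_report
from .io import (
    read_edge_list,
    read_gene_coordinates,
    read_lookup_table,
    read_phenotype_table,
    read_risk_set,
)
from .phenotypes import PhenotypeVocabulary, tally_categories
from .synteny import block_report, evaluate_block, find_candidates

logger = logging.getLogger(__name__)


def _header_lines(config: RunConfig) -> str:
    return (
        f"# consynt {__version__}\n"
        f"# seed={config.seed}\n"
        f"# config_hash={config.config_hash}\n"
    )


def _write_report(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_header_lines(config))
        frame.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a manifest of the reports written.

    Any stage failure leaves a ``FAILED`` marker next to the partial outputs
    and re-raises.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    try:
        manifest = _run_stages(config, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n", encoding="utf-8")
        raise
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(
            {"seed": config.seed, "config_hash": config.config_hash,
             "reports": manifest},
            fh, indent=2, sort_keys=True,
        )
    return manifest


def _run_stages(config: RunConfig, out: Path) -> dict[str, str]:
    inputs = config.inputs
    manifest: dict[str, str] = {}
    vocab = (
        PhenotypeVocabulary.from_yaml(config.phenotype_vocabulary)
        if config.phenotype_vocabulary
        else PhenotypeVocabulary.default()
    )
    risk = read_risk_set(Path(inputs["risk_set"]))
    logger.info("risk set: %d genes", risk.size)

    # --- counterpart mapping and conservation enrichment (per species)
    assignments_by_species = {}
    rows = []
    cons_results = []
    for species, lookup_path in dict(inputs.get("counterparts", {})).items():
        curated = read_lookup_table(lookup_path)
        hits_path = dict(inputs.get("homology_hits", {})).get(species)
        hits = read_homology_hits(hits_path) if hits_path else []
        assignments = assign_counterparts(
            risk, curated, hits,
            thresholds=config.counterparts_params,
            target_species=species,
        )
        assignments_by_species[species] = assignments
        tally = tally_conservation(assignments)
        row = {
            "species": species,
            "with_counterpart": tally.with_counterpart,
            "total": tally.total,
            "conservation_pct": round(tally.percent, 1),
        }
        background = config.backgrounds.get("conservation", {}).get(species)
        if background:
            K, N = background
            res = chi_square_gof(
                tally.with_counterpart, tally.total, K, N,
                category=f"conservation_{species}",
                alpha=config.enrichment.alpha,
                continuity_correction=config.enrichment.continuity_correction,
            )
            cons_results.append(res)
            row.update(
                background_K=K, background_N=N,
                background_pct=round(100.0 * K / N, 1),
                chi2=res.chi2, p_value=res.p_value,
                significant=res.p_value < res.significant_at,
                direction=res.direction,
            )
        rows.append(row)
    if rows:
        _write_report(pd.DataFrame(rows), out / "conservation_report.tsv", config)
        manifest["conservation"] = "conservation_report.tsv"

    # --- phenotype categories and enrichment
    pheno_species = config.phenotype_species or next(iter(assignments_by_species), None)
    phenotype_rows = []
    if "phenotypes" in inputs and pheno_species in assignments_by_species:
        annotations = read_phenotype_table(Path(inputs["phenotypes"]))
        annotated_ids = {a.gene_id for a in annotations}
        subset = [
            a.human_gene
            for a in assignments_by_species[pheno_species]
            if a.has_counterpart and a.human_gene in annotated_ids
        ]
        counts = tally_categories(annotations, subset, vocabulary=vocab)
        results = []
        for category, (K, N) in config.backgrounds.get("phenotypes", {}).items():
            cc = counts.get(category)
            if cc is None:
                continue
            results.append(
                chi_square_gof(
                    cc.k, cc.n, K, N, category=category,
                    alpha=config.enrichment.alpha,
                    continuity_correction=config.enrichment.continuity_correction,
                )
            )
        if results:
            frame = enrichment_report(results)
            _write_report(frame, out / "phenotype_report.tsv", config)
            manifest["phenotypes"] = "phenotype_report.tsv"
        phenotype_rows = [
            {"category": c.category, "k": c.k, "n": c.n,
             "fraction": round(c.fraction, 4)}
            for c in counts.values()
        ]
        _write_report(
            pd.DataFrame(phenotype_rows), out / "phenotype_counts.tsv", config
        )

    # --- network connectivity
    connectivity_result = None
    if "edge_list" in inputs:
        graph = read_edge_list(Path(inputs["edge_list"]))
        if "gene_universe" in inputs:
            universe_frame = pd.read_csv(Path(inputs["gene_universe"]), sep="\t")
            universe = sorted(
                set(universe_frame.iloc[:, 0].astype(str)) | graph.nodes
            )
        else:
            universe = sorted(graph.nodes)
        connectivity_result = assess_connectivity(
            graph, risk, universe,
            n_sets=config.connectivity.n_sets,
            cutoff_sd=config.connectivity.cutoff_sd,
            seed=config.seed,
            denominator=config.connectivity.denominator,
        )
        r = connectivity_result
        frame = pd.DataFrame(
            [{
                "set_label": r.set_label, "n_genes": r.n_genes,
                "within_edges": r.within_edges,
                "links_per_gene": round(r.links_per_gene, 4),
                "null_sets": r.null_sets,
                "null_mean": round(r.null_mean, 4),
                "null_sd": round(r.null_sd, 4),
                "cutoff_sd": r.cutoff_sd, "ci_bound": round(r.ci_bound, 4),
                "significant": r.significant, "seed": r.seed,
            }]
        )
        _write_report(frame, out / "connectivity_report.tsv", config)
        audit = pd.DataFrame(
            {"null_set": range(1, len(r.null_values) + 1),
             "links_per_gene": [round(x, 4) for x in r.null_values]}
        )
        _write_report(audit, out / "connectivity_null_audit.tsv", config)
        manifest["connectivity"] = "connectivity_report.tsv"

    # --- cross-study conservation/connectivity correlation
    if config.studies and connectivity_result is not None:
        corr_species = config.correlation_species or pheno_species
        points = [
            StudyPoint(s["label"], float(s["conservation_pct"]),
                       float(s["links_per_gene"]))
            for s in config.studies
        ]
        if corr_species in assignments_by_species:
            tally = tally_conservation(assignments_by_species[corr_species])
            # studies plot integer-rounded conservation percentages
            points.append(
                StudyPoint("this_study", round(tally.percent),
                           connectivity_result.links_per_gene)
            )
        points.sort(key=lambda p: p.conservation_pct)
        r2dp, r_full = conservation_connectivity_correlation(points)
        frame = pd.DataFrame(
            [{"n_studies": len(points), "pearson_r": r2dp,
              "pearson_r_full": r_full}]
        )
        _write_report(frame, out / "correlation_report.tsv", config)
        pts = pd.DataFrame(
            [{"study": p.study_label, "conservation_pct": p.conservation_pct,
              "links_per_gene": round(p.links_per_gene, 4)} for p in points]
        )
        _write_report(pts, out / "correlation_points.tsv", config)
        manifest["correlation"] = "correlation_report.tsv"

    # --- synteny blocks
    secondary_species = config.synteny_secondary_species
    if (
        "coordinates_primary" in inputs
        and "coordinates_secondary" in inputs
        and secondary_species in assignments_by_species
    ):
        fmt = inputs.get("coordinates_format", "BED6")
        primary = read_gene_coordinates(Path(inputs["coordinates_primary"]), fmt)
        secondary = read_gene_coordinates(Path(inputs["coordinates_secondary"]), fmt)
        risk_members = set(risk.members)
        risk_coords = [r for r in primary if r.gene_id in risk_members]
        candidates = find_candidates(
            risk_coords, config.synteny.max_gap_bp, config.synteny.min_genes
        )
        annotations = (
            read_phenotype_table(Path(inputs["phenotypes"]))
            if "phenotypes" in inputs
            else []
        )
        blocks = [
            evaluate_block(
                c, assignments_by_species[secondary_species], secondary,
                annotations, config.synteny, vocabulary=vocab,
            )
            for c in candidates
        ]
        block_report(
            blocks,
            path=out / "synteny_blocks.tsv",
            audit_path=out / "synteny_audit.tsv",
        )
        manifest["synteny"] = "synteny_blocks.tsv"

    return manifest
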