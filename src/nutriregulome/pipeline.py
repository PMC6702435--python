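"""End-to-end pipeline runner with a provenance manifest.

Stages run in order: markers -> mr -> extract -> modules -> signature ->
regulators -> correlate (the last only when TF perturbation DEG lists are
supplied).  Each stage writes its table into the run directory; the
manifest records the configuration, input checksums, and per-stage row
counts.  Reruns with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as nio
from .config import PipelineConfig
from .errors import NutriregulomeError
from .markers import select_markers
from .mutual_rank import correlation_matrix, mutual_rank
from .network import extract_network
from .partition import find_modules, subgroup_giant
from .regulators import classify_regulators, map_regulators
from .regulome import prediction_overlap, regulome_profile, signature_correlation
from .regulators import target_sets
from .signatures import signature_matrix

logger = logging.getLogger(__name__)

STAGES = ("markers", "mr", "extract", "modules", "signature", "regulators", "correlate")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    expression_path,
    deg_path,
    evidence_path,
    outdir,
    tf_deg_dir=None,
) -> dict:
    """Run every stage on on-disk inputs and return the manifest.

    Parameters
    ----------
    config : PipelineConfig
    expression_path, deg_path, evidence_path
        Expression matrix TSV, tidy DEG table TSV, TF evidence TSV.
    outdir
        Run directory; stage outputs land here (created if needed).
    tf_deg_dir
        Optional directory of per-TF perturbation DEG TSVs
        (``<TF>.tsv`` with columns gene, direction); enables the
        correlate stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "expression": Path(expression_path),
        "deg": Path(deg_path),
        "evidence": Path(evidence_path),
    }
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {k: {"path": str(p), "sha256": _checksum(p)} for k, p in inputs.items()},
        "stages": {},
    }

    stage = "markers"
    try:
        deg = nio.read_deg_tables(deg_path)
        markers = select_markers(deg, config.min_studies, config.min_fraction_consistent)
        nio.write_markers(markers, outdir / "markers.tsv")
        manifest["stages"][stage] = {"rows": len(markers)}
        logger.info("markers: %d records selected", len(markers))

        stage = "mr"
        expr = nio.read_expression(expression_path)
        corr = correlation_matrix(expr)
        mr = mutual_rank(corr)
        nio.write_mr_table(mr[mr["mr"] <= config.mr_max], outdir / "mr.tsv")
        manifest["stages"][stage] = {"rows": int((mr["mr"] <= config.mr_max).sum())}

        stage = "extract"
        net = extract_network(
            mr, markers, mr_max=config.mr_max, tier_depth=config.tier_depth,
            gene_universe=corr.index,
        )
        nio.write_network(net, outdir / "network.graphml")
        nio.write_edge_list(net, outdir / "edges.tsv")
        manifest["stages"][stage] = {
            "nodes": net.number_of_nodes(), "edges": net.number_of_edges(),
        }

        stage = "modules"
        partition = find_modules(net, config.min_module_size)
        partition = subgroup_giant(net, partition)
        nio.write_partition(partition, outdir / "partition.tsv")
        manifest["stages"][stage] = {"units": len(partition.units)}

        stage = "signature"
        sig = signature_matrix(partition, markers, config.ambiguity_fraction)
        nio.write_signature(sig, outdir / "signature.tsv")
        manifest["stages"][stage] = {
            "cells": sig.attrs["n_cells"], "ambiguous": sig.attrs["n_ambiguous"],
        }

        stage = "regulators"
        evidence = nio.read_evidence(evidence_path)
        regmap = map_regulators(evidence, partition, motif_alpha=config.motif_alpha)
        nio.write_regmap(regmap, outdir / "regmap.tsv")
        summary = classify_regulators(
            regmap,
            n_analyzed_units=len(partition.analyzed_units),
            general_fraction=config.general_fraction,
            network_genes=partition.gene_universe,
            marker_genes=set(markers["gene"]),
        )
        manifest["stages"][stage] = {
            "records": len(regmap),
            "tfs": summary.n_tfs,
            "general_threshold": summary.general_threshold,
            "general_tfs": summary.general_tfs,
        }

        stage = "correlate"
        if tf_deg_dir is not None:
            predicted = target_sets(regmap)
            reports, overlaps = [], []
            for path in sorted(Path(tf_deg_dir).glob("*.tsv")):
                tf = path.stem
                deg_list = pd.read_csv(path, sep="\t", dtype={"gene": str})
                profile = regulome_profile(deg_list, partition, tf=tf,
                                           ambiguity_fraction=config.ambiguity_fraction)
                ov = prediction_overlap(profile, predicted.get(tf, set()))
                overlaps.append((tf, ov.n_regulated, ov.n_overlap, ov.percent))
                reports.append(signature_correlation(profile, sig, config.correlation_band))
            corr_report = pd.concat(reports, ignore_index=True)
            nio.write_correlation_report(corr_report, outdir / "correlation.tsv")
            overlap_df = pd.DataFrame(
                overlaps, columns=["tf", "n_regulated", "n_overlap", "overlap_pct"]
            )
            overlap_df.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "tfs": len(overlaps),
                "considered": int(corr_report["considered"].sum()),
            }
        else:
            manifest["stages"][stage] = {"skipped": True}
    except NutriregulomeError as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise NutriregulomeError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
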