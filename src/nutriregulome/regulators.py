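"""Mapping transcription factors to target response units.

A TF targets a unit when any of three evidence criteria holds:

1. a literature record links the TF to at least one member gene;
2. a ChIP-seq record does;
3. the TF's motif-carrying genes are over-represented in the unit —
   upper-tail hypergeometric test against the network gene universe,
   Benjamini-Hochberg adjusted across all (TF, unit) motif tests, at a
   stringent default threshold (adjusted p < 1e-3), standing in for an
   "extremely high" binding-site prediction score at module level.

Only units of at least ``min_module_size`` genes are analyzed and the
pooled "rest" unit is excluded.  A TF is a *general* regulator when it
targets more than ``general_fraction`` (default 10%) of the analyzed
units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .partition import ModulePartition

logger = logging.getLogger(__name__)

EVIDENCE_BASES = ("literature", "chipseq", "motif_enrichment")
REGMAP_COLUMNS = ["tf", "unit", "evidence", "score"]


def motif_module_enrichment(tf_motif_genes, unit, universe) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p-value.

    Probability of drawing at least the observed number of motif-carrying
    genes when ``|unit|`` genes are drawn without replacement from a
    universe containing ``|motif genes|`` successes.
    """
    universe = set(universe)
    unit = set(unit)
    if not unit or not universe:
        raise ValidationError("motif_module_enrichment: empty unit or universe")
    if not unit <= universe:
        raise ValidationError("motif_module_enrichment: unit must be a subset of the universe")
    motif = set(tf_motif_genes) & universe
    overlap = len(motif & unit)
    # P(X >= overlap), X ~ Hypergeom(N=|universe|, K=|motif|, n=|unit|)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(motif), len(unit)))
    return overlap, min(p, 1.0)


def map_regulators(
    evidence: pd.DataFrame,
    partition: ModulePartition,
    motif_alpha: float = 1e-3,
    evidence_classes=("literature", "chipseq", "motif"),
) -> pd.DataFrame:
    """Build the TF -> unit regulator map from an evidence table.

    ``evidence`` has columns ``tf, gene, evidence_class`` with classes in
    {literature, chipseq, motif}.  Literature/ChIP-seq records map a TF to
    every analyzed unit containing a linked gene; motif records are tested
    for unit-level enrichment (BH-adjusted hypergeometric, threshold
    ``motif_alpha``).  ``evidence_classes`` restricts which classes are
    used (dropping a class can only remove targets).

    Returns a table with columns ``tf, unit, evidence, score`` (score =
    BH-adjusted p for motif_enrichment rows, NaN otherwise), one row per
    (tf, unit, evidence basis).
    """
    missing = [c for c in ("tf", "gene", "evidence_class") if c not in evidence.columns]
    if missing:
        raise ValidationError(f"evidence table missing columns: {missing}")
    unknown = set(evidence["evidence_class"]) - {"literature", "chipseq", "motif"}
    if unknown:
        raise ValidationError(f"unknown evidence class label(s): {sorted(unknown)}")

    analyzed = partition.analyzed_units
    universe = partition.gene_universe
    unit_sets = {u: set(partition.units[u]) for u in analyzed}

    records: list[tuple[str, str, str, float]] = []
    for cls in ("literature", "chipseq"):
        if cls not in evidence_classes:
            continue
        sub = evidence[evidence["evidence_class"] == cls]
        sub = sub[sub["gene"].isin(universe)]
        for tf, genes in sub.groupby("tf")["gene"]:
            gene_set = set(genes)
            for u in analyzed:
                if gene_set & unit_sets[u]:
                    records.append((tf, u, cls, float("nan")))

    if "motif" in evidence_classes:
        motif = evidence[evidence["evidence_class"] == "motif"]
        tests: list[tuple[str, str, float]] = []
        for tf, genes in motif.groupby("tf")["gene"]:
            motif_set = set(genes) & universe
            if not motif_set:
                continue
            for u in analyzed:
                _, p = motif_module_enrichment(motif_set, unit_sets[u], universe)
                tests.append((tf, u, p))
        if tests:
            pvals = [t[2] for t in tests]
            _, adj, _, _ = multipletests(pvals, method="fdr_bh")
            for (tf, u, _), q in zip(tests, adj):
                if q < motif_alpha:
                    records.append((tf, u, "motif_enrichment", float(q)))

    out = pd.DataFrame(records, columns=REGMAP_COLUMNS)
    out = out.drop_duplicates(subset=["tf", "unit", "evidence"])
    return out.sort_values(["tf", "unit", "evidence"], ignore_index=True)


def target_sets(regmap: pd.DataFrame) -> dict[str, set]:
    """TF -> set of target units from a regulator map."""
    return {tf: set(sub["unit"]) for tf, sub in regmap.groupby("tf")}


def general_regulator_threshold(n_analyzed_units: int, general_fraction: float = 0.10) -> int:
    """Smallest integer target count strictly greater than
    ``general_fraction * n_analyzed_units`` (e.g. 54 units at 10% -> 6)."""
    if n_analyzed_units < 1:
        raise ValidationError("n_analyzed_units must be >= 1")
    return math.floor(general_fraction * n_analyzed_units) + 1


@dataclass
class RegulatorSummary:
    """Counts describing a regulator map."""

    n_tfs: int
    n_multi_target: int
    general_threshold: int
    general_tfs: list
    n_in_network: int
    n_network_markers: int
    per_tf_targets: dict


def classify_regulators(
    regmap: pd.DataFrame,
    n_analyzed_units: int,
    general_fraction: float = 0.10,
    network_genes=None,
    marker_genes=None,
    tf_gene_map: dict | None = None,
) -> RegulatorSummary:
    """Classify mapped TFs as general vs specialized and count flags.

    A TF is general when its target-unit count reaches the threshold from
    :func:`general_regulator_threshold`.  ``tf_gene_map`` (TF id -> gene
    id; identity when omitted) lets the TF's own gene be checked for
    network membership and marker status.
    """
    targets = target_sets(regmap)
    threshold = general_regulator_threshold(n_analyzed_units, general_fraction)
    general = sorted(tf for tf, t in targets.items() if len(t) >= threshold)
    network_genes = set(network_genes or ())
    marker_genes = set(marker_genes or ())
    gene_of = tf_gene_map or {}
    in_net = [tf for tf in targets if gene_of.get(tf, tf) in network_genes]
    as_marker = [tf for tf in in_net if gene_of.get(tf, tf) in marker_genes]
    return RegulatorSummary(
        n_tfs=len(targets),
        n_multi_target=sum(1 for t in targets.values() if len(t) >= 2),
        general_threshold=threshold,
        general_tfs=general,
        n_in_network=len(in_net),
        n_network_markers=len(as_marker),
        per_tf_targets={tf: sorted(t) for tf, t in sorted(targets.items())},
    )


def summarize_families(tf_family_table: pd.DataFrame, regmap: pd.DataFrame) -> pd.Series:
    """Mapped-regulator counts per protein family, sorted descending.

    TFs missing from the family table are counted under "unassigned" with
    a warning.
    """
    mapped = sorted(set(regmap["tf"]))
    if not mapped:
        return pd.Series(dtype=int, name="n_regulators")
    fam = dict(tf_family_table[["tf", "family"]].itertuples(index=False))
    unassigned = [tf for tf in mapped if tf not in fam]
    if unassigned:
        logger.warning("%d mapped TF(s) missing from the family table", len(unassigned))
    counts = pd.Series(
        [fam.get(tf, "unassigned") for tf in mapped], name="n_regulators"
    ).value_counts()
    counts = counts.sort_values(ascending=False)
    counts.index.name = "family"
    return counts
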