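"""Recovery metrics against the planted ground truth.

Used by the analysis drivers and the acceptance checks to quantify how
well each pipeline stage recovers the structure the synthetic compendium
planted: marker sensitivity and false rate, partition Jaccard against the
planted modules, response-direction accuracy, and TF target-set
precision/recall.  Planted modules that received no markers (no condition
regulates them) are invisible to a marker-seeded network by construction,
so module-level metrics are computed over the seeded (responsive) planted
modules.
"""

from __future__ import annotations

import pandas as pd

from .partition import ModulePartition
from .simulate import GroundTruth


def marker_recovery(markers: pd.DataFrame, truth: GroundTruth) -> dict:
    """Sensitivity and false rate of selected (gene, condition, direction)
    records against the planted markers."""
    planted = truth.marker_records()
    selected = {
        (g, c, d)
        for g, c, d in markers[["gene", "condition", "direction"]].itertuples(index=False)
    }
    tp = selected & planted
    return {
        "n_planted": len(planted),
        "n_selected": len(selected),
        "sensitivity": len(tp) / len(planted) if planted else float("nan"),
        "false_rate": (len(selected - planted) / len(selected)) if selected else 0.0,
    }


def match_units(partition: ModulePartition, truth: GroundTruth) -> dict:
    """unit id -> planted module with the largest member overlap
    ("background" when background genes dominate)."""
    out = {}
    for unit, genes in partition.units.items():
        tally: dict[str, int] = {}
        for g in genes:
            m = truth.gene_module.get(g, "background")
            tally[m] = tally.get(m, 0) + 1
        out[unit] = max(sorted(tally), key=lambda m: tally[m])
    return out


def partition_jaccard(partition: ModulePartition, truth: GroundTruth) -> dict:
    """Mean best-match Jaccard index between each seeded planted module
    and the recovered units.

    Like any partition-vs-labels comparison (ARI, NMI), the score is
    defined on a common element universe: each planted module is
    restricted to its members present in the network before matching, so
    the score isolates partition quality (are a module's recovered genes
    kept together and unmixed?) from network recall, which is reported
    separately as ``gene_recall``.
    """
    seeded = sorted(truth.responsive_modules)
    universe = partition.gene_universe
    unit_sets = {u: set(g) for u, g in partition.units.items()}
    per_module = {}
    n_members = n_recovered = 0
    for mod in seeded:
        members = set(truth.module_genes(mod))
        n_members += len(members)
        present = members & universe
        n_recovered += len(present)
        if not present:
            per_module[mod] = 0.0
            continue
        per_module[mod] = max(
            len(present & s) / len(present | s) for s in unit_sets.values()
        )
    mean = sum(per_module.values()) / len(per_module) if per_module else float("nan")
    return {
        "per_module": per_module,
        "mean_jaccard": mean,
        "gene_recall": n_recovered / n_members if n_members else float("nan"),
    }


def response_recovery(sig: pd.DataFrame, partition: ModulePartition, truth: GroundTruth) -> dict:
    """Fraction of planted (module, condition, direction) responses whose
    best-matching unit was called in the planted direction."""
    unit_to_mod = match_units(partition, truth)
    mod_to_unit: dict[str, str] = {}
    for unit, mod in unit_to_mod.items():
        if mod == "background":
            continue
        # prefer the unit holding more of the module's genes
        held = len(set(truth.module_genes(mod)) & set(partition.units[unit]))
        prev = mod_to_unit.get(mod)
        if prev is None or held > len(set(truth.module_genes(mod)) & set(partition.units[prev])):
            mod_to_unit[mod] = unit
    status = {(u, c): s for u, c, s in sig[["unit", "condition", "status"]].itertuples(index=False)}
    total = correct = 0
    misses = []
    for cond, responses in truth.response_map.items():
        for mod, direction in responses:
            total += 1
            unit = mod_to_unit.get(mod)
            if unit is not None and status.get((unit, cond)) == direction:
                correct += 1
            else:
                misses.append((mod, cond, direction, unit))
    return {
        "n_planted": total,
        "n_correct": correct,
        "accuracy": correct / total if total else float("nan"),
        "misses": misses,
    }


def tf_mapping_scores(regmap: pd.DataFrame, partition: ModulePartition, truth: GroundTruth) -> dict:
    """Micro-averaged precision/recall of predicted TF target modules.

    Predicted units are translated to planted modules via best-overlap
    matching; truth is restricted to seeded planted modules (unseeded
    modules cannot appear in the network).
    """
    unit_to_mod = match_units(partition, truth)
    seeded = truth.responsive_modules
    true_pairs = {
        (tf, mod)
        for tf, targets in truth.tf_targets.items()
        for mod in targets
        if mod in seeded
    }
    pred_pairs = {
        (tf, unit_to_mod[unit])
        for tf, unit in regmap[["tf", "unit"]].drop_duplicates().itertuples(index=False)
        if unit_to_mod.get(unit, "background") != "background"
    }
    tp = len(true_pairs & pred_pairs)
    return {
        "n_true": len(true_pairs),
        "n_predicted": len(pred_pairs),
        "precision": tp / len(pred_pairs) if pred_pairs else float("nan"),
        "recall": tp / len(true_pairs) if true_pairs else float("nan"),
    }
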