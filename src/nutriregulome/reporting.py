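"""Summary arithmetic and narrative reporting helpers.

The paper-style summary sentences ("N genes (P%) fell in M modules of at
least four genes", "K of the mapped regulators target at least two
modules") are all shares of small integer tallies; the helpers here make
those computations explicit and testable.
"""

from __future__ import annotations

from .errors import ValidationError
from .partition import ModulePartition


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """``100 * part / whole`` rounded to ``ndigits`` (as printed in
    summary sentences)."""
    if whole == 0:
        raise ValidationError("percentage: whole must be non-zero")
    return round(100.0 * part / whole, ndigits)


def partition_report(partition: ModulePartition) -> dict:
    """Headline counts of a module partition.

    Returns total genes, the giant group's size and share, the number of
    non-giant modules and their gene count/share, the rest size, and a
    conservation total (sum of the three groups, which must equal the
    node count).
    """
    giant_units = [u for u, k in partition.kinds.items() if k in ("giant", "giant_subgroup")]
    module_units = [u for u, k in partition.kinds.items() if k == "module"]
    n_giant = sum(len(partition.units[u]) for u in giant_units)
    n_modules = sum(len(partition.units[u]) for u in module_units)
    n_rest = len(partition.units.get("rest", ()))
    total = n_giant + n_modules + n_rest
    return {
        "n_genes": total,
        "giant_genes": n_giant,
        "giant_pct": percentage(n_giant, total),
        "n_giant_subgroups": sum(1 for u in giant_units if partition.kinds[u] == "giant_subgroup"),
        "n_modules": len(module_units),
        "module_genes": n_modules,
        "module_pct": percentage(n_modules, total),
        "rest_genes": n_rest,
        "conservation_total": total,
    }


def network_sentence(report: dict) -> str:
    return (
        f"{report['n_genes']} genes: {report['giant_genes']} "
        f"({report['giant_pct']}%) in the giant group, {report['module_genes']} "
        f"({report['module_pct']}%) in {report['n_modules']} modules of at least "
        f"four genes, {report['rest_genes']} in smaller components."
    )
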