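"""Condition-specific marker genes by cross-study consistency.

A gene is a marker for a condition when independent studies of that
condition call it differentially expressed in the same direction often
enough: at least ``min_studies`` supporting calls, and at least
``min_fraction_consistent`` of all its calls for the condition agreeing
with that direction.  With the defaults (2, 1.0) a single opposite call
vetoes the gene, which is the strict reading of "consistent response in
independent studies".
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["study", "condition", "gene", "direction", "effect", "p_value"]
MARKER_COLUMNS = ["gene", "condition", "direction", "n_studies"]


def select_markers(
    deg_tables: pd.DataFrame,
    min_studies: int = 2,
    min_fraction_consistent: float = 1.0,
) -> pd.DataFrame:
    """Select markers from tidy per-study DEG calls.

    Parameters
    ----------
    deg_tables
        Tidy table with at least ``study, condition, gene, direction``
        (one row per significant call in one study).
    min_studies
        Minimum number of studies calling the gene in the winning
        direction.
    min_fraction_consistent
        Minimum fraction of the gene's calls (within the condition) that
        must agree with the winning direction.  Ties between directions
        never yield a marker.

    Returns
    -------
    DataFrame with columns ``gene, condition, direction, n_studies``,
    sorted by (condition, gene).
    """
    if min_studies < 1:
        raise ValidationError("min_studies must be >= 1")
    missing = [c for c in ("study", "condition", "gene", "direction") if c not in deg_tables.columns]
    if missing:
        raise ValidationError(f"DEG table missing columns: {missing}")

    dup = deg_tables.groupby(["study", "condition", "gene"])["direction"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index[0]
        raise ValidationError(
            f"conflicting duplicate rows within one study table: study={bad[0]!r}, "
            f"condition={bad[1]!r}, gene={bad[2]!r}"
        )
    # collapse exact duplicates so a study contributes one call per gene
    calls = deg_tables[["study", "condition", "gene", "direction"]].drop_duplicates()

    records = []
    counts = (
        calls.groupby(["condition", "gene", "direction"])
        .size()
        .unstack("direction", fill_value=0)
    )
    for d in ("up", "down"):
        if d not in counts.columns:
            counts[d] = 0
    for (condition, gene), row in counts.iterrows():
        n_up, n_down = int(row["up"]), int(row["down"])
        if n_up == n_down:
            continue  # tie -> not a marker
        direction = "up" if n_up > n_down else "down"
        n_win = max(n_up, n_down)
        if n_win < min_studies:
            continue
        if n_win / (n_up + n_down) < min_fraction_consistent:
            continue
        records.append((gene, condition, direction, n_win))

    out = pd.DataFrame(records, columns=MARKER_COLUMNS)
    return out.sort_values(["condition", "gene"], ignore_index=True)


def marker_overlap(markers: pd.DataFrame) -> dict:
    """Summarise marker sharing between conditions.

    Returns a dict with:

    - ``matrix``: symmetric condition x condition shared-gene count table
      (diagonal = set sizes),
    - ``unique``: per-condition count of genes in exactly one set,
    - ``shared_ge2`` / ``shared_ge3``: genes in >= 2 / >= 3 condition sets,
    - ``max_sharing_genes``: the gene(s) in the most sets, and
      ``max_sharing``: that count.
    """
    if markers.empty:
        raise ValidationError("marker_overlap: empty marker set")
    sets = {c: set(g["gene"]) for c, g in markers.groupby("condition")}
    conditions = sorted(sets)
    matrix = pd.DataFrame(0, index=conditions, columns=conditions, dtype=int)
    for a in conditions:
        for b in conditions:
            matrix.loc[a, b] = len(sets[a] & sets[b])

    membership = markers.groupby("gene")["condition"].nunique()
    unique = {
        c: int(sum(1 for g in sets[c] if membership[g] == 1)) for c in conditions
    }
    max_sharing = int(membership.max())
    return {
        "matrix": matrix,
        "unique": unique,
        "shared_ge2": int((membership >= 2).sum()),
        "shared_ge3": int((membership >= 3).sum()),
        "max_sharing": max_sharing,
        "max_sharing_genes": sorted(membership[membership == max_sharing].index),
    }
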