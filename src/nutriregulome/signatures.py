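"""Per-unit, per-condition response status calls and signature clustering.

A unit's status under a condition is called from the marker genes it
contains: "none" when no marker of the condition is a member, "ambiguous"
when up- and down-regulated marker counts differ by less than 50% of the
larger count, otherwise the majority direction.  The ambiguity rule is
formalised as ``|n_up - n_down| / max(n_up, n_down) < 0.5`` with an
exclusive boundary, so (6, 0) is decisive, (3, 2) is ambiguous, and
(2, 1) is called up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .partition import ModulePartition

logger = logging.getLogger(__name__)

STATUS_ENCODING = {"up": 1.0, "down": -1.0, "none": 0.0, "ambiguous": 0.0}
SIGNATURE_COLUMNS = ["unit", "condition", "status", "n_up", "n_down"]


def call_status(n_up: int, n_down: int, ambiguity_fraction: float = 0.5) -> str:
    """Status of a unit-condition cell from marker counts.

    Pure function: "none" if both counts are zero; "ambiguous" if the
    relative difference ``|n_up - n_down| / max(n_up, n_down)`` is below
    ``ambiguity_fraction``; else the majority direction.
    """
    if n_up < 0 or n_down < 0:
        raise ValidationError("call_status: counts must be >= 0")
    if n_up == 0 and n_down == 0:
        return "none"
    if abs(n_up - n_down) / max(n_up, n_down) < ambiguity_fraction:
        return "ambiguous"
    return "up" if n_up > n_down else "down"


def signature_matrix(
    partition: ModulePartition,
    markers: pd.DataFrame,
    ambiguity_fraction: float = 0.5,
) -> pd.DataFrame:
    """Status call for every (unit, condition) cell.

    ``markers`` is a marker table with columns ``gene, condition,
    direction``.  Markers absent from the network are dropped with a
    logged count.  Returns a tidy table with columns
    ``unit, condition, status, n_up, n_down`` covering every unit x
    condition cell exactly once, plus summary attrs ``n_cells`` and
    ``n_ambiguous``.
    """
    if not partition.units:
        raise ValidationError("signature_matrix: empty partition")
    if markers.empty:
        raise ValidationError("signature_matrix: empty marker set")
    universe = partition.gene_universe
    inside = markers[markers["gene"].isin(universe)]
    dropped = len(markers) - len(inside)
    if dropped:
        logger.info("signature_matrix: %d marker record(s) outside the network", dropped)

    unit_of = partition.unit_of()
    conditions = sorted(markers["condition"].unique())
    counts: dict[tuple[str, str], list[int]] = {}
    for gene, condition, direction in inside[["gene", "condition", "direction"]].itertuples(index=False):
        key = (unit_of[gene], condition)
        cell = counts.setdefault(key, [0, 0])
        cell[0 if direction == "up" else 1] += 1

    rows = []
    for unit in partition.unit_ids:
        for condition in conditions:
            n_up, n_down = counts.get((unit, condition), (0, 0))
            rows.append((unit, condition, call_status(n_up, n_down, ambiguity_fraction), n_up, n_down))
    sig = pd.DataFrame(rows, columns=SIGNATURE_COLUMNS)
    sig.attrs["n_cells"] = len(sig)
    sig.attrs["n_ambiguous"] = int((sig["status"] == "ambiguous").sum())
    sig.attrs["n_dropped_markers"] = int(dropped)
    return sig


def encode_signature(sig: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy signature table to a unit x condition matrix of
    {+1, -1, 0} (up / down / no regulation)."""
    wide = sig.pivot(index="unit", columns="condition", values="status")
    return wide.apply(lambda col: col.map(STATUS_ENCODING)).astype(float)


@dataclass
class SignatureClustering:
    """Row/column dendrograms and leaf orders of an encoded signature."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def _ordered_leaves(matrix: np.ndarray, labels: list) -> tuple[list, np.ndarray | None]:
    if matrix.shape[0] < 2:
        return list(labels), None
    link = hierarchy.linkage(pdist(matrix, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(link)
    return [labels[i] for i in leaves], link


def cluster_signature(sig: pd.DataFrame) -> SignatureClustering:
    """Agglomerative clustering (average linkage, Euclidean) of the
    encoded signature matrix, over both units and conditions.

    Statuses encode as up = +1, down = -1, none/ambiguous = 0.  An
    all-zero matrix cannot be clustered meaningfully and is returned in
    input order with a warning.
    """
    wide = encode_signature(sig)
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValidationError("cluster_signature: need >= 2 units and >= 2 conditions")
    # stable tie-breaking: pre-sort labels so equal rows keep id order
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    if not wide.values.any():
        logger.warning("cluster_signature: all-zero signature matrix; clustering skipped")
        return SignatureClustering(list(wide.index), list(wide.columns), None, None)
    row_order, row_link = _ordered_leaves(wide.values, list(wide.index))
    col_order, col_link = _ordered_leaves(wide.values.T, list(wide.columns))
    return SignatureClustering(row_order, col_order, row_link, col_link)
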