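"""TF regulomes: perturbation DEG lists mapped onto the network.

A TF's *regulome profile* is the vector of per-unit statuses obtained by
counting its perturbation-responsive genes inside each unit and applying
the same majority/ambiguity rule used for condition signatures.  The
profile is compared with (a) the TF's predicted binding targets
(prediction-observation overlap) and (b) each condition's stress
signature (Pearson correlation over the encoded unit vectors, with a
reporting band of |r| < 0.24 treated as non-informative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .partition import ModulePartition
from .signatures import STATUS_ENCODING, call_status, encode_signature

logger = logging.getLogger(__name__)


@dataclass
class RegulomeProfile:
    """Per-unit status vector of one TF's perturbation response."""

    tf: str
    status: pd.Series  # unit -> {up, down, none, ambiguous}
    counts: pd.DataFrame  # unit x {n_up, n_down}
    n_de_genes: int
    n_dropped: int

    def encoded(self) -> pd.Series:
        return self.status.map(STATUS_ENCODING).astype(float)

    @property
    def regulated_units(self) -> set:
        return set(self.status.index[self.status.isin(["up", "down"])])


def regulome_profile(
    deg_list: pd.DataFrame,
    partition: ModulePartition,
    tf: str = "TF",
    ambiguity_fraction: float = 0.5,
) -> RegulomeProfile:
    """Map a TF perturbation DEG list onto the partition's units.

    ``deg_list`` needs columns ``gene, direction``.  Genes outside the
    network are dropped with a logged count; an empty list is an error
    (too small a perturbation experiment to profile).
    """
    if deg_list.empty:
        raise ValidationError(f"regulome_profile: empty DEG list for {tf}")
    missing = [c for c in ("gene", "direction") if c not in deg_list.columns]
    if missing:
        raise ValidationError(f"DEG list missing columns: {missing}")
    bad = set(deg_list["direction"]) - {"up", "down"}
    if bad:
        raise ValidationError(f"unknown direction token(s): {sorted(bad)}")

    unit_of = partition.unit_of()
    inside = deg_list[deg_list["gene"].isin(unit_of)]
    n_dropped = len(deg_list) - len(inside)
    if n_dropped:
        logger.info("regulome_profile(%s): %d DEG(s) outside the network", tf, n_dropped)

    counts = pd.DataFrame(0, index=partition.unit_ids, columns=["n_up", "n_down"])
    for gene, direction in inside[["gene", "direction"]].itertuples(index=False):
        counts.loc[unit_of[gene], "n_up" if direction == "up" else "n_down"] += 1
    status = pd.Series(
        [
            call_status(int(r["n_up"]), int(r["n_down"]), ambiguity_fraction)
            for _, r in counts.iterrows()
        ],
        index=counts.index,
        name=tf,
    )
    return RegulomeProfile(
        tf=tf, status=status, counts=counts,
        n_de_genes=len(deg_list), n_dropped=n_dropped,
    )


@dataclass
class OverlapResult:
    """Prediction-observation overlap of one TF."""

    tf: str
    n_regulated: int
    n_overlap: int
    percent: float | None  # None when no unit is differentially regulated

    @property
    def defined(self) -> bool:
        return self.percent is not None


def prediction_overlap(profile: RegulomeProfile, predicted) -> OverlapResult:
    """Fraction of the TF's differentially regulated units that were
    predicted binding targets, as a percentage.

    Undefined (flagged, not 0) when the profile regulates no unit.
    """
    predicted = set(predicted)
    regulated = profile.regulated_units
    if not regulated:
        logger.warning("prediction_overlap(%s): no differentially regulated units", profile.tf)
        return OverlapResult(profile.tf, 0, 0, None)
    overlap = len(regulated & predicted)
    return OverlapResult(
        profile.tf, len(regulated), overlap, 100.0 * overlap / len(regulated)
    )


def signature_correlation(
    profile: RegulomeProfile,
    sig: pd.DataFrame,
    band: float = 0.24,
) -> pd.DataFrame:
    """Pearson correlation of a TF regulome with each condition signature.

    Both vectors are encoded as {+1, -1, 0} over the full shared unit
    universe (zeros are informative: neither the TF nor the stress touches
    the unit).  A pair is *considered* when both vectors are non-constant
    and |r| >= ``band`` (the band boundary itself is considered; only the
    open interval is dropped).  Positive r means the TF promotes the
    stress signature.

    Returns columns ``tf, condition, r, n_units, considered``.
    """
    if band < 0:
        raise ValidationError("signature_correlation: band must be >= 0")
    wide = encode_signature(sig)
    if set(wide.index) != set(profile.status.index):
        raise ValidationError("signature_correlation: unit universes differ")
    units = sorted(wide.index)
    x = profile.encoded().reindex(units).values
    rows = []
    for condition in wide.columns:
        y = wide[condition].reindex(units).values
        if np.std(x) == 0 or np.std(y) == 0:
            logger.info(
                "signature_correlation(%s, %s): constant vector, r undefined",
                profile.tf, condition,
            )
            rows.append((profile.tf, condition, np.nan, len(units), False))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((profile.tf, condition, r, len(units), abs(r) >= band))
    return pd.DataFrame(rows, columns=["tf", "condition", "r", "n_units", "considered"])
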