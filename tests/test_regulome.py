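"""Regulome profiles, prediction-observation overlap, and
regulome-signature correlation."""

import numpy as np
import pandas as pd
import pytest

from nutriregulome.errors import ValidationError
from nutriregulome.partition import ModulePartition
from nutriregulome.regulome import (
    prediction_overlap,
    regulome_profile,
    signature_correlation,
)


def _partition():
    return ModulePartition(
        units={
            "M01": tuple(f"a{i}" for i in range(4)),
            "M02": tuple(f"b{i}" for i in range(4)),
            "M03": tuple(f"c{i}" for i in range(4)),
        },
        kinds={"M01": "giant", "M02": "module", "M03": "module"},
    )


def _deg(rows):
    return pd.DataFrame(rows, columns=["gene", "direction"])


def test_profile_of_single_module_deg_list():
    deg = _deg([(f"b{i}", "up") for i in range(4)])
    prof = regulome_profile(deg, _partition(), tf="TFX")
    assert prof.status["M02"] == "up"
    assert prof.status["M01"] == "none"
    assert prof.status["M03"] == "none"
    assert prof.regulated_units == {"M02"}
    assert prof.n_dropped == 0


def test_deg_list_outside_network_all_none():
    deg = _deg([("zz1", "up"), ("zz2", "down")])
    prof = regulome_profile(deg, _partition())
    assert set(prof.status) == {"none"}
    assert prof.n_dropped == 2


def test_empty_deg_list_rejected():
    with pytest.raises(ValidationError, match="empty"):
        regulome_profile(_deg([]), _partition())


def test_unknown_direction_token_rejected():
    with pytest.raises(ValidationError, match="direction"):
        regulome_profile(_deg([("a0", "sideways")]), _partition())


def _profile_with(statuses):
    part = ModulePartition(
        units={u: (f"{u}_g",) for u in statuses},
        kinds={u: "module" for u in statuses},
    )
    rows = []
    for u, s in statuses.items():
        if s == "up":
            rows.append((f"{u}_g", "up"))
        elif s == "down":
            rows.append((f"{u}_g", "down"))
    if not rows:  # non-empty list of out-of-network genes: all units "none"
        rows = [("outside_gene", "up")]
    return regulome_profile(_deg(rows), part, tf="TFX"), part


def test_overlap_arithmetic():
    statuses = {f"M{i:02d}": "up" for i in range(1, 12)}  # 11 regulated units
    prof, _ = _profile_with(statuses)
    predicted = {f"M{i:02d}" for i in range(1, 10)}  # 9 of them predicted
    ov = prediction_overlap(prof, predicted)
    assert ov.n_regulated == 11 and ov.n_overlap == 9
    assert ov.percent == pytest.approx(81.8, abs=0.05)


def test_overlap_boundary_cases():
    prof, _ = _profile_with({"M01": "up", "M02": "down", "M03": "none"})
    assert prediction_overlap(prof, {"M01", "M02", "M03"}).percent == 100.0
    assert prediction_overlap(prof, set()).percent == 0.0
    none_prof, _ = _profile_with({"M01": "none", "M02": "none"})
    ov = prediction_overlap(none_prof, {"M01"})
    assert not ov.defined and ov.percent is None


def test_overlap_monotone_in_predicted_set():
    statuses = {f"M{i:02d}": "up" for i in range(1, 8)}
    prof, _ = _profile_with(statuses)
    last = 0.0
    for k in range(0, 8):
        predicted = {f"M{i:02d}" for i in range(1, k + 1)}
        pct = prediction_overlap(prof, predicted).percent
        assert pct >= last
        last = pct


def _sig_from_column(statuses, condition="c1"):
    count = {"up": (1, 0), "down": (0, 1), "none": (0, 0), "ambiguous": (2, 2)}
    return pd.DataFrame(
        [(u, condition, s, *count[s]) for u, s in statuses.items()],
        columns=["unit", "condition", "status", "n_up", "n_down"],
    )


def test_identical_vectors_correlate_one():
    statuses = {"M01": "up", "M02": "down", "M03": "none", "M04": "up", "M05": "none"}
    prof, _ = _profile_with(statuses)
    rep = signature_correlation(prof, _sig_from_column(statuses))
    assert rep.loc[0, "r"] == pytest.approx(1.0)
    assert bool(rep.loc[0, "considered"])


def test_negated_vector_correlates_minus_one():
    statuses = {"M01": "up", "M02": "down", "M03": "none", "M04": "up"}
    flipped = {"M01": "down", "M02": "up", "M03": "none", "M04": "down"}
    prof, _ = _profile_with(statuses)
    rep = signature_correlation(prof, _sig_from_column(flipped))
    assert rep.loc[0, "r"] == pytest.approx(-1.0)
    assert bool(rep.loc[0, "considered"])


def test_hand_computed_pearson_value_and_band():
    # profile (+1,+1,0,-1,0) vs signature (+1,0,0,-1,-1): r = 2.2/2.8
    prof, _ = _profile_with(
        {"M01": "up", "M02": "up", "M03": "none", "M04": "down", "M05": "none"}
    )
    sig = _sig_from_column(
        {"M01": "up", "M02": "none", "M03": "none", "M04": "down", "M05": "down"}
    )
    rep = signature_correlation(prof, sig)
    expected = 2.2 / 2.8
    assert rep.loc[0, "r"] == pytest.approx(expected)
    assert bool(rep.loc[0, "considered"])
    # band boundary is inclusive: |r| == band is still considered
    rep_edge = signature_correlation(prof, sig, band=expected)
    assert bool(rep_edge.loc[0, "considered"])
    rep_above = signature_correlation(prof, sig, band=expected + 1e-9)
    assert not bool(rep_above.loc[0, "considered"])


def test_constant_vector_gives_undefined_not_considered(caplog):
    statuses = {"M01": "none", "M02": "none", "M03": "none"}
    prof, _ = _profile_with(statuses)
    sig = _sig_from_column({"M01": "up", "M02": "down", "M03": "none"})
    rep = signature_correlation(prof, sig)
    assert np.isnan(rep.loc[0, "r"])
    assert not bool(rep.loc[0, "considered"])


def test_sign_flips_when_profile_inverted():
    statuses = {"M01": "up", "M02": "down", "M03": "none", "M04": "up"}
    sig = _sig_from_column({"M01": "up", "M02": "none", "M03": "down", "M04": "up"})
    prof, _ = _profile_with(statuses)
    inverted, _ = _profile_with(
        {u: {"up": "down", "down": "up", "none": "none"}[s] for u, s in statuses.items()}
    )
    r1 = signature_correlation(prof, sig).loc[0, "r"]
    r2 = signature_correlation(inverted, sig).loc[0, "r"]
    assert r1 == pytest.approx(-r2)


def test_ambiguous_statuses_encode_as_zero():
    prof, _ = _profile_with({"M01": "up", "M02": "none", "M03": "down"})
    sig = _sig_from_column({"M01": "up", "M02": "ambiguous", "M03": "down"})
    rep = signature_correlation(prof, sig)
    assert rep.loc[0, "r"] == pytest.approx(1.0)


def test_mismatched_unit_universe_rejected():
    prof, _ = _profile_with({"M01": "up", "M02": "down"})
    sig = _sig_from_column({"M01": "up", "MXX": "down"})
    with pytest.raises(ValidationError, match="universe"):
        signature_correlation(prof, sig)


def test_planted_aligned_tf_attains_considered_positive_correlation(default_run):
    """The TF planted to drive the same modules as Fe deficiency (same
    directions) correlates positively with the Fe-deficiency signature,
    above the reporting band."""
    prof = regulome_profile(
        default_run["tf_degs"]["TF01"], default_run["partition"], tf="TF01"
    )
    rep = signature_correlation(prof, default_run["sig"])
    row = rep[rep["condition"] == "Fe_def"].iloc[0]
    assert row["r"] >= 0.24
    assert bool(row["considered"])
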