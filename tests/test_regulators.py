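"""TF-to-module mapping: enrichment statistic, evidence criteria,
general/specialized classification, family tallies."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nutriregulome.errors import ValidationError
from nutriregulome.partition import ModulePartition
from nutriregulome.regulators import (
    classify_regulators,
    general_regulator_threshold,
    map_regulators,
    motif_module_enrichment,
    summarize_families,
    target_sets,
)


def enumerate_hypergeom_tail(N, K, n, k_obs):
    """Oracle: P(overlap >= k_obs) by summing the hypergeometric pmf
    written directly from binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(k_obs, min(K, n) + 1)
    ) / total


def test_zero_overlap_gives_p_one():
    universe = [f"g{i}" for i in range(10)]
    _, p = motif_module_enrichment(universe[:3], universe[5:9], universe)
    assert p == pytest.approx(1.0)


def test_full_overlap_small_universe_exact_value():
    universe = [f"g{i}" for i in range(20)]
    motif = universe[:5]
    unit = universe[:5]
    overlap, p = motif_module_enrichment(motif, unit, universe)
    assert overlap == 5
    assert p == pytest.approx(1 / math.comb(20, 5))


def test_unit_equal_to_universe_degenerate():
    universe = [f"g{i}" for i in range(8)]
    overlap, p = motif_module_enrichment(universe[:3], universe, universe)
    assert overlap == 3
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(15))
def test_hypergeometric_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(5, 26))
    universe = [f"g{i:02d}" for i in range(N)]
    K = int(rng.integers(1, N + 1))
    n = int(rng.integers(1, N + 1))
    motif = list(rng.choice(universe, size=K, replace=False))
    unit = list(rng.choice(universe, size=n, replace=False))
    overlap, p = motif_module_enrichment(motif, unit, universe)
    assert overlap == len(set(motif) & set(unit))
    assert p == pytest.approx(enumerate_hypergeom_tail(N, K, n, overlap))


def test_tail_probability_by_exhaustive_draws():
    """For a tiny universe, check the tail against literal enumeration of
    every possible unit draw."""
    N, K, n = 9, 4, 3
    universe = list(range(N))
    successes = set(range(K))
    for k_obs in range(0, 4):
        exhaustive = sum(
            1 for draw in itertools.combinations(universe, n)
            if len(successes & set(draw)) >= k_obs
        ) / math.comb(N, n)
        assert enumerate_hypergeom_tail(N, K, n, k_obs) == pytest.approx(exhaustive)


def _partition():
    units = {
        "M01": tuple(f"a{i}" for i in range(6)),
        "M02": tuple(f"b{i}" for i in range(5)),
        "M03": tuple(f"c{i}" for i in range(4)),
        "rest": ("r0", "r1"),
    }
    kinds = {"M01": "giant", "M02": "module", "M03": "module", "rest": "rest"}
    return ModulePartition(units=units, kinds=kinds)


def test_single_literature_record_suffices():
    evidence = pd.DataFrame(
        [("TF1", "b0", "literature")], columns=["tf", "gene", "evidence_class"]
    )
    regmap = map_regulators(evidence, _partition())
    assert target_sets(regmap) == {"TF1": {"M02"}}
    assert list(regmap["evidence"]) == ["literature"]


def test_rest_unit_never_analyzed():
    evidence = pd.DataFrame(
        [("TF1", "r0", "literature"), ("TF1", "r1", "chipseq")],
        columns=["tf", "gene", "evidence_class"],
    )
    regmap = map_regulators(evidence, _partition())
    assert regmap.empty


def test_unknown_evidence_class_rejected():
    evidence = pd.DataFrame(
        [("TF1", "a0", "rumor")], columns=["tf", "gene", "evidence_class"]
    )
    with pytest.raises(ValidationError, match="rumor"):
        map_regulators(evidence, _partition())


def test_background_rate_motif_genes_yield_no_targets():
    """A TF whose motif genes are scattered at background rate across the
    universe is never called a module target at stringency 1e-3."""
    rng = np.random.default_rng(8)
    part = ModulePartition(
        units={f"M{i:02d}": tuple(f"g{i:02d}_{j}" for j in range(10)) for i in range(1, 9)},
        kinds={f"M{i:02d}": "module" for i in range(1, 9)},
    )
    universe = sorted(part.gene_universe)
    false_targets = 0
    for trial in range(20):
        motif_genes = [g for g in universe if rng.random() < 0.05]
        if not motif_genes:
            continue
        evidence = pd.DataFrame(
            [("TFnull", g, "motif") for g in motif_genes],
            columns=["tf", "gene", "evidence_class"],
        )
        false_targets += len(map_regulators(evidence, part, motif_alpha=1e-3))
    assert false_targets <= 1  # family-wise false-target rate ~ 0


def test_removing_an_evidence_class_never_adds_targets(small_run):
    part = small_run["partition"]
    evidence = small_run["evidence"]
    full = target_sets(map_regulators(evidence, part))
    for dropped in ("literature", "chipseq", "motif"):
        classes = tuple(c for c in ("literature", "chipseq", "motif") if c != dropped)
        reduced = target_sets(map_regulators(evidence, part, evidence_classes=classes))
        for tf, units in reduced.items():
            assert units <= full[tf]


@pytest.mark.parametrize(
    "n_units, fraction, expected",
    [(54, 0.10, 6), (10, 0.10, 2), (60, 0.10, 7), (5, 0.5, 3)],
)
def test_general_regulator_threshold(n_units, fraction, expected):
    assert general_regulator_threshold(n_units, fraction) == expected


def test_tf_targeting_every_unit_is_general():
    regmap = pd.DataFrame(
        [("TF1", f"M{i:02d}", "literature", float("nan")) for i in range(1, 11)],
        columns=["tf", "unit", "evidence", "score"],
    )
    summary = classify_regulators(regmap, n_analyzed_units=10, general_fraction=0.9)
    assert summary.general_tfs == ["TF1"]
    assert summary.n_multi_target == 1


def test_network_membership_and_marker_flags():
    regmap = pd.DataFrame(
        [("TF1", "M01", "literature", float("nan")),
         ("TF2", "M01", "chipseq", float("nan"))],
        columns=["tf", "unit", "evidence", "score"],
    )
    summary = classify_regulators(
        regmap, n_analyzed_units=10,
        network_genes={"gA"}, marker_genes={"gA"},
        tf_gene_map={"TF1": "gA", "TF2": "gB"},
    )
    assert summary.n_in_network == 1
    assert summary.n_network_markers == 1


def test_family_tallies():
    fam = pd.DataFrame(
        [("TF1", "MYB"), ("TF2", "MYB"), ("TF3", "MYB"), ("TF4", "bZIP")],
        columns=["tf", "family"],
    )
    regmap = pd.DataFrame(
        [(tf, "M01", "literature", float("nan")) for tf in ("TF1", "TF2", "TF3", "TF4", "TF5")],
        columns=["tf", "unit", "evidence", "score"],
    )
    counts = summarize_families(fam, regmap)
    assert counts["MYB"] == 3
    assert counts["bZIP"] == 1
    assert counts["unassigned"] == 1
    assert summarize_families(fam, regmap.iloc[0:0]).empty


def test_planted_tf_targets_recovered(default_run):
    """Criterion check on the default fixture: mapped target sets match
    the planted TF-module truth at precision/recall >= 0.9."""
    from nutriregulome.evaluation import tf_mapping_scores

    scores = tf_mapping_scores(
        default_run["regmap"], default_run["partition"], default_run["truth"]
    )
    assert scores["precision"] >= 0.9
    assert scores["recall"] >= 0.9


def test_family_counts_match_planted_labels(default_run):
    truth = default_run["truth"]
    counts = summarize_families(default_run["families"], default_run["regmap"])
    mapped = set(default_run["regmap"]["tf"])
    expected = pd.Series(
        [truth.tf_families[tf] for tf in sorted(mapped)]
    ).value_counts()
    for family, n in expected.items():
        assert counts[family] == n
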