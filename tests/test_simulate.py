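"""Generator contracts: determinism, calibration, DEG error rates,
evidence sampling, and ground-truth round-trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import nutriregulome as nr
from nutriregulome.errors import ConfigError, ValidationError
from nutriregulome.simulate import GroundTruth, SimulationConfig

from conftest import small_simulation_config


def _flat_config(n_genes=1000, **kw):
    """A structureless compendium: all genes background."""
    base = dict(
        n_genes=n_genes, n_modules=0, module_sizes=(), n_conditions=1,
        studies_per_condition=1, replicates_per_arm=4,
        within_module_correlation=0.0, response_map={}, marker_fraction=0.5,
        effect_size=1.0, noise_sd=1.0, n_tfs=0, tf_target_map={}, seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_same_seed_gives_bit_identical_outputs():
    cfg = small_simulation_config(seed=11)
    expr1, truth1 = nr.generate_compendium(cfg)
    expr2, truth2 = nr.generate_compendium(cfg)
    assert (expr1.values == expr2.values).all()
    assert list(expr1.columns) == list(expr2.columns)
    assert truth1 == truth2
    deg1 = nr.generate_deg_tables(expr1, truth1)
    deg2 = nr.generate_deg_tables(expr2, truth2)
    pd.testing.assert_frame_equal(deg1, deg2)
    ev1, fam1 = nr.generate_tf_evidence(truth1)
    ev2, fam2 = nr.generate_tf_evidence(truth2)
    pd.testing.assert_frame_equal(ev1, ev2)
    pd.testing.assert_frame_equal(fam1, fam2)


def test_planted_correlation_calibration():
    """3 modules of 20 genes at rho=0.8 over 40 samples: realised mean
    within-module correlation within 0.1 of target, between-module near 0."""
    cfg = SimulationConfig(
        n_genes=60, n_modules=3, module_sizes=(20, 20, 20), n_conditions=1,
        studies_per_condition=2, replicates_per_arm=10,
        within_module_correlation=0.8, response_map={}, marker_fraction=0.5,
        effect_size=1.0, noise_sd=1.0, n_tfs=0, tf_target_map={}, seed=3,
    )
    expr, truth = nr.generate_compendium(cfg)
    assert expr.shape == (60, 40)
    corr = np.corrcoef(expr.values)
    modules = np.array([truth.gene_module[g] for g in expr.index])
    same = modules[:, None] == modules[None, :]
    off_diag = ~np.eye(60, dtype=bool)
    within = corr[same & off_diag]
    between = corr[~same]
    assert abs(within.mean() - 0.8) < 0.1
    assert abs(between.mean()) < 0.1


def test_no_structure_when_correlation_and_effect_zero():
    cfg = _flat_config(n_genes=80, replicates_per_arm=10, effect_size=1e-12)
    expr, _ = nr.generate_compendium(cfg)
    corr = np.corrcoef(expr.values)
    off = corr[~np.eye(80, dtype=bool)]
    assert abs(off.mean()) < 0.05


def test_ground_truth_round_trip(tmp_path, small_config):
    _, truth = nr.generate_compendium(small_config)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    assert GroundTruth.from_json(path) == truth


@pytest.mark.parametrize(
    "override, field",
    [
        ({"module_sizes": (200, 200, 300), "n_modules": 3}, "module_sizes"),
        ({"within_module_correlation": 1.5}, "within_module_correlation"),
        ({"noise_sd": 0.0}, "noise_sd"),
        ({"effect_size": -1.0}, "effect_size"),
        ({"response_map": {"Fe_def": [("nope", "up")]}}, "response_map"),
        ({"response_map": {"bogus_cond": [("mod01", "up")]}}, "response_map"),
        ({"tf_target_map": {"TFx": ["nope"]}}, "tf_target_map"),
        ({"evidence_class_probs": {"literature": 2.0}}, "evidence_class_probs"),
    ],
)
def test_config_validation_names_offending_field(override, field):
    cfg = dataclasses.replace(small_simulation_config(), **override)
    with pytest.raises(ConfigError, match=field):
        cfg.validate()


def test_null_genes_called_at_nominal_alpha():
    """Uncorrected calls on 1000 pure-noise genes: the number of DEG rows
    matches the binomial expectation at alpha=0.05."""
    cfg = _flat_config(n_genes=1000)
    expr, truth = nr.generate_compendium(cfg)
    deg = nr.generate_deg_tables(expr, truth, alpha=0.05, correction=None)
    # Binomial(1000, 0.05): mean 50, sd ~6.9; 4 sigma band
    assert 22 <= len(deg) <= 78


def test_zero_effect_responsive_module_at_null_rate():
    cfg = small_simulation_config(seed=5)
    cfg = dataclasses.replace(cfg, effect_size=1e-9)
    expr, truth = nr.generate_compendium(cfg)
    deg = nr.generate_deg_tables(expr, truth, alpha=0.05, correction=None)
    responsive = {g for mod in truth.responsive_modules for g in truth.module_genes(mod)}
    calls = deg[deg["gene"].isin(responsive)]
    # 64 responsive-module genes x 12 (condition, study) tests at alpha 0.05
    n_tests = 64 * 4 * 3
    assert len(calls) < n_tests * 0.05 * 3


def test_large_effect_marker_called_up_in_every_study(small_run):
    truth = small_run["truth"]
    deg = small_run["deg"]
    marker = truth.module_markers["mod01"][0]  # planted up under Fe_def
    calls = deg[(deg["gene"] == marker) & (deg["condition"] == "Fe_def")]
    assert len(calls) == truth.config.studies_per_condition
    assert (calls["direction"] == "up").all()


def test_deg_requires_two_replicates():
    cfg = _flat_config(n_genes=10, replicates_per_arm=1)
    expr, truth = nr.generate_compendium(cfg)
    with pytest.raises(ValidationError, match="replicates"):
        nr.generate_deg_tables(expr, truth)


def test_degenerate_motif_rates_cover_targets_exactly(small_config):
    cfg = dataclasses.replace(
        small_config,
        motif_rate_in_target=1.0,
        motif_rate_background=0.0,
        evidence_class_probs={"literature": 0.0, "chipseq": 0.0, "motif": 1.0},
    )
    _, truth = nr.generate_compendium(cfg)
    evidence, _ = nr.generate_tf_evidence(truth)
    assert set(evidence["evidence_class"]) == {"motif"}
    for tf, targets in truth.tf_targets.items():
        expected = {g for mod in targets for g in truth.module_genes(mod)}
        assert set(evidence.loc[evidence["tf"] == tf, "gene"]) == expected


def test_motif_counts_follow_binomial_rate():
    """At rate 0.8 in a 30-gene target module, the per-seed motif count in
    the module behaves like Binomial(30, 0.8) across seeds."""
    counts = []
    for seed in range(30):
        cfg = SimulationConfig(
            n_genes=60, n_modules=1, module_sizes=(30,), n_conditions=1,
            studies_per_condition=1, replicates_per_arm=2,
            within_module_correlation=0.5,
            response_map={"Fe_def": [("mod01", "up")]},
            marker_fraction=0.5, effect_size=1.0, noise_sd=1.0,
            n_tfs=1, tf_target_map={"TFa": ["mod01"]},
            motif_rate_in_target=0.8, motif_rate_background=0.05,
            evidence_class_probs={"literature": 0, "chipseq": 0, "motif": 1},
            seed=seed,
        )
        _, truth = nr.generate_compendium(cfg)
        evidence, _ = nr.generate_tf_evidence(truth)
        members = set(truth.module_genes("mod01"))
        motif = evidence[(evidence["evidence_class"] == "motif")
                         & evidence["gene"].isin(members)]
        counts.append(len(motif))
    mean_rate = np.mean(counts) / 30
    # sd of the mean rate = sqrt(0.8*0.2/30)/sqrt(30) ~ 0.013; 4 sigma
    assert abs(mean_rate - 0.8) < 0.055
    assert np.std(counts) > 0  # genuinely stochastic across seeds


def test_perturbation_degs_follow_planted_directions(small_run):
    truth = small_run["truth"]
    degs = small_run["tf_degs"]["TFa"]
    planted = {
        g: d for mod, d in truth.tf_targets["TFa"].items()
        for g in truth.module_genes(mod)
    }
    assert set(degs["gene"]) <= set(planted)
    for gene, direction in degs.itertuples(index=False):
        assert planted[gene] == direction
    # 90% sensitivity: most target genes present
    assert len(degs) >= 0.75 * len(planted)
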