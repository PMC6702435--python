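"""Shared fixtures: a small fast compendium and the full default fixture.

Both are generated programmatically; the expensive default fixture is
built once per session and shared by the recovery and acceptance tests.
"""

from __future__ import annotations

import pytest

import nutriregulome as nr
from nutriregulome.simulate import SimulationConfig


def small_simulation_config(seed: int = 0) -> SimulationConfig:
    """120 genes, 6 modules, 4 conditions: fast but fully structured."""
    return SimulationConfig(
        n_genes=120,
        n_modules=6,
        module_sizes=(12, 12, 10, 10, 10, 10),
        n_conditions=4,
        studies_per_condition=3,
        replicates_per_arm=8,
        within_module_correlation=0.8,
        response_map={
            "Fe_def": [("mod01", "up"), ("mod05", "down")],
            "Zn_def": [("mod02", "up")],
            "Mn_def": [("mod03", "down"), ("mod06", "up")],
            "Cu_exc": [("mod04", "up")],
        },
        marker_fraction=0.6,
        effect_size=3.0,
        noise_sd=1.0,
        n_tfs=3,
        tf_target_map={
            "TFa": [("mod01", "up"), ("mod05", "down")],
            "TFb": ["mod02", "mod03"],
            "TFc": ["mod04"],
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_config():
    return small_simulation_config()


@pytest.fixture(scope="session")
def small_run(small_config):
    """Small compendium pushed through every pipeline stage in memory."""
    expr, truth = nr.generate_compendium(small_config)
    deg = nr.generate_deg_tables(expr, truth)
    markers = nr.select_markers(deg)
    corr = nr.correlation_matrix(expr)
    mr = nr.mutual_rank(corr)
    net = nr.extract_network(mr, markers, gene_universe=corr.index)
    part = nr.subgroup_giant(net, nr.find_modules(net))
    sig = nr.signature_matrix(part, markers)
    evidence, families = nr.generate_tf_evidence(truth)
    regmap = nr.map_regulators(evidence, part)
    tf_degs = nr.generate_tf_perturbation_degs(truth)
    return {
        "config": small_config, "expr": expr, "truth": truth, "deg": deg,
        "markers": markers, "corr": corr, "mr": mr, "net": net,
        "partition": part, "sig": sig, "evidence": evidence,
        "families": families, "regmap": regmap, "tf_degs": tf_degs,
    }


@pytest.fixture(scope="session")
def default_run():
    """The full default fixture (600 genes, 13 conditions) at seed 0,
    pushed through every stage once per session."""
    cfg = nr.default_config(seed=0)
    expr, truth = nr.generate_compendium(cfg)
    deg = nr.generate_deg_tables(expr, truth)
    markers = nr.select_markers(deg)
    corr = nr.correlation_matrix(expr)
    mr = nr.mutual_rank(corr)
    net = nr.extract_network(mr, markers, gene_universe=corr.index)
    part = nr.subgroup_giant(net, nr.find_modules(net))
    sig = nr.signature_matrix(part, markers)
    evidence, families = nr.generate_tf_evidence(truth)
    regmap = nr.map_regulators(evidence, part)
    tf_degs = nr.generate_tf_perturbation_degs(truth)
    return {
        "config": cfg, "expr": expr, "truth": truth, "deg": deg,
        "markers": markers, "corr": corr, "mr": mr, "net": net,
        "partition": part, "sig": sig, "evidence": evidence,
        "families": families, "regmap": regmap, "tf_degs": tf_degs,
    }
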