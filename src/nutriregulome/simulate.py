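"""Synthetic expression compendium with planted coexpression structure.

The generator emulates the kind of mined public data the downstream
analysis assumes: a multi-condition expression compendium in which groups
of genes are coexpressed (planted modules driven by a shared latent
factor), a subset of each stress-responsive module is consistently
differentially expressed across independent studies of that condition
(the planted marker genes), and transcription factors carry binding
evidence (literature / ChIP-seq / motif occurrence) concentrated on their
target modules.

Generative model
----------------
Each module ``m`` has one latent factor per sample, ``f_m ~ N(0, 1)``.
A member gene's value is::

    x_g = mu_g + noise_sd * (sqrt(rho) * f_m + sqrt(1 - rho) * eps_g)

with ``eps_g ~ N(0, 1)`` independent per gene and sample, so the expected
pairwise within-module Pearson correlation is exactly ``rho``
(``within_module_correlation``).  Background genes are pure noise around
their baseline.  In a perturbed arm of condition ``c``, each designated
marker gene of a module listed in ``response_map[c]`` is shifted by
``±effect_size`` log-units (sign per the planted direction).  Restricting
the shift to the marker subset keeps ``marker_fraction`` meaningful: the
non-marker members coexpress with the module but are not consistently
condition-responsive, so marker selection has genuine negatives inside
responsive modules.

Samples are organised as independent "studies": for every condition and
study there is a control arm and a perturbed arm with
``replicates_per_arm`` replicates each, and sample ids encode
``condition:study:arm:replicate``.

The random stream is split hierarchically (expression matrix / DEG noise /
evidence / perturbation lists) so, e.g., changing ``n_tfs`` never perturbs
the expression matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError

DIRECTIONS = ("up", "down")

#: 13 nutrient stress conditions (deficiencies and excesses) used by the
#: default compendium; mirrors the scale of a typical multi-nutrient study.
DEFAULT_CONDITIONS = (
    "Fe_def", "Zn_def", "Mn_def", "Cu_exc", "Zn_exc", "Cd_exc", "NaCl_exc",
    "N_def", "P_def", "K_def", "S_def", "Mg_def", "B_def",
)

EVIDENCE_CLASSES = ("literature", "chipseq", "motif")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium.

    ``response_map`` maps a condition name to ``[(module_id, direction)]``;
    ``tf_target_map`` maps a TF id to a list of module ids or
    ``(module_id, direction)`` pairs (a bare module id inherits the
    direction the module has under the first condition that regulates it,
    else "up").
    """

    n_genes: int = 600
    n_modules: int = 30
    module_sizes: Sequence[int] = ()
    n_conditions: int = 13
    studies_per_condition: int = 3
    replicates_per_arm: int = 4
    within_module_correlation: float = 0.8
    response_map: Mapping[str, Sequence] = field(default_factory=dict)
    marker_fraction: float = 0.6
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_tfs: int = 12
    tf_target_map: Mapping[str, Sequence] = field(default_factory=dict)
    motif_rate_in_target: float = 0.8
    motif_rate_background: float = 0.02
    evidence_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"literature": 0.15, "chipseq": 0.15, "motif": 0.7}
    )
    seed: int = 0

    # -- derived naming -------------------------------------------------
    @property
    def conditions(self) -> tuple[str, ...]:
        base = list(DEFAULT_CONDITIONS)
        while len(base) < self.n_conditions:
            base.append(f"cond{len(base) + 1:02d}")
        return tuple(base[: self.n_conditions])

    @property
    def module_ids(self) -> tuple[str, ...]:
        return tuple(f"mod{i + 1:02d}" for i in range(len(self.module_sizes)))

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the offending field."""
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError(
                f"module_sizes: expected {self.n_modules} entries, got {len(self.module_sizes)}"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ConfigError("module_sizes: every module size must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("module_sizes: sum exceeds n_genes")
        for name, value in [
            ("within_module_correlation", self.within_module_correlation),
            ("marker_fraction", self.marker_fraction),
            ("motif_rate_in_target", self.motif_rate_in_target),
            ("motif_rate_background", self.motif_rate_background),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1], got {value}")
        for cls, p in self.evidence_class_probs.items():
            if cls not in EVIDENCE_CLASSES:
                raise ConfigError(f"evidence_class_probs: unknown class {cls!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"evidence_class_probs[{cls}]: must lie in [0, 1]")
        if self.effect_size < 0:
            raise ConfigError("effect_size: must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd: must be > 0")
        if self.n_conditions < 1:
            raise ConfigError("n_conditions: must be >= 1")
        module_set = set(self.module_ids)
        conditions = set(self.conditions)
        for cond, responses in self.response_map.items():
            if cond not in conditions:
                raise ConfigError(f"response_map: unknown condition {cond!r}")
            for entry in responses:
                mod, direction = entry
                if mod not in module_set:
                    raise ConfigError(f"response_map[{cond}]: unknown module {mod!r}")
                if direction not in DIRECTIONS:
                    raise ConfigError(
                        f"response_map[{cond}]: direction must be up/down, got {direction!r}"
                    )
        for tf, targets in self.tf_target_map.items():
            for entry in targets:
                mod = entry[0] if isinstance(entry, (tuple, list)) else entry
                if mod not in module_set:
                    raise ConfigError(f"tf_target_map[{tf}]: unknown module {mod!r}")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["response_map"] = {
            c: [[m, di] for m, di in v] for c, v in self.response_map.items()
        }
        d["tf_target_map"] = {
            tf: [list(e) if isinstance(e, (tuple, list)) else e for e in v]
            for tf, v in self.tf_target_map.items()
        }
        d["evidence_class_probs"] = dict(self.evidence_class_probs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["module_sizes"] = tuple(d.get("module_sizes", ()))
        d["response_map"] = {
            c: [tuple(e) for e in v] for c, v in d.get("response_map", {}).items()
        }
        d["tf_target_map"] = {
            tf: [tuple(e) if isinstance(e, list) else e for e in v]
            for tf, v in d.get("tf_target_map", {}).items()
        }
        return cls(**d)


def default_config(seed: int = 0) -> SimulationConfig:
    """The standard synthetic fixture: 600 genes, 30 modules, 13 conditions.

    Every module responds to at least one condition (two or three modules
    per condition, with planted overlaps such as a module shared by Fe
    deficiency and Zn excess); 94 background genes are unresponsive noise.
    Studies are powered (8 replicates per arm) so per-study BH-corrected
    DEG lists recover the planted effects.  12 TFs target responsive
    modules; ``TF01`` is planted signature-aligned with Fe deficiency
    (same target modules, same directions).
    """
    sizes = (26, 24, 24, 22, 22, 20, 20, 20, 18, 18, 18, 18, 16, 16, 16,
             16, 16, 16, 14, 14, 14, 14, 14, 14, 14, 14, 12, 12, 12, 12)
    response_map = {
        "Fe_def": [("mod01", "up"), ("mod05", "down")],
        "Zn_exc": [("mod05", "down"), ("mod06", "up")],
        "Zn_def": [("mod06", "up"), ("mod23", "down")],
        "Mn_def": [("mod02", "down"), ("mod07", "up")],
        "Cu_exc": [("mod03", "up"), ("mod08", "up")],
        "Cd_exc": [("mod03", "up"), ("mod09", "down")],
        "NaCl_exc": [("mod04", "up"), ("mod10", "down"), ("mod24", "up")],
        "N_def": [("mod11", "up"), ("mod12", "down"), ("mod25", "down")],
        "P_def": [("mod13", "up"), ("mod14", "down"), ("mod26", "up")],
        "K_def": [("mod15", "up"), ("mod16", "down"), ("mod27", "down")],
        "S_def": [("mod17", "down"), ("mod18", "up"), ("mod28", "up")],
        "Mg_def": [("mod19", "up"), ("mod20", "down"), ("mod29", "down")],
        "B_def": [("mod21", "up"), ("mod22", "down"), ("mod30", "up")],
    }
    tf_target_map = {
        "TF01": [("mod01", "up"), ("mod05", "down")],   # aligned with Fe_def
        "TF02": [("mod05", "down"), ("mod06", "up")],
        "TF03": ["mod02", "mod07", "mod11"],
        "TF04": ["mod03"],
        "TF05": ["mod04", "mod10"],
        "TF06": ["mod08", "mod09", "mod12", "mod13"],   # broad: general regulator
        "TF07": ["mod14"],
        "TF08": ["mod15", "mod16"],
        "TF09": ["mod17", "mod18"],
        "TF10": ["mod19"],
        "TF11": ["mod20", "mod21"],
        "TF12": ["mod22", "mod23"],
    }
    return SimulationConfig(
        n_genes=600,
        n_modules=len(sizes),
        module_sizes=sizes,
        n_conditions=13,
        studies_per_condition=3,
        replicates_per_arm=8,
        within_module_correlation=0.8,
        response_map=response_map,
        marker_fraction=0.6,
        effect_size=3.0,
        noise_sd=1.0,
        n_tfs=len(tf_target_map),
        tf_target_map=tf_target_map,
        seed=seed,
    )


TF_FAMILIES = ("MYB", "bHLH", "bZIP", "WRKY", "NAC", "ERF", "NF-Y", "C2H2")


@dataclass
class GroundTruth:
    """Planted structure of a generated compendium.

    Attributes
    ----------
    gene_module
        gene id -> module id, with background genes mapped to "background".
    response_map
        condition -> list of (module id, direction).
    markers
        condition -> {gene id: direction}; the planted marker genes.
    module_markers
        module id -> sorted list of designated marker genes.
    tf_targets
        TF id -> {module id: direction}.
    tf_genes
        TF id -> the gene id hosting the TF in the compendium.
    tf_families
        TF id -> protein family label.
    config
        the :class:`SimulationConfig` used.
    """

    gene_module: dict
    response_map: dict
    markers: dict
    module_markers: dict
    tf_targets: dict
    tf_genes: dict
    tf_families: dict
    config: SimulationConfig

    def module_genes(self, module: str) -> list[str]:
        return sorted(g for g, m in self.gene_module.items() if m == module)

    @property
    def responsive_modules(self) -> set[str]:
        return {m for resp in self.response_map.values() for m, _ in resp}

    def marker_records(self) -> set[tuple[str, str, str]]:
        """Planted (gene, condition, direction) triples."""
        return {
            (g, cond, d)
            for cond, genes in self.markers.items()
            for g, d in genes.items()
        }

    # -- round-trip serialisation ---------------------------------------
    def to_dict(self) -> dict:
        return {
            "gene_module": self.gene_module,
            "response_map": {c: [[m, d] for m, d in v] for c, v in self.response_map.items()},
            "markers": self.markers,
            "module_markers": self.module_markers,
            "tf_targets": self.tf_targets,
            "tf_genes": self.tf_genes,
            "tf_families": self.tf_families,
            "config": self.config.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            gene_module=dict(d["gene_module"]),
            response_map={c: [tuple(e) for e in v] for c, v in d["response_map"].items()},
            markers={c: dict(v) for c, v in d["markers"].items()},
            module_markers={m: list(v) for m, v in d["module_markers"].items()},
            tf_targets={tf: dict(v) for tf, v in d["tf_targets"].items()},
            tf_genes=dict(d["tf_genes"]),
            tf_families=dict(d["tf_families"]),
            config=SimulationConfig.from_dict(d["config"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# sample bookkeeping


def sample_id(condition: str, study: int, arm: str, replicate: int) -> str:
    return f"{condition}:s{study}:{arm}:{replicate}"


def parse_sample_id(sid: str) -> dict:
    """Split a ``condition:study:arm:replicate`` sample id into fields."""
    parts = sid.split(":")
    if len(parts) != 4 or parts[2] not in ("ctrl", "pert"):
        raise ValidationError(f"malformed sample id {sid!r}")
    return {
        "condition": parts[0],
        "study": parts[1],
        "arm": parts[2],
        "replicate": int(parts[3]),
    }


def sample_table(columns: Sequence[str]) -> pd.DataFrame:
    """Per-sample metadata parsed from the column ids of a compendium."""
    return pd.DataFrame([parse_sample_id(c) for c in columns], index=list(columns))


# ---------------------------------------------------------------------------
# generation


def _streams(seed: int) -> dict[str, np.random.Generator]:
    kids = np.random.SeedSequence(seed).spawn(4)
    names = ("matrix", "deg", "evidence", "perturbation")
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


def _resolve_tf_direction(config: SimulationConfig, module: str) -> str:
    for cond in config.conditions:
        for mod, direction in config.response_map.get(cond, ()):
            if mod == module:
                return direction
    return "up"


def generate_compendium(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a log-scale expression matrix (genes x samples) and its truth.

    Deterministic given ``config.seed``: two calls with the same config
    produce bit-identical matrices and equal :class:`GroundTruth` objects.
    """
    config.validate()
    rng = _streams(config.seed)["matrix"]

    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]

    # contiguous gene -> module assignment; remainder is background
    gene_module: dict[str, str] = {}
    cursor = 0
    members: dict[str, list[str]] = {}
    for mod, size in zip(config.module_ids, config.module_sizes):
        members[mod] = genes[cursor: cursor + size]
        for g in members[mod]:
            gene_module[g] = mod
        cursor += size
    for g in genes[cursor:]:
        gene_module[g] = "background"

    columns = [
        sample_id(cond, s, arm, r)
        for cond in config.conditions
        for s in range(1, config.studies_per_condition + 1)
        for arm in ("ctrl", "pert")
        for r in range(1, config.replicates_per_arm + 1)
    ]
    n_samples = len(columns)

    baselines = rng.normal(8.0, 2.0, size=config.n_genes)
    factors = rng.standard_normal((len(config.module_ids), n_samples))
    eps = rng.standard_normal((config.n_genes, n_samples))

    rho = config.within_module_correlation
    load, resid = np.sqrt(rho), np.sqrt(1.0 - rho)
    values = np.empty((config.n_genes, n_samples))
    mod_index = {m: i for i, m in enumerate(config.module_ids)}
    for gi, g in enumerate(genes):
        m = gene_module[g]
        if m == "background":
            signal = eps[gi]
        else:
            signal = load * factors[mod_index[m]] + resid * eps[gi]
        values[gi] = baselines[gi] + config.noise_sd * signal

    # designate marker genes per responsive module (once per module, so a
    # module shared by two conditions contributes the same markers to both)
    module_markers: dict[str, list[str]] = {}
    responsive = sorted({m for resp in config.response_map.values() for m, _ in resp})
    for mod in responsive:
        k = max(1, round(config.marker_fraction * len(members[mod])))
        chosen = rng.choice(len(members[mod]), size=k, replace=False)
        module_markers[mod] = sorted(members[mod][i] for i in sorted(chosen))

    # apply the response shift to marker genes in perturbed arms
    gene_index = {g: i for i, g in enumerate(genes)}
    col_meta = [parse_sample_id(c) for c in columns]
    markers: dict[str, dict[str, str]] = {c: {} for c in config.conditions}
    for cond, responses in config.response_map.items():
        cols = [
            j for j, meta in enumerate(col_meta)
            if meta["condition"] == cond and meta["arm"] == "pert"
        ]
        for mod, direction in responses:
            shift = config.effect_size if direction == "up" else -config.effect_size
            for g in module_markers[mod]:
                values[gene_index[g], cols] += shift
                markers[cond][g] = direction

    # TF placement: cycle marker / non-marker member / background hosts so
    # the in-network and is-marker regulator flags are all exercised
    tf_targets: dict[str, dict[str, str]] = {}
    for tf, targets in config.tf_target_map.items():
        resolved: dict[str, str] = {}
        for entry in targets:
            if isinstance(entry, (tuple, list)):
                mod, direction = entry
            else:
                mod, direction = entry, _resolve_tf_direction(config, entry)
            resolved[mod] = direction
        tf_targets[tf] = resolved

    background_genes = genes[cursor:]
    tf_genes: dict[str, str] = {}
    tf_families: dict[str, str] = {}
    for i, tf in enumerate(sorted(tf_targets)):
        first_mod = sorted(tf_targets[tf])[0]
        kind = i % 3
        if kind == 0 and first_mod in module_markers:
            tf_genes[tf] = module_markers[first_mod][0]
        elif kind == 1:
            non_markers = [g for g in members[first_mod]
                           if g not in module_markers.get(first_mod, [])]
            tf_genes[tf] = non_markers[0] if non_markers else members[first_mod][0]
        else:
            tf_genes[tf] = background_genes[i % len(background_genes)] if background_genes else genes[i]
        tf_families[tf] = TF_FAMILIES[i % len(TF_FAMILIES)]

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=columns)
    truth = GroundTruth(
        gene_module=gene_module,
        response_map={c: [tuple(e) for e in v] for c, v in config.response_map.items()},
        markers=markers,
        module_markers=module_markers,
        tf_targets=tf_targets,
        tf_genes=tf_genes,
        tf_families=tf_families,
        config=config,
    )
    return expr, truth


def generate_deg_tables(
    expr: pd.DataFrame,
    truth: GroundTruth,
    alpha: float = 0.05,
    correction: str | None = "fdr_bh",
) -> pd.DataFrame:
    """Per-study differential-expression calls from the compendium.

    For every condition and study, each gene is tested with a two-sample
    t-test between the study's perturbed and control replicates; genes
    significant at ``alpha`` enter the table with the sign of the mean
    shift.  By default p-values are Benjamini-Hochberg adjusted within
    each study, as published DEG lists are; pass ``correction=None`` for
    raw per-gene calls at nominal ``alpha``.

    Returns a tidy table with columns
    ``study, condition, gene, direction, effect, p_value`` (p_value is
    the adjusted value when a correction is applied).
    """
    meta = sample_table(expr.columns)
    config = truth.config
    if config.replicates_per_arm < 2:
        raise ValidationError("generate_deg_tables: need >= 2 replicates per arm")
    rows = []
    for cond in config.conditions:
        for s in range(1, config.studies_per_condition + 1):
            study = f"s{s}"
            sel = (meta["condition"] == cond) & (meta["study"] == study)
            pert = expr.loc[:, (sel & (meta["arm"] == "pert")).values]
            ctrl = expr.loc[:, (sel & (meta["arm"] == "ctrl")).values]
            if pert.shape[1] < 2 or ctrl.shape[1] < 2:
                raise ValidationError(
                    f"generate_deg_tables: fewer than 2 replicates in {cond}/{study}"
                )
            t, p = stats.ttest_ind(pert.values, ctrl.values, axis=1)
            effect = pert.values.mean(axis=1) - ctrl.values.mean(axis=1)
            if correction is not None:
                _, p, _, _ = multipletests(p, method=correction)
            hit = p < alpha
            for gi in np.flatnonzero(hit):
                rows.append((
                    study, cond, expr.index[gi],
                    "up" if effect[gi] > 0 else "down",
                    float(effect[gi]), float(p[gi]),
                ))
    return pd.DataFrame(
        rows, columns=["study", "condition", "gene", "direction", "effect", "p_value"]
    )


def generate_tf_evidence(
    truth: GroundTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a TF binding-evidence table and a TF family table.

    Motif records occur per gene at ``motif_rate_in_target`` inside a TF's
    target modules and at ``motif_rate_background`` elsewhere.  Literature
    and ChIP-seq records are sampled only for true-target genes, at the
    per-class probabilities in ``evidence_class_probs``.

    Returns ``(evidence, families)`` where evidence has columns
    ``tf, gene, evidence_class`` and families has ``tf, family``.
    """
    config = truth.config
    if not truth.tf_targets:
        raise ValidationError("generate_tf_evidence: tf_target_map is empty")
    rng = _streams(config.seed if seed is None else seed)["evidence"]
    genes = sorted(truth.gene_module)
    p_lit = config.evidence_class_probs.get("literature", 0.0)
    p_chip = config.evidence_class_probs.get("chipseq", 0.0)

    rows = []
    for tf in sorted(truth.tf_targets):
        target_mods = set(truth.tf_targets[tf])
        in_target = np.array([truth.gene_module[g] in target_mods for g in genes])
        rate = np.where(in_target, config.motif_rate_in_target, config.motif_rate_background)
        draw = rng.random(len(genes))
        for gi in np.flatnonzero(draw < rate):
            rows.append((tf, genes[gi], "motif"))
        target_genes = [g for g, flag in zip(genes, in_target) if flag]
        lit_draw = rng.random(len(target_genes))
        chip_draw = rng.random(len(target_genes))
        for g, d in zip(target_genes, lit_draw):
            if d < p_lit:
                rows.append((tf, g, "literature"))
        for g, d in zip(target_genes, chip_draw):
            if d < p_chip:
                rows.append((tf, g, "chipseq"))
    evidence = pd.DataFrame(rows, columns=["tf", "gene", "evidence_class"])
    families = pd.DataFrame(
        sorted(truth.tf_families.items()), columns=["tf", "family"]
    )
    return evidence, families


def generate_tf_perturbation_degs(
    truth: GroundTruth,
    sensitivity: float = 0.9,
    background_rate: float = 0.0,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-TF perturbation DEG lists derived from the planted regulation.

    Each gene of a TF's target modules enters the list with probability
    ``sensitivity`` and the module's planted direction; background genes
    enter with probability ``background_rate`` and a random direction
    (the noise floor of a perturbation experiment).
    """
    config = truth.config
    rng = _streams(config.seed if seed is None else seed)["perturbation"]
    genes = sorted(truth.gene_module)
    out: dict[str, pd.DataFrame] = {}
    for tf in sorted(truth.tf_targets):
        rows = []
        target_mods = truth.tf_targets[tf]
        for g in genes:
            mod = truth.gene_module[g]
            if mod in target_mods:
                if rng.random() < sensitivity:
                    rows.append((g, target_mods[mod]))
            elif rng.random() < background_rate:
                rows.append((g, "up" if rng.random() < 0.5 else "down"))
        out[tf] = pd.DataFrame(rows, columns=["gene", "direction"])
    return out
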