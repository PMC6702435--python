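"""Readers and writers for every pipeline table.

All tables are TSV with strict, validated headers; the network travels as
GraphML (node attributes ``is_seed`` and ``tier``, edge attribute ``mr``)
or a plain edge-list TSV; ground truth and run manifests are JSON.  Every
writer/reader pair round-trips its object exactly.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import SchemaError
from .markers import DEG_COLUMNS, MARKER_COLUMNS
from .mutual_rank import MR_COLUMNS
from .partition import ModulePartition
from .regulators import REGMAP_COLUMNS
from .signatures import SIGNATURE_COLUMNS

PARTITION_COLUMNS = ["gene", "unit", "kind"]
EVIDENCE_COLUMNS = ["tf", "gene", "evidence_class"]
CORRELATION_COLUMNS = ["tf", "condition", "r", "n_units", "considered"]


def _read_tsv(path, expected: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("gene", "gene_a", "gene_b")})
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed TSV ({exc})") from exc
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: column mismatch (missing {missing or 'none'}, extra {extra or 'none'})"
        )
    return df[expected]


def _write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# -- expression -------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col="gene")
    except (ValueError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: cannot parse expression matrix ({exc})") from exc
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise SchemaError(f"{path}: ragged or missing values (first bad gene: {bad})")
    for col in df.columns:
        if len(col.split(":")) != 4:
            raise SchemaError(
                f"{path}: sample id {col!r} is not condition:study:arm:replicate"
            )
    return df


# -- flat tables ------------------------------------------------------------

def write_deg_tables(deg: pd.DataFrame, path) -> None:
    _write_tsv(deg[DEG_COLUMNS], path)


def read_deg_tables(path) -> pd.DataFrame:
    df = _read_tsv(path, DEG_COLUMNS)
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise SchemaError(f"{path}: unknown direction token(s) {sorted(bad)}")
    return df


def write_markers(markers: pd.DataFrame, path) -> None:
    _write_tsv(markers[MARKER_COLUMNS], path)


def read_markers(path) -> pd.DataFrame:
    df = _read_tsv(path, MARKER_COLUMNS)
    df["n_studies"] = df["n_studies"].astype(int)
    return df


def write_mr_table(mr: pd.DataFrame, path) -> None:
    _write_tsv(mr[MR_COLUMNS], path)


def read_mr_table(path) -> pd.DataFrame:
    df = _read_tsv(path, MR_COLUMNS)
    df["rank_ab"] = df["rank_ab"].astype(int)
    df["rank_ba"] = df["rank_ba"].astype(int)
    return df


def write_evidence(evidence: pd.DataFrame, path) -> None:
    _write_tsv(evidence[EVIDENCE_COLUMNS], path)


def read_evidence(path) -> pd.DataFrame:
    df = _read_tsv(path, EVIDENCE_COLUMNS)
    bad = set(df["evidence_class"]) - {"literature", "chipseq", "motif"}
    if bad:
        raise SchemaError(f"{path}: unknown evidence class label(s) {sorted(bad)}")
    return df


def write_signature(sig: pd.DataFrame, path) -> None:
    _write_tsv(sig[SIGNATURE_COLUMNS], path)


def read_signature(path) -> pd.DataFrame:
    df = _read_tsv(path, SIGNATURE_COLUMNS)
    df["n_up"] = df["n_up"].astype(int)
    df["n_down"] = df["n_down"].astype(int)
    return df


def write_regmap(regmap: pd.DataFrame, path) -> None:
    _write_tsv(regmap[REGMAP_COLUMNS], path)


def read_regmap(path) -> pd.DataFrame:
    return _read_tsv(path, REGMAP_COLUMNS)


def write_correlation_report(report: pd.DataFrame, path) -> None:
    _write_tsv(report[CORRELATION_COLUMNS], path)


def read_correlation_report(path) -> pd.DataFrame:
    df = _read_tsv(path, CORRELATION_COLUMNS)
    df["considered"] = df["considered"].astype(bool)
    return df


# -- partition ---------------------------------------------------------------

def write_partition(partition: ModulePartition, path) -> None:
    _write_tsv(partition.to_frame(), path)


def read_partition(path, min_module_size: int = 4) -> ModulePartition:
    df = _read_tsv(path, PARTITION_COLUMNS)
    units: dict[str, list] = {}
    kinds: dict[str, str] = {}
    for gene, unit, kind in df.itertuples(index=False):
        units.setdefault(unit, []).append(gene)
        kinds[unit] = kind
    return ModulePartition(
        units={u: tuple(sorted(g)) for u, g in units.items()},
        kinds=kinds,
        min_module_size=min_module_size,
    )


# -- network -----------------------------------------------------------------

def write_network(net: nx.Graph, path) -> None:
    """GraphML with is_seed/tier node attributes and mr edge weights."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net, path)


def read_network(path) -> nx.Graph:
    net = nx.read_graphml(path)
    out = nx.Graph()
    for node, data in sorted(net.nodes(data=True)):
        out.add_node(node, is_seed=bool(data.get("is_seed")), tier=int(data.get("tier", 0)))
    for a, b, data in net.edges(data=True):
        out.add_edge(a, b, mr=float(data.get("mr", 0.0)))
    return out


def write_edge_list(net: nx.Graph, path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), data["mr"]) for a, b, data in net.edges(data=True)
    )
    _write_tsv(pd.DataFrame(rows, columns=["gene_a", "gene_b", "mr"]), path)
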