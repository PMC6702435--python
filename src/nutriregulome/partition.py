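"""Partition of the network into response units by connectivity.

Connected components are the primary structure: the largest component is
M01 (the "giant" group), other components of at least ``min_module_size``
genes are numbered M02, M03, ... in descending size, and smaller
components are pooled into a single "rest" unit.  M01 is optionally
refined into letter-labelled sub-groups (M01a, M01b, ...) by greedy
modularity maximisation, since a large dense component usually hides
several coexpression neighbourhoods.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

KINDS = ("giant", "giant_subgroup", "module", "rest")


@dataclass
class ModulePartition:
    """Disjoint response units covering the network's gene set.

    ``units`` maps unit id -> sorted tuple of member genes; ``kinds`` maps
    unit id -> one of giant / giant_subgroup / module / rest.
    """

    units: dict = field(default_factory=dict)
    kinds: dict = field(default_factory=dict)
    min_module_size: int = 4

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units)

    @property
    def gene_universe(self) -> set:
        return {g for genes in self.units.values() for g in genes}

    def unit_of(self) -> dict:
        """gene -> unit id lookup."""
        return {g: u for u, genes in self.units.items() for g in genes}

    @property
    def analyzed_units(self) -> list[str]:
        """Units eligible for regulator analysis: giant sub-groups and
        modules with at least ``min_module_size`` genes; rest excluded."""
        return [
            u for u, k in self.kinds.items()
            if k in ("giant", "giant_subgroup", "module")
            and len(self.units[u]) >= self.min_module_size
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, u, self.kinds[u])
            for u, genes in self.units.items()
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["gene", "unit", "kind"])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(u, self.kinds[u], len(genes)) for u, genes in self.units.items()],
            columns=["unit", "kind", "size"],
        )


def _components(net: nx.Graph) -> list[tuple[str, ...]]:
    comps = [tuple(sorted(c)) for c in nx.connected_components(net)]
    # descending size, ties by smallest member gene id
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def find_modules(net: nx.Graph, min_module_size: int = 4) -> ModulePartition:
    """Partition the network into M01 / numbered modules / rest.

    The largest component becomes M01 regardless of size; remaining
    components of >= ``min_module_size`` genes become M02, M03, ... in
    descending size (ties broken by smallest member gene id); everything
    smaller is pooled into "rest".
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("find_modules: empty network")
    comps = _components(net)
    units: dict[str, tuple] = {"M01": comps[0]}
    kinds: dict[str, str] = {"M01": "giant"}
    rest: list[str] = []
    counter = 2
    for comp in comps[1:]:
        if len(comp) >= min_module_size:
            uid = f"M{counter:02d}"
            units[uid] = comp
            kinds[uid] = "module"
            counter += 1
        else:
            rest.extend(comp)
    if rest:
        units["rest"] = tuple(sorted(rest))
        kinds["rest"] = "rest"
    part = ModulePartition(units=units, kinds=kinds, min_module_size=min_module_size)
    assert sum(len(g) for g in part.units.values()) == net.number_of_nodes()
    return part


def _letters(n: int) -> list[str]:
    out = []
    letters = string.ascii_lowercase
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def subgroup_giant(
    net: nx.Graph,
    partition: ModulePartition,
    min_module_size: int | None = None,
) -> ModulePartition:
    """Refine M01 into letter-labelled sub-groups by greedy modularity.

    Communities are detected on the M01-induced subgraph (rebuilt with
    sorted node and edge insertion so the result is independent of input
    order), labelled a, b, c, ... in descending size, and communities
    smaller than ``min_module_size`` are merged into the neighbouring
    community they share the most edges with.  If M01 is too small to
    sub-group (fewer than twice ``min_module_size`` genes) the partition
    is returned unchanged.
    """
    if "M01" not in partition.units:
        raise ValidationError("subgroup_giant: partition has no M01 unit")
    size = min_module_size if min_module_size is not None else partition.min_module_size
    m01 = partition.units["M01"]
    if len(m01) < 2 * size:
        logger.info("M01 has %d genes (< %d); not sub-grouped", len(m01), 2 * size)
        return partition

    sub = nx.Graph()
    sub.add_nodes_from(sorted(m01))
    sub.add_edges_from(sorted((min(a, b), max(a, b)) for a, b in net.subgraph(m01).edges))
    communities = [set(c) for c in nx.community.greedy_modularity_communities(sub)]

    # merge tiny communities into the neighbour community with most edges
    def edges_between(c1, c2):
        return sum(1 for a in c1 for b in sub.neighbors(a) if b in c2)

    communities.sort(key=lambda c: (-len(c), min(c)))
    changed = True
    while changed and len(communities) > 1:
        changed = False
        for i, c in enumerate(communities):
            if len(c) < size:
                others = [j for j in range(len(communities)) if j != i]
                best = max(
                    others,
                    key=lambda j: (edges_between(c, communities[j]),
                                   len(communities[j]), min(communities[j])),
                )
                communities[best] |= c
                del communities[i]
                changed = True
                break
    communities.sort(key=lambda c: (-len(c), min(c)))

    units: dict[str, tuple] = {}
    kinds: dict[str, str] = {}
    if len(communities) == 1:
        units["M01"] = m01
        kinds["M01"] = "giant"
    else:
        for label, comm in zip(_letters(len(communities)), communities):
            uid = f"M01{label}"
            units[uid] = tuple(sorted(comm))
            kinds[uid] = "giant_subgroup"
    for uid, genes in partition.units.items():
        if uid != "M01":
            units[uid] = genes
            kinds[uid] = partition.kinds[uid]
    out = ModulePartition(units=units, kinds=kinds, min_module_size=partition.min_module_size)
    assert out.gene_universe == partition.gene_universe
    return out
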