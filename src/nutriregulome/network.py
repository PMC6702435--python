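"""Marker-seeded coexpression network extraction.

The MR table is thresholded at a ceiling (default 5) and the network is
the subgraph induced on all genes within graph distance ``tier_depth``
(default 2, i.e. up to second-tier neighbours) of any seed marker gene.
Edges between two tier-2 nodes are retained whenever their MR passes the
ceiling (induced subgraph, not an expansion tree).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


def extract_network(
    mr_table: pd.DataFrame,
    seeds,
    mr_max: float = 5.0,
    tier_depth: int = 2,
    gene_universe=None,
) -> nx.Graph:
    """Extract the seeded network from a mutual rank table.

    Parameters
    ----------
    mr_table
        Table with columns ``gene_a, gene_b, mr`` (output of
        :func:`nutriregulome.mutual_rank.mutual_rank`).
    seeds
        Marker table (with a ``gene`` column) or an iterable of gene ids.
    mr_max
        MR ceiling; only pairs with MR <= ceiling form edges.
    tier_depth
        Maximum graph distance from a seed (0 = seed itself).
    gene_universe
        Optional explicit gene universe; defaults to all genes appearing
        in the MR table.  Seeds absent from the universe raise an error.

    Returns
    -------
    networkx.Graph with node attributes ``is_seed`` (bool) and ``tier``
    (minimum distance to a seed) and edge attribute ``mr``.
    """
    if mr_max < 1:
        raise ValidationError("mr_max must be >= 1 (MR is never below 1)")
    seed_genes = set(seeds["gene"]) if isinstance(seeds, pd.DataFrame) else set(seeds)
    if not seed_genes:
        raise ValidationError("extract_network: empty seed set")

    if gene_universe is None:
        gene_universe = set(mr_table["gene_a"]) | set(mr_table["gene_b"])
    else:
        gene_universe = set(gene_universe)
    missing = sorted(seed_genes - gene_universe)
    if missing:
        raise ValidationError(
            f"{len(missing)} seed gene(s) absent from the MR gene universe: {missing[:10]}"
        )

    kept = mr_table[mr_table["mr"] <= mr_max]
    full = nx.Graph()
    full.add_nodes_from(sorted(seed_genes))
    for a, b, w in kept[["gene_a", "gene_b", "mr"]].itertuples(index=False):
        if a != b:
            full.add_edge(a, b, mr=float(w))

    tiers = nx.multi_source_dijkstra_path_length(
        full, seed_genes, cutoff=tier_depth, weight=None
    )
    keep_nodes = sorted(tiers)
    isolated = [g for g in seed_genes if full.degree(g) == 0]
    if isolated:
        logger.info("%d seed gene(s) isolated under MR <= %s", len(isolated), mr_max)

    net = nx.Graph()
    for g in keep_nodes:
        net.add_node(g, is_seed=g in seed_genes, tier=int(tiers[g]))
    for a, b, data in full.subgraph(keep_nodes).edges(data=True):
        net.add_edge(a, b, mr=data["mr"])
    logger.info(
        "extracted network: %d nodes (%d seeds), %d edges",
        net.number_of_nodes(), len(seed_genes & set(keep_nodes)), net.number_of_edges(),
    )
    return net
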