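#!/usr/bin/env python
"""Compute mutual ranks and extract the marker-seeded coexpression network.

Writes the thresholded MR table, the network GraphML and an edge list.
"""

import argparse
from pathlib import Path

import nutriregulome as nr
from nutriregulome import io as nio


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--mr-max", type=float, default=5.0)
    ap.add_argument("--depth", type=int, default=2)
    args = ap.parse_args()

    expr = nio.read_expression(args.datadir / "expression.tsv")
    markers = nio.read_markers(args.outdir / "markers.tsv")
    corr = nr.correlation_matrix(expr)
    mr = nr.mutual_rank(corr)
    nio.write_mr_table(mr[mr["mr"] <= args.mr_max], args.outdir / "mr.tsv")
    net = nr.extract_network(mr, markers, mr_max=args.mr_max,
                             tier_depth=args.depth, gene_universe=corr.index)
    nio.write_network(net, args.outdir / "network.graphml")
    nio.write_edge_list(net, args.outdir / "edges.tsv")

    seeds = sum(1 for _, d in net.nodes(data=True) if d["is_seed"])
    print(f"{len(markers['gene'].unique())} seed genes -> network of "
          f"{net.number_of_nodes()} genes ({seeds} seeds) and "
          f"{net.number_of_edges()} edges at MR <= {args.mr_max}, "
          f"tier depth {args.depth}")


if __name__ == "__main__":
    main()
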