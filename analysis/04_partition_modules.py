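#!/usr/bin/env python
"""Partition the network into response units and compare with the truth.

Writes results/partition.tsv and results/unit_summary.tsv.
"""

import argparse
from pathlib import Path

import nutriregulome as nr
from nutriregulome import io as nio
from nutriregulome.evaluation import partition_jaccard
from nutriregulome.reporting import network_sentence, partition_report
from nutriregulome.simulate import GroundTruth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--min-size", type=int, default=4)
    args = ap.parse_args()

    net = nio.read_network(args.outdir / "network.graphml")
    part = nr.subgroup_giant(net, nr.find_modules(net, args.min_size))
    nio.write_partition(part, args.outdir / "partition.tsv")
    part.summary().to_csv(args.outdir / "unit_summary.tsv", sep="\t", index=False)

    print(network_sentence(partition_report(part)))
    truth = GroundTruth.from_json(args.datadir / "truth.json")
    pj = partition_jaccard(part, truth)
    print(f"mean best-match Jaccard vs planted modules: {pj['mean_jaccard']:.3f} "
          f"(gene recall into the network: {pj['gene_recall']:.1%})")


if __name__ == "__main__":
    main()
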