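#!/usr/bin/env python
"""Map TFs to target units from binding evidence; classify general vs
specialized regulators and tally protein families.

Writes results/regmap.tsv and results/family_counts.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

import nutriregulome as nr
from nutriregulome import io as nio
from nutriregulome.evaluation import tf_mapping_scores
from nutriregulome.regulators import classify_regulators, summarize_families
from nutriregulome.simulate import GroundTruth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=1e-3)
    args = ap.parse_args()

    part = nio.read_partition(args.outdir / "partition.tsv")
    evidence = nio.read_evidence(args.datadir / "evidence.tsv")
    markers = nio.read_markers(args.outdir / "markers.tsv")
    truth = GroundTruth.from_json(args.datadir / "truth.json")

    regmap = nr.map_regulators(evidence, part, motif_alpha=args.alpha)
    nio.write_regmap(regmap, args.outdir / "regmap.tsv")
    summary = classify_regulators(
        regmap, n_analyzed_units=len(part.analyzed_units),
        network_genes=part.gene_universe, marker_genes=set(markers["gene"]),
        tf_gene_map=truth.tf_genes,
    )
    families = pd.read_csv(args.datadir / "families.tsv", sep="\t")
    counts = summarize_families(families, regmap)
    counts.to_csv(args.outdir / "family_counts.tsv", sep="\t")

    print(f"{summary.n_tfs} regulators mapped over {len(part.analyzed_units)} "
          f"analyzed units; {summary.n_multi_target} target >=2 units")
    print(f"general-regulator threshold: >{len(part.analyzed_units)}*10% -> "
          f">={summary.general_threshold} units; general: "
          f"{', '.join(summary.general_tfs) or 'none'}")
    print(f"{summary.n_in_network} regulator genes are network members, "
          f"{summary.n_network_markers} of them markers")
    scores = tf_mapping_scores(regmap, part, truth)
    print(f"vs planted targets: precision {scores['precision']:.1%}, "
          f"recall {scores['recall']:.1%}")


if __name__ == "__main__":
    main()
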