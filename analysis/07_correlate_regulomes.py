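#!/usr/bin/env python
"""Map TF-perturbation DEG lists onto the network, score the
prediction-observation overlap, and correlate regulomes with the stress
signatures.

Writes results/overlap.tsv and results/regulome_correlation.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nutriregulome import io as nio
from nutriregulome.regulators import target_sets
from nutriregulome.regulome import (
    prediction_overlap,
    regulome_profile,
    signature_correlation,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--band", type=float, default=0.24)
    args = ap.parse_args()

    part = nio.read_partition(args.outdir / "partition.tsv")
    sig = nio.read_signature(args.outdir / "signature.tsv")
    predicted = target_sets(nio.read_regmap(args.outdir / "regmap.tsv"))

    overlaps, reports = [], []
    for path in sorted((args.datadir / "tf_degs").glob("*.tsv")):
        tf = path.stem
        deg = pd.read_csv(path, sep="\t", dtype={"gene": str})
        profile = regulome_profile(deg, part, tf=tf)
        ov = prediction_overlap(profile, predicted.get(tf, set()))
        overlaps.append((tf, profile.n_de_genes, ov.n_regulated, ov.n_overlap,
                         float("nan") if ov.percent is None else ov.percent))
        reports.append(signature_correlation(profile, sig, band=args.band))

    overlap_df = pd.DataFrame(
        overlaps, columns=["tf", "n_de_genes", "n_regulated", "n_overlap", "overlap_pct"]
    )
    overlap_df.to_csv(args.outdir / "overlap.tsv", sep="\t", index=False)
    corr = pd.concat(reports, ignore_index=True)
    nio.write_correlation_report(corr, args.outdir / "regulome_correlation.tsv")

    print("prediction-observation overlap per TF:")
    for _, row in overlap_df.iterrows():
        pct = "undefined" if pd.isna(row["overlap_pct"]) else f"{row['overlap_pct']:.1f}%"
        print(f"  {row['tf']}: {pct} ({row['n_overlap']}/{row['n_regulated']} "
              f"regulated units predicted)")
    considered = corr[corr["considered"]]
    print(f"{len(considered)} considered TF-condition correlations "
          f"(|r| >= {args.band}) of {len(corr)}; strongest:")
    top = considered.reindex(considered["r"].abs().sort_values(ascending=False).index)
    for _, row in top.head(5).iterrows():
        print(f"  {row['tf']} ~ {row['condition']}: r = {row['r']:+.2f}")


if __name__ == "__main__":
    main()
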