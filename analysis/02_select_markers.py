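#!/usr/bin/env python
"""Select cross-study consistent marker genes and summarise their sharing.

Reads results/data/, writes results/markers.tsv and
results/marker_overlap.tsv, and reports recovery of the planted markers.
"""

import argparse
from pathlib import Path

import nutriregulome as nr
from nutriregulome import io as nio
from nutriregulome.evaluation import marker_recovery
from nutriregulome.simulate import GroundTruth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--min-studies", type=int, default=2)
    ap.add_argument("--min-fraction", type=float, default=1.0)
    args = ap.parse_args()

    deg = nio.read_deg_tables(args.datadir / "deg.tsv")
    markers = nr.select_markers(deg, args.min_studies, args.min_fraction)
    nio.write_markers(markers, args.outdir / "markers.tsv")
    overlap = nr.marker_overlap(markers)
    overlap["matrix"].to_csv(args.outdir / "marker_overlap.tsv", sep="\t")

    print(f"{len(markers)} marker records across "
          f"{markers['condition'].nunique()} conditions")
    print(f"{overlap['shared_ge2']} genes shared by >=2 conditions, "
          f"{overlap['shared_ge3']} by >=3; most-shared gene(s) "
          f"{overlap['max_sharing_genes'][:3]} in {overlap['max_sharing']} sets")

    truth = GroundTruth.from_json(args.datadir / "truth.json")
    rec = marker_recovery(markers, truth)
    print(f"recovery vs planted truth: sensitivity {rec['sensitivity']:.1%}, "
          f"false records {rec['false_rate']:.1%} of output")


if __name__ == "__main__":
    main()
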