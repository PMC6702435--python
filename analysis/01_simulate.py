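#!/usr/bin/env python
"""Generate the synthetic nutrient-stress compendium.

Writes the expression matrix, per-study DEG tables, TF binding evidence,
per-TF perturbation DEG lists, and the planted ground truth under
results/data/.
"""

import argparse
from pathlib import Path

import nutriregulome as nr
from nutriregulome import io as nio


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = nr.default_config(seed=args.seed)
    expr, truth = nr.generate_compendium(cfg)
    deg = nr.generate_deg_tables(expr, truth)
    evidence, families = nr.generate_tf_evidence(truth)
    tf_degs = nr.generate_tf_perturbation_degs(truth)

    out = args.outdir
    nio.write_expression(expr, out / "expression.tsv")
    nio.write_deg_tables(deg, out / "deg.tsv")
    nio.write_evidence(evidence, out / "evidence.tsv")
    families.to_csv(out / "families.tsv", sep="\t", index=False)
    tf_dir = out / "tf_degs"
    tf_dir.mkdir(parents=True, exist_ok=True)
    for tf, table in tf_degs.items():
        table.to_csv(tf_dir / f"{tf}.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")

    n_markers = sum(len(v) for v in truth.markers.values())
    print(f"compendium: {expr.shape[0]} genes x {expr.shape[1]} samples "
          f"({cfg.n_conditions} conditions x {cfg.studies_per_condition} studies "
          f"x 2 arms x {cfg.replicates_per_arm} replicates)")
    print(f"planted: {cfg.n_modules} modules ({sum(cfg.module_sizes)} genes), "
          f"{n_markers} marker records, {len(truth.tf_targets)} TFs")
    print(f"DEG table: {len(deg)} significant per-study calls; "
          f"evidence: {len(evidence)} records")


if __name__ == "__main__":
    main()
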