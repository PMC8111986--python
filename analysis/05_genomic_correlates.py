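#!/usr/bin/env python
"""Genomic correlates of the immune classes: copy-number burden and
segment counts, arm-level aneuploidy, the leukocyte-fraction association
with segment counts, frequently mutated genes and mutational-signature
extraction with the cosine match against the packaged reference.
"""

import argparse
import sys

import pandas as pd

from immunodissect.pipeline import PipelineConfig, run_pipeline


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results/analysis")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = PipelineConfig(
        out_dir=args.out_dir, seed=args.seed,
        stages=["simulate", "score", "nmf", "classify", "cnv", "mutsig"],
    )
    run_pipeline(cfg)

    labels = pd.read_csv(
        f"{args.out_dir}/class_labels.tsv", sep="\t", index_col=0
    )["class"]
    fga = pd.read_csv(
        f"{args.out_dir}/fraction_genome_altered.tsv", sep="\t", index_col=0
    )
    print("fraction genome altered by class (mean):")
    print(fga["fraction_altered"].groupby(labels).mean().round(3).to_string())
    print("\nsegment counts by class (mean):")
    print(fga["n_segments"].groupby(labels).mean().round(1).to_string())

    corr = pd.read_csv(
        f"{args.out_dir}/leukocyte_cnv_correlation.tsv", sep="\t", index_col=0
    )
    print("\nleukocyte fraction vs segment count (Spearman):")
    print(corr.round(4).to_string())

    match = pd.read_csv(
        f"{args.out_dir}/signature_match.tsv", sep="\t", index_col=0
    )
    print("\nextracted-signature best reference match (cosine):")
    print(match.max(axis=1).round(3).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
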