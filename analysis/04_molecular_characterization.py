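#!/usr/bin/env python
"""Characterize the classes molecularly: differential expression between
immune and non-immune (FDR < 0.05, |log2 FC| > 1), preranked GSEA on the
t-statistic ranking, and the differential miRNA / lncRNA / protein layers.
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
        stages=["simulate", "score", "nmf", "classify", "de", "gsea"],
    )
    run_pipeline(cfg)

    de = pd.read_csv(
        f"{args.out_dir}/de_immune_vs_nonimmune.tsv", sep="\t", index_col=0
    )
    up = ((de["pass"]) & (de["direction"] == "up")).sum()
    down = ((de["pass"]) & (de["direction"] == "down")).sum()
    print(f"differential genes (immune vs non-immune): {up} up, {down} down")
    for layer in ["mirna", "lncrna", "protein"]:
        tab = pd.read_csv(
            f"{args.out_dir}/de_{layer}.tsv", sep="\t", index_col=0
        )
        print(f"differential {layer}: {int(tab['pass'].sum())} features")
    gsea = pd.read_csv(f"{args.out_dir}/gsea_results.tsv", sep="\t", index_col=0)
    print("\ntop enriched sets (by |NES|):")
    print(
        gsea.reindex(gsea["nes"].abs().sort_values(ascending=False).index)
        [["es", "nes", "p_value", "fdr"]].head(5).round(3).to_string()
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
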