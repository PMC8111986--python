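"""Plain-text table input/output for the pipeline's standard formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SEG_HEADER = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV with gene identifiers in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t")


def read_segments(path: str | Path) -> pd.DataFrame:
    """SEG file (tab-separated, standard header) to the internal column names."""
    df = pd.read_csv(path, sep="\t")
    rename = {
        "Sample": "sample", "Chromosome": "chromosome", "Start": "start",
        "End": "end", "Num_Probes": "num_mark", "Segment_Mean": "seg_mean",
    }
    df = df.rename(columns=rename)
    df["chromosome"] = df["chromosome"].astype(str)
    return df


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    out = segments.rename(
        columns={
            "sample": "Sample", "chromosome": "Chromosome", "start": "Start",
            "end": "End", "num_mark": "Num_Probes", "seg_mean": "Segment_Mean",
        }
    )
    cols = [c for c in SEG_HEADER if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    return df


def write_maf(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)
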