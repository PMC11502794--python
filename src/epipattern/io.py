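"""Plain-text readers and writers (TSV / BED dialects)."""

from __future__ import annotations

import pandas as pd


def write_methylation_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_methylation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"methylation table needs columns {sorted(required)}")
    meth_cols = [c for c in df.columns if c.startswith("meth_")]
    for mc in meth_cols:
        tc = "total_" + mc[len("meth_"):]
        if tc not in df.columns:
            raise ValueError(f"missing {tc} for {mc}")
        if ((df[mc] < 0) | (df[mc] > df[tc])).any():
            raise ValueError("need 0 <= methylated <= total")
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_count_matrix(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    if (df < 0).any().any():
        raise ValueError("counts must be non-negative")
    return df


def write_annotation_bed(genes: pd.DataFrame, path) -> None:
    """BED6 plus an is_tf column (0/1)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
            "is_tf": genes["is_tf"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "is_tf"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    if df["name"].duplicated().any():
        raise ValueError("gene ids must be unique")
    return pd.DataFrame(
        {
            "gene_id": df["name"],
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "strand": df["strand"],
            "is_tf": df["is_tf"].astype(bool),
        }
    )
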