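"""Reading and writing the tab-separated input tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_expression(path: str | Path) -> pd.DataFrame:
    """Probes x samples matrix, TSV with a header row of sample ids and the
    probe id as first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    for col in ("is_case", "hypertension", "smoking_ever", "familial_ia"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    for col in ("is_specific", "is_retired", "is_sex_check_probe"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
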