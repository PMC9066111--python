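"""Readers and writers for the plain-text formats the pipeline speaks.

Conventions, stated once to prevent off-by-one drift:
  * BED / BED12 / narrowPeak / bedGraph coordinates are 0-based half-open.
  * HiC-Pro-dialect triplet ``.matrix`` files carry 1-based bin IDs and the
    upper triangle only; the companion bin ``.bed`` is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                   "signal", "pvalue", "qvalue", "summit"]
BED12_COLS = ["chrom", "start", "end", "name", "score", "strand",
              "thickStart", "thickEnd", "itemRgb", "blockCount",
              "blockSizes", "blockStarts"]


def read_bed(path, names=("chrom", "start", "end", "name", "score", "strand")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=NARROWPEAK_COLS)
    if df.shape[1] != 10:
        raise ValueError(f"{path}: narrowPeak requires 10 columns, got {df.shape[1]}")
    df.columns = NARROWPEAK_COLS
    bad = (df["summit"] != -1) & ((df["summit"] < 0) |
                                  (df["summit"] >= df["end"] - df["start"]))
    if bad.any():
        raise ValueError(f"{path}: summit offset outside peak at line {bad.idxmax() + 1}")
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=NARROWPEAK_COLS, float_format="%.6g")


def peak_summits(peaks: pd.DataFrame) -> np.ndarray:
    """Absolute summit position per peak; midpoint when summit offset is -1."""
    mid = (peaks["start"] + peaks["end"]) // 2
    has = peaks["summit"].to_numpy() != -1
    return np.where(has, peaks["start"].to_numpy() + peaks["summit"].to_numpy(),
                    mid.to_numpy())


def read_bed12(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] != 12:
        raise ValueError(f"{path}: BED12 requires 12 columns, got {df.shape[1]}")
    df.columns = BED12_COLS
    for i, row in df.iterrows():
        sizes = _int_list(row["blockSizes"])
        starts = _int_list(row["blockStarts"])
        if len(sizes) != row["blockCount"] or len(starts) != row["blockCount"]:
            raise ValueError(f"{path}: malformed BED12 blocks at line {i + 1}")
        if starts and row["start"] + starts[-1] + sizes[-1] > row["end"]:
            raise ValueError(f"{path}: blocks exceed interval at line {i + 1}")
    return df


def write_bed12(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED12_COLS)


def _int_list(csv: str) -> list[int]:
    return [int(v) for v in str(csv).rstrip(",").split(",") if v != ""]


def gene_tss(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware transcription start site (start if +, end if -)."""
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy())


def gene_tes(genes: pd.DataFrame) -> np.ndarray:
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["end"].to_numpy(), genes["start"].to_numpy())


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"], float_format="%.6g")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_keyvalue(d: dict, path) -> None:
    lines = [f"{k}\t{d[k]}" for k in d]
    Path(path).write_text("\n".join(lines) + "\n")


def read_keyvalue(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        k, v = line.split("\t", 1)
        out[k] = v
    return out
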