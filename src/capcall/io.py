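"""Plain-text readers/writers for the pipeline's tabular interchange formats.

Coordinates are 0-based, half-open everywhere (BED/bedGraph native; GTF is
converted on read by the annotation module).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

TAG_COLUMNS = ["chrom", "pos", "strand", "umi", "sample", "name", "mapq"]


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    if not sizes:
        raise ValueError(f"no chromosomes found in {path}")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


def read_tag_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "umi": str, "sample": str})
    missing = [c for c in ("chrom", "pos", "strand") if c not in df.columns]
    if missing:
        raise ValueError(f"tag table {path} lacks columns {missing}")
    return df


def write_tag_table(tags: pd.DataFrame, path: str) -> None:
    cols = [c for c in TAG_COLUMNS if c in tags.columns]
    out = tags[cols].sort_values(
        [c for c in ("chrom", "pos", "strand", "umi", "name") if c in cols],
        kind="mergesort",
    )
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> dict[str, str]:
    """TSV of sample name -> index sequence (header optional)."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2 or parts[0].lower() in ("sample", "name"):
                continue
            entries[parts[0]] = parts[1].upper()
    return entries


def write_bed(df: pd.DataFrame, path: str, score_col: str = "score") -> None:
    """BED6; scores capped to [0, 1000] per BED convention."""
    out = df.copy()
    name = out["name"] if "name" in out else [f"tss_{i}" for i in range(len(out))]
    score = np.clip(out[score_col].to_numpy(float), 0, 1000) if score_col in out else 0
    bed = pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["start"].astype(int),
            "end": out["end"].astype(int),
            "name": name,
            "score": np.round(score, 3),
            "strand": out["strand"],
        }
    ).sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
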