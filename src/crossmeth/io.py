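"""Readers and writers for the plain-text formats used across the package.

Beta-value, detection-p and bead-count matrices are tab-delimited with probes
as rows (first column = probe ID, header row = sample IDs); a ``.gz`` suffix
triggers gzip compression transparently.  Sample sheets, probe annotation and
planted-truth tables are CSV.  Interval sets are BED3+ (0-based, half-open).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_bed",
    "write_bed",
    "read_probe_list",
    "write_probe_list",
    "write_json",
    "read_json",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample matrix (TSV, first column = probe ID)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index_label=None) -> None:
    df.to_csv(path, index_label=index_label)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into columns (chrom, start, end[, name...])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, ncol)]
    if ncol >= 4:
        names[3] = "name"
    df.columns = names[:ncol]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_probe_list(path: str | Path) -> set[str]:
    """One probe ID per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_probe_list(probes, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(probes)) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
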