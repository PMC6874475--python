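"""Readers and writers for the pipeline's plain-text table formats.

Everything is TSV with a header except BED/bedGraph tracks; coordinates
are 0-based half-open throughout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SITE_COUNT_COLUMNS = ["chrom", "start", "strand", "u_bs", "c_bs", "u_ox", "c_ox"]


def read_site_counts(path: str | Path) -> pd.DataFrame:
    """Load a per-CpG BS/OxBS count table, validating the schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("u_bs", "c_bs", "u_ox", "c_ox"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(f"{path}: negative {col} at line {bad[0] + 2}")
    return df


def write_site_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a 3+ column BED file into chrom/start/end, with line numbers on error."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or end < start:
            raise ValueError(f"{path}:{lineno}: malformed interval {start}-{end}")
        rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Long-format HELP array probe intensities: fragment, sample, probe, hpaii, mspi."""
    df = pd.read_csv(path, sep="\t")
    required = ["fragment", "sample", "hpaii", "mspi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample log-expression matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_mid_signals(path: str | Path) -> pd.DataFrame:
    """Isotopomer signal table: metabolite, m0..mn columns, internal_standard."""
    df = pd.read_csv(path, sep="\t")
    if "metabolite" not in df.columns or "internal_standard" not in df.columns:
        raise ValueError(f"{path}: need 'metabolite' and 'internal_standard' columns")
    return df
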