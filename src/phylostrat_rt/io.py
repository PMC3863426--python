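"""Readers and writers for the plain-text interchange formats.

All tables move as TSV; gene annotations as BED6 (0-based half-open);
trees as one NHX file per family.  pandas does the parsing — these helpers
only pin column names and dtypes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cnv import CopyNumberMatrix
from .errors import DataError
from .regions import ChromosomeMap
from .replication_timing import HIGHER_IS_EARLIER, RTProbeSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_map",
    "read_copy_number",
    "read_probes",
]

_BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 gene table (chrom, start, end, gene_id, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise DataError(f"{path}: BED needs at least 4 columns")
    df = df.iloc[:, : len(_BED_COLUMNS)]
    df.columns = _BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise DataError(f"{path}: non-positive gene span")
    return df


def write_bed(genes: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLUMNS if c in genes.columns]
    genes[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_map(path) -> ChromosomeMap:
    df = pd.read_csv(path, sep="\t")
    return ChromosomeMap(df)


def read_copy_number(path, genes: pd.DataFrame) -> CopyNumberMatrix:
    copies = pd.read_csv(path, sep="\t", index_col=0)
    return CopyNumberMatrix(
        copies=copies, genes=genes.set_index("gene_id")[["chrom", "start", "end"]]
    )


def read_probes(path, sign_convention: str = HIGHER_IS_EARLIER) -> RTProbeSet:
    """Read a probe TSV (chrom, pos, one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise DataError(f"{path}: probe table needs 'chrom' and 'pos' columns")
    return RTProbeSet(probes=df, sign_convention=sign_convention)


def read_probes_bedgraph(paths: dict, sign_convention: str = HIGHER_IS_EARLIER) -> RTProbeSet:
    """Build a probe set from one bedGraph per sample (position = interval
    midpoint); samples are aligned on (chrom, pos)."""
    from .replication_timing import read_bedgraph

    merged = None
    for sample, path in paths.items():
        df = read_bedgraph(path, sample)
        merged = df if merged is None else merged.merge(df, on=["chrom", "pos"])
    if merged is None:
        raise DataError("no bedGraph files given")
    return RTProbeSet(probes=merged, sign_convention=sign_convention)


def ensure_outdir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
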