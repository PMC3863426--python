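"""Chromosomal-region stratification: pericentromeric / subtelomeric /
interstitial.

A gene is pericentromeric when its center lies within ``window`` (default
5 Mb) of the centromere interval (distance 0 inside the interval),
otherwise subtelomeric when within ``window`` of either chromosome end, and
interstitial otherwise.  "Within" is inclusive, and the pericentromeric
label takes precedence when both windows cover a gene — relevant on short
or acrocentric chromosomes, where the centromere abuts position 0 and the
first megabases are pericentromeric, not subtelomeric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ChromosomeMap", "RegionParameters", "classify_gene_region"]


@dataclass
class ChromosomeMap:
    """Per-chromosome lengths and centromere intervals.

    ``table`` needs columns ``chrom, length, cen_start, cen_end`` with
    0 <= cen_start < cen_end <= length.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"chrom", "length", "cen_start", "cen_end"}
        if missing := required - set(t.columns):
            raise DataError(f"chromosome map missing columns: {sorted(missing)}")
        if t["chrom"].duplicated().any():
            raise DataError("duplicate chromosomes in map")
        bad = ~(
            (0 <= t["cen_start"])
            & (t["cen_start"] < t["cen_end"])
            & (t["cen_end"] <= t["length"])
        )
        if bad.any():
            raise DataError(
                f"invalid centromere interval for: {list(t.loc[bad, 'chrom'][:5])}"
            )

    def is_acrocentric(self, chrom: str) -> bool:
        row = self.table.set_index("chrom").loc[chrom]
        return int(row["cen_start"]) == 0


@dataclass(frozen=True)
class RegionParameters:
    window: int = 5_000_000

    def __post_init__(self):
        if self.window <= 0:
            raise DataError("region window must be positive")


def classify_gene_region(
    genes: pd.DataFrame,
    chrom_map: ChromosomeMap,
    params: RegionParameters = RegionParameters(),
) -> pd.DataFrame:
    """Label each gene pericentromeric / subtelomeric / interstitial.

    *genes* needs columns ``gene_id, chrom, start, end``; distances are
    measured from the gene center (floor midpoint).  Returns columns
    ``gene_id, region, dist_centromere, dist_telomere``.
    """
    cmap = chrom_map.table.set_index("chrom")
    unknown = set(genes["chrom"]) - set(cmap.index)
    if unknown:
        raise DataError(f"gene chromosome(s) not in map: {sorted(unknown)[:5]}")

    centers = ((genes["start"].to_numpy() + genes["end"].to_numpy()) // 2).astype(
        np.int64
    )
    length = cmap.loc[genes["chrom"], "length"].to_numpy(dtype=np.int64)
    cen_start = cmap.loc[genes["chrom"], "cen_start"].to_numpy(dtype=np.int64)
    cen_end = cmap.loc[genes["chrom"], "cen_end"].to_numpy(dtype=np.int64)

    outside = (centers < 0) | (centers >= length)
    if outside.any():
        bad = genes.loc[outside, "gene_id"]
        raise DataError(f"gene center outside chromosome for: {list(bad[:5])}")

    # distance to the nearest edge of the centromere interval, 0 inside it
    dist_cen = np.maximum(
        np.maximum(cen_start - centers, centers - (cen_end - 1)), 0
    )
    dist_tel = np.minimum(centers, length - centers)

    region = np.where(
        dist_cen <= params.window,
        "pericentromeric",
        np.where(dist_tel <= params.window, "subtelomeric", "interstitial"),
    )
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "region": region,
            "dist_centromere": dist_cen,
            "dist_telomere": dist_tel,
        }
    )
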