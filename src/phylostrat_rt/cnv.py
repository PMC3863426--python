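"""Copy-number-variable (CNV) gene classification.

A gene is called CNV when its estimated copy number is >= 4 (gain) or < 2
(loss) in at least ``min_individuals`` individuals of the panel; the two
criteria are evaluated independently and either suffices.  Genes shorter
than 1 kb (unreliable copy-number estimates) and non-autosomal genes are
excluded before calling.  A length of exactly 1,000 bp is kept: only genes
strictly smaller than 1 kb are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .timelines import PhylostratumTimeline

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberMatrix",
    "CNVCallParameters",
    "call_cnv_genes",
    "cnv_by_age_table",
    "is_autosome",
]

_NON_AUTOSOMES = {"x", "y", "z", "w", "m", "mt", "chrx", "chry", "chrm", "chrmt"}


def is_autosome(chrom: str) -> bool:
    """Heuristic autosome check on common chromosome naming (chrX/X/Y/MT
    and friends are non-autosomal; everything else counts as autosomal)."""
    return str(chrom).lower() not in _NON_AUTOSOMES


@dataclass
class CopyNumberMatrix:
    """Integer copy numbers per gene and individual, plus gene coordinates.

    ``copies`` is a gene x individual DataFrame (index = gene_id);
    ``genes`` holds columns chrom, start, end (0-based half-open) indexed by
    gene_id and must cover every row of ``copies``.
    """

    copies: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self):
        if self.copies.shape[1] == 0:
            raise DataError("copy-number matrix has no individuals")
        if not self.copies.index.is_unique:
            raise DataError("duplicate gene ids in copy-number matrix")
        missing = self.copies.index.difference(self.genes.index)
        if len(missing):
            raise DataError(f"genes without coordinates: {list(missing[:5])}")
        values = self.copies.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.mod(values, 1) == 0):
                raise DataError("copy numbers must be integers")
            self.copies = self.copies.astype(int)
        if (self.copies.to_numpy() < 0).any():
            raise DataError("copy numbers must be non-negative")
        g = self.genes.loc[self.copies.index]
        if (g["end"] <= g["start"]).any():
            bad = g.index[g["end"] <= g["start"]]
            raise DataError(f"non-positive gene length for: {list(bad[:5])}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.copies.columns)


@dataclass(frozen=True)
class CNVCallParameters:
    """Thresholds for the CNV call.

    gain_threshold is inclusive (>= 4 copies is a gain); loss_threshold is an
    exclusive lower bound (< 2 copies is a loss, so copy number 0 counts).
    Setting ``loss_threshold = 0`` turns losses off (gains-only mode).
    """

    min_gene_length: int = 1000
    gain_threshold: int = 4
    loss_threshold: int = 2
    min_individuals: int = 2
    autosomes_only: bool = True

    def __post_init__(self):
        if self.min_individuals < 1:
            raise DataError("min_individuals must be >= 1")
        if self.gain_threshold <= self.loss_threshold:
            raise DataError("gain_threshold must exceed loss_threshold")


def call_cnv_genes(
    matrix: CopyNumberMatrix, params: CNVCallParameters = CNVCallParameters()
) -> pd.DataFrame:
    """Classify every gene as CNV / NON_CNV / EXCLUDED.

    Returns a DataFrame with columns ``gene_id, status, exclusion_reason,
    n_gain, n_loss`` in the input gene order.  Exclusions (too short /
    non-autosomal) are applied before the thresholds are evaluated.
    """
    genes = matrix.genes.loc[matrix.copies.index]
    copies = matrix.copies.to_numpy()

    n_gain = (copies >= params.gain_threshold).sum(axis=1)
    n_loss = (copies < params.loss_threshold).sum(axis=1)

    length = (genes["end"] - genes["start"]).to_numpy()
    too_short = length < params.min_gene_length
    non_auto = (
        ~genes["chrom"].map(is_autosome).to_numpy()
        if params.autosomes_only
        else np.zeros(len(genes), dtype=bool)
    )

    status = np.where(
        (n_gain >= params.min_individuals) | (n_loss >= params.min_individuals),
        "CNV",
        "NON_CNV",
    )
    reason = np.full(len(genes), "", dtype=object)
    # too_short takes precedence when both exclusions apply
    reason[non_auto] = "non_autosomal"
    reason[too_short] = "too_short"
    excluded = too_short | non_auto
    status = np.where(excluded, "EXCLUDED", status)

    return pd.DataFrame(
        {
            "gene_id": matrix.copies.index,
            "status": status,
            "exclusion_reason": reason,
            "n_gain": n_gain,
            "n_loss": n_loss,
        }
    ).reset_index(drop=True)


def cnv_by_age_table(
    calls: pd.DataFrame,
    ages: pd.DataFrame,
    timeline: Optional[PhylostratumTimeline] = None,
    include_singletons: bool = True,
) -> pd.DataFrame:
    """Cross-tabulate CNV status against duplication age class.

    Joins CNV calls and age assignments on gene_id, drops EXCLUDED and
    UNASSIGNED genes (with logged counts) and returns one row per
    phylostratum ordered oldest -> youngest — columns ``age_class_index,
    age_class_label, n_cnv, n_noncnv, fraction_cnv`` — plus, when
    ``include_singletons``, a trailing SINGLETON row.
    """
    merged = calls.merge(ages, on="gene_id", how="inner")
    if merged.empty:
        raise DataError("CNV calls and age assignments share no gene ids")
    n_excluded = int((merged["status_x"] == "EXCLUDED").sum())
    n_unassigned = int((merged["status_y"] == "UNASSIGNED").sum())
    if n_excluded or n_unassigned:
        logger.info(
            "cnv_by_age_table: dropping %d EXCLUDED and %d UNASSIGNED genes",
            n_excluded,
            n_unassigned,
        )
    keep = merged[(merged["status_x"] != "EXCLUDED") & (merged["status_y"] != "UNASSIGNED")]
    if not include_singletons:
        keep = keep[keep["status_y"] == "PDG"]
    if keep.empty:
        raise DataError("no genes left after exclusions in CNV-by-age table")

    rows = []
    pdg = keep[keep["status_y"] == "PDG"]
    classes = sorted(pdg["age_class_index"].dropna().unique())
    if timeline is not None:
        classes = range(1, timeline.n_classes + 1)
    for idx in classes:
        sub = pdg[pdg["age_class_index"] == idx]
        label = (
            timeline.label_of(int(idx))
            if timeline is not None
            else (sub["age_class_label"].iloc[0] if len(sub) else str(idx))
        )
        rows.append((int(idx), label, sub))
    if include_singletons:
        rows.append((None, "SINGLETON", keep[keep["status_y"] == "SINGLETON"]))

    records = []
    for idx, label, sub in rows:
        n_cnv = int((sub["status_x"] == "CNV").sum())
        n_noncnv = int((sub["status_x"] == "NON_CNV").sum())
        total = n_cnv + n_noncnv
        records.append(
            {
                "age_class_index": idx,
                "age_class_label": label,
                "n_cnv": n_cnv,
                "n_noncnv": n_noncnv,
                "fraction_cnv": n_cnv / total if total else np.nan,
            }
        )
    table = pd.DataFrame.from_records(records)
    table["age_class_index"] = pd.array(table["age_class_index"], dtype="Int64")
    return table
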