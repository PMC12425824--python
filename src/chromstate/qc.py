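"""Cell-level quality-control filters for RNA and ATAC modalities.

Boundary semantics follow the source rules literally: RNA cells with fewer
than 500 transcripts or more than 100k transcripts are removed, as are cells
with 40% or more mitochondrial reads; ATAC cells need TSS enrichment >= 4 and
>= 1,000 unique fragments, and cells with more than one million reads are
removed as putative multiplets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RnaQcThresholds:
    min_transcripts: int = 500
    max_transcripts: int = 100_000
    max_mito_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.min_transcripts >= self.max_transcripts:
            raise ValueError("min_transcripts must be below max_transcripts")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AtacQcThresholds:
    min_tss_enrichment: float = 4.0
    min_fragments: int = 1_000
    max_reads: int = 1_000_000

    def __post_init__(self) -> None:
        if (
            self.min_tss_enrichment <= 0
            or self.min_fragments <= 0
            or self.max_reads <= 0
        ):
            raise ValueError("all ATAC QC thresholds must be positive")


def rna_qc_mask(
    counts: CountMatrix,
    mito_mask: np.ndarray,
    thresholds: RnaQcThresholds = RnaQcThresholds(),
) -> np.ndarray:
    """Boolean keep-mask over cells, in matrix column order.

    A cell is kept iff total transcripts are within
    [min_transcripts, max_transcripts] and its mitochondrial fraction is
    strictly below max_mito_fraction. Zero-transcript cells are treated as
    fully mitochondrial (fraction 1) and hence removed.
    """
    mito_mask = np.asarray(mito_mask, dtype=bool)
    if mito_mask.shape[0] != counts.n_features:
        raise ValueError(
            f"mito_mask length {mito_mask.shape[0]} != {counts.n_features} genes"
        )
    totals = counts.cell_totals()
    mito_totals = np.asarray(
        counts.matrix[mito_mask, :].sum(axis=0)
    ).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning("%d zero-transcript cells removed", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero, 1.0, mito_totals / np.where(zero, 1, totals))
    keep = (
        (totals >= thresholds.min_transcripts)
        & (totals <= thresholds.max_transcripts)
        & (frac < thresholds.max_mito_fraction)
    )
    logger.info("RNA QC kept %d / %d cells", int(keep.sum()), counts.n_cells)
    return keep


def filter_rna_cells(
    counts: CountMatrix,
    mito_mask: np.ndarray,
    thresholds: RnaQcThresholds = RnaQcThresholds(),
) -> list[str]:
    """Identifiers of cells passing RNA QC, preserving matrix order."""
    keep = rna_qc_mask(counts, mito_mask, thresholds)
    return [c for c, k in zip(counts.cells, keep) if k]


def atac_qc_mask(
    fragments: np.ndarray,
    reads: np.ndarray,
    tss_enrichment: np.ndarray,
    thresholds: AtacQcThresholds = AtacQcThresholds(),
) -> np.ndarray:
    """Boolean keep-mask for ATAC cells.

    Kept iff TSS enrichment >= min_tss_enrichment, fragments >=
    min_fragments, and reads <= max_reads.
    """
    fragments = np.asarray(fragments, dtype=float)
    reads = np.asarray(reads, dtype=float)
    tss = np.asarray(tss_enrichment, dtype=float)
    if not (fragments.shape == reads.shape == tss.shape):
        raise ValueError("per-cell QC vectors must have equal length")
    if (fragments < 0).any() or (reads < 0).any() or (tss < 0).any():
        raise ValueError("per-cell QC metrics must be non-negative")
    keep = (
        (tss >= thresholds.min_tss_enrichment)
        & (fragments >= thresholds.min_fragments)
        & (reads <= thresholds.max_reads)
    )
    logger.info("ATAC QC kept %d / %d cells", int(keep.sum()), keep.size)
    return keep


def filter_atac_cells(
    cell_ids: list[str],
    fragments: np.ndarray,
    reads: np.ndarray,
    tss_enrichment: np.ndarray,
    thresholds: AtacQcThresholds = AtacQcThresholds(),
) -> list[str]:
    """Identifiers of cells passing ATAC QC, preserving input order."""
    keep = atac_qc_mask(fragments, reads, tss_enrichment, thresholds)
    if len(cell_ids) != keep.size:
        raise ValueError("cell_ids length does not match metric vectors")
    return [c for c, k in zip(cell_ids, keep) if k]
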