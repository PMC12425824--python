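"""Epithelial flagging, lineage signature scoring and marker derivation.

Clusters with >= 50% Epcam+ cells are flagged as epithelial; cells are scored
against basal / L1 / L2 / L3 (or any other) gene signatures as the mean
z-score of log-normalized expression; cells in flagged clusters take the
argmax label; markers are derived label-vs-rest by Wilcoxon rank-sum with
Benjamini-Hochberg correction and ranked by average log fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, SignatureSet

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: pseudocount added to normalized group means before the log2 fold change
LOG2FC_PSEUDOCOUNT = 1.0


def normalize_cp10k(counts: CountMatrix) -> pd.DataFrame:
    """Counts-per-10,000 per cell followed by log1p, as a genes x cells frame.

    Zero-total cells normalize to all-zero columns.
    """
    totals = counts.cell_totals().astype(float)
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    dense = counts.matrix.toarray().astype(float) * scale[None, :]
    return pd.DataFrame(
        np.log1p(dense), index=counts.features, columns=counts.cells
    )


def flag_epithelial_clusters(
    clusters: pd.Series | np.ndarray,
    epcam_positive: pd.Series | np.ndarray,
    threshold: float = 0.5,
) -> set[str]:
    """Cluster labels whose Epcam+ fraction is >= threshold (default 50%)."""
    clusters = np.asarray(clusters)
    pos = np.asarray(epcam_positive, dtype=bool)
    if clusters.shape != pos.shape:
        raise ValueError("clusters and epcam_positive must align per cell")
    flagged = set()
    for label in np.unique(clusters):
        members = clusters == label
        n = int(members.sum())
        if n == 0:  # pragma: no cover - unique() never yields empty groups
            logger.warning("empty cluster %r excluded", label)
            continue
        if pos[members].sum() / n >= threshold:
            flagged.add(label)
    return flagged


def epcam_positive_cells(counts: CountMatrix, gene: str = "Epcam") -> np.ndarray:
    """Epcam positivity as a detectable transcript: raw count >= 1."""
    try:
        row = counts.features.index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} not present in the matrix") from None
    return np.asarray(counts.matrix[row, :].todense()).ravel() >= 1


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    """Per-row z-score; zero-variance rows map to all zeros."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return z


def score_signature(expression: pd.DataFrame, signature: SignatureSet) -> pd.Series:
    """Per-cell signature score: mean over signature genes of per-gene
    z-scored (log-normalized) expression. Zero-variance genes contribute 0;
    genes missing from the matrix are dropped with a warning."""
    present = [g for g in signature.genes if g in expression.index]
    missing = set(signature.genes) - set(present)
    if missing:
        logger.warning(
            "signature %r: %d genes absent from matrix", signature.name, len(missing)
        )
    if not present:
        raise ValueError(
            f"signature {signature.name!r}: no signature gene present in the matrix"
        )
    z = _zscore_rows(expression.loc[present].to_numpy(dtype=float))
    return pd.Series(z.mean(axis=0), index=expression.columns, name=signature.name)


@dataclass(frozen=True)
class CellTypeCall:
    cell: str
    scores: dict[str, float]
    label: str
    epithelial: bool


def assign_cell_type(
    scores: pd.DataFrame,
    epithelial_cells: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Assign each cell the strictly-maximal signature label.

    ``scores`` is cells x labels; ``epithelial_cells`` is a per-cell boolean
    (membership in a flagged epithelial cluster). Cells outside flagged
    clusters, and cells whose top two scores tie exactly, are labeled
    ``unassigned``; only assigned cells are confident epithelial.
    """
    epi = np.asarray(epithelial_cells, dtype=bool)
    if epi.shape[0] != scores.shape[0]:
        raise ValueError("epithelial flags must align with score rows")
    values = scores.to_numpy(dtype=float)
    order = np.argsort(values, axis=1)
    best = order[:, -1]
    strict = values[np.arange(len(scores)), best] > (
        values[np.arange(len(scores)), order[:, -2]]
        if scores.shape[1] > 1
        else -np.inf
    )
    labels = np.where(
        epi & strict, scores.columns.to_numpy()[best], UNASSIGNED
    )
    out = scores.copy()
    out["label"] = labels
    out["epithelial"] = labels != UNASSIGNED
    return out


def derive_markers(
    expression: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    min_cells: int = 3,
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Label-vs-rest marker table.

    For each label with >= min_cells cells: per-gene two-sample Wilcoxon
    rank-sum on log-normalized expression, log2 fold change of linear-scale
    group means (with pseudocount), BH FDR within the label, and a rank over
    FDR-significant genes by descending average log fold change.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != expression.shape[1]:
        raise ValueError("labels must align with expression columns")
    uniq = []
    for lab in pd.unique(labels):
        if (labels == lab).sum() >= min_cells:
            uniq.append(lab)
        else:
            logger.warning("label %r has <%d cells; skipped", lab, min_cells)
    if len(uniq) < 2:
        raise ValueError("need >=2 labels with enough cells to derive markers")
    values = expression.to_numpy(dtype=float)
    linear = np.expm1(values)
    frames = []
    for lab in uniq:
        in_group = labels == lab
        a, b = values[:, in_group], values[:, ~in_group]
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue)
        log2fc = np.log2(
            (linear[:, in_group].mean(axis=1) + pseudocount)
            / (linear[:, ~in_group].mean(axis=1) + pseudocount)
        )
        fdr = multipletests(pvals, method="fdr_bh")[1]
        tbl = pd.DataFrame(
            {
                "label": lab,
                "gene": expression.index,
                "log2fc": log2fc,
                "fold_change": np.exp2(log2fc),
                "p_value": pvals,
                "fdr": fdr,
            }
        )
        sig = tbl["fdr"] < 0.05
        tbl["rank"] = np.nan
        tbl.loc[sig, "rank"] = (
            (-tbl.loc[sig, "log2fc"]).rank(method="first").astype(float)
        )
        frames.append(tbl.sort_values("log2fc", ascending=False, kind="stable"))
    return pd.concat(frames, ignore_index=True)


def signature_from_markers(
    markers: pd.DataFrame,
    label: str,
    padj_cutoff: float = 0.05,
    fc_cutoff: float = 2.0,
) -> SignatureSet:
    """Select a gene signature from a marker table.

    Keeps genes with FDR < padj_cutoff and fold change strictly > fc_cutoff,
    ordered by rank. Returns an empty signature (with a warning) when no gene
    qualifies.
    """
    rows = markers[
        (markers["label"] == label)
        & (markers["fdr"] < padj_cutoff)
        & (markers["fold_change"] > fc_cutoff)
    ].sort_values("rank", kind="stable")
    if rows.empty:
        logger.warning("no genes pass cutoffs for label %r; empty signature", label)
    return SignatureSet(name=label, genes=tuple(rows["gene"]))
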