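"""Motif-level analyses: family reduction, per-cell-type enrichment with
expression and correlation retention filters, and differential accessibility.

The ETS family (ERG/ETS/ETV/FLI position-weight matrices are near-identical)
is collapsed into one membership column by logical OR. Per-cell-type motif
enrichment is an upper-tail hypergeometric test of motif-accessible cells
(deviation Z > 0) within each cell type against all others, BH-corrected; an
FDR < 1e-20 display cutoff marks the motifs a heatmap would show. Candidate
motifs are retained only if their gene's normalized mean expression in the
cell type exceeds 1 and their deviation Z correlates positively (Spearman)
with the gene score.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: display cutoff for calling a motif "enriched" in a cell type
ENRICHMENT_DISPLAY_FDR = 1e-20

#: a cell is "motif-accessible" when its deviation Z exceeds this
ACCESSIBILITY_Z_THRESHOLD = 0.0


def reduce_motif_family(
    membership: pd.DataFrame,
    members: list[str],
    family_name: str,
) -> pd.DataFrame:
    """Add a family column as the logical OR of member motif columns.

    Member columns are retained. Unknown member names raise.
    """
    missing = [m for m in members if m not in membership.columns]
    if missing:
        raise KeyError(f"unknown motif member(s): {missing}")
    out = membership.copy()
    out[family_name] = (
        membership[members].to_numpy().astype(bool).any(axis=1).astype(np.int8)
    )
    return out


def celltype_motif_enrichment(
    z: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    z_threshold: float = ACCESSIBILITY_Z_THRESHOLD,
    display_fdr: float = ENRICHMENT_DISPLAY_FDR,
) -> pd.DataFrame:
    """Hypergeometric enrichment of motif-accessible cells per cell type.

    ``z`` is motif x cell deviation Z scores (NaN = undefined, excluded from
    that motif's population). For each (motif, cell type): upper-tail
    hypergeometric p of observing >= overlap accessible cells when drawing
    the cell type from the population; BH FDR across all pairs; ``enriched``
    marks rows under the display cutoff.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != z.shape[1]:
        raise ValueError("labels must cover all cells in the Z matrix")
    rows = []
    for motif in z.index:
        zvec = z.loc[motif].to_numpy(dtype=float)
        defined = ~np.isnan(zvec)
        population = int(defined.sum())
        accessible = zvec > z_threshold
        n_accessible = int((accessible & defined).sum())
        for ct in pd.unique(labels):
            in_type = (labels == ct) & defined
            type_size = int(in_type.sum())
            if type_size == 0:
                logger.warning("cell type %r has no cells with defined Z", ct)
                continue
            overlap = int((accessible & in_type).sum())
            p = stats.hypergeom.sf(overlap - 1, population, n_accessible, type_size)
            rows.append(
                {
                    "motif": motif,
                    "cell_type": ct,
                    "overlap": overlap,
                    "type_size": type_size,
                    "accessible": n_accessible,
                    "population": population,
                    "p_value": float(p),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no (motif, cell type) pair could be tested")
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["enriched"] = table["fdr"] < display_fdr
    return table


def expression_filter(
    motif_genes: Mapping[str, str],
    mean_expression: pd.DataFrame,
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Retain motifs whose gene is expressed in a cell type.

    ``mean_expression`` is genes x cell types (normalized mean expression).
    A motif is retained in a cell type iff its gene's value there is strictly
    greater than ``cutoff``. Motifs whose gene is absent are dropped
    everywhere with a warning. Returns a motif x cell-type boolean frame.
    """
    out = {}
    for motif, gene in motif_genes.items():
        if gene not in mean_expression.index:
            logger.warning("motif %r: gene %r absent from expression; dropped",
                           motif, gene)
            out[motif] = pd.Series(False, index=mean_expression.columns)
            continue
        out[motif] = mean_expression.loc[gene] > cutoff
    return pd.DataFrame(out).T


def correlation_filter(
    z: np.ndarray | pd.Series,
    gene_score: np.ndarray | pd.Series,
    min_cells: int = 10,
) -> tuple[float, bool]:
    """Spearman correlation between a motif's deviation Z and its gene score.

    Retained iff rho > 0. Pairs with undefined values are dropped; a constant
    vector yields an undefined rho and the motif is not retained.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(gene_score, dtype=float)
    if z.shape != g.shape:
        raise ValueError("z and gene_score must align per cell")
    ok = ~(np.isnan(z) | np.isnan(g))
    if int(ok.sum()) < min_cells:
        raise ValueError(f"need >= {min_cells} cells with both values defined")
    if np.ptp(z[ok]) == 0 or np.ptp(g[ok]) == 0:
        logger.warning("constant input; Spearman rho undefined, motif dropped")
        return float("nan"), False
    rho = stats.spearmanr(z[ok], g[ok]).statistic
    return float(rho), bool(rho > 0)


def normalize_depth(X: np.ndarray) -> np.ndarray:
    """Scale each cell (column) to the mean total depth."""
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=0)
    target = totals[totals > 0].mean() if (totals > 0).any() else 1.0
    scale = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    return X * scale[None, :]


def differential_accessibility(
    X_norm: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    peak_ids: list[str] | None = None,
    fdr_cutoff: float = 0.05,
    log2fc_cutoff: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-peak differential accessibility between two cell groups.

    ``X_norm`` is peaks x cells, depth-normalized. Per peak: two-sided
    Wilcoxon rank-sum p, log2 fold change of group means (pseudocount), BH
    FDR across peaks, and the DAR flag: FDR < 0.05 and log2FC >= 0.5.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    if group_a.size < 3 or group_b.size < 3:
        raise ValueError("each group needs >= 3 cells")
    X_norm = np.asarray(X_norm, dtype=float)
    a, b = X_norm[:, group_a], X_norm[:, group_b]
    pvals = np.asarray(
        stats.mannwhitneyu(a, b, axis=1, alternative="two-sided").pvalue
    )
    log2fc = np.log2(
        (a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount)
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "peak_id": peak_ids if peak_ids is not None else np.arange(len(pvals)),
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "is_dar": (fdr < fdr_cutoff) & (log2fc >= log2fc_cutoff),
        }
    )
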