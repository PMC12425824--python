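"""ETS motif co-occurrence co-accessibility test.

For each candidate motif, peaks carrying the candidate and/or the ETS family
motif are partitioned into BOTH (candidate AND ETS), CAND_ONLY and ETS_ONLY
sets. Per-cell deviation Z scores of each set are computed with the
background-corrected deviation machinery and compared, within a named cell
subset (e.g. IM cells of one genotype), by a one-sided Wilcoxon rank-sum test
with alternative "greater": is accessibility of co-occurring peaks higher
than that of peaks carrying exclusively one motif? P values are BH-corrected
across candidates within each comparison direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .deviations import (
    DEFAULT_BACKGROUND_ITERATIONS,
    DEFAULT_K_NEIGHBORS,
    BackgroundSets,
    deviation_z,
    sample_background_peaks,
)

logger = logging.getLogger(__name__)

#: exact rank-sum enumeration is used up to this combined sample size
EXACT_ENUMERATION_LIMIT = 20

COMPARISON_VS_ETS_ONLY = "both_vs_ets_only"
COMPARISON_VS_CAND_ONLY = "both_vs_cand_only"


@dataclass(frozen=True)
class PeakPartition:
    """Disjoint peak index sets for one candidate motif versus the ETS family."""

    candidate: str
    both: np.ndarray
    cand_only: np.ndarray
    ets_only: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both": self.both.size,
            "cand_only": self.cand_only.size,
            "ets_only": self.ets_only.size,
        }


def partition_peaks(
    membership: pd.DataFrame,
    candidate: str,
    family: str = "ETS",
) -> PeakPartition:
    """Partition peaks by candidate/family co-occurrence.

    Raises when no peak carries both motifs (the test is undefined).
    """
    for col in (candidate, family):
        if col not in membership.columns:
            raise KeyError(f"motif column {col!r} not in membership matrix")
    cand = membership[candidate].to_numpy().astype(bool)
    fam = membership[family].to_numpy().astype(bool)
    both = np.where(cand & fam)[0]
    if both.size == 0:
        raise ValueError(
            f"no co-occurring peaks for candidate {candidate!r} and {family!r}"
        )
    return PeakPartition(
        candidate=candidate,
        both=both,
        cand_only=np.where(cand & ~fam)[0],
        ets_only=np.where(fam & ~cand)[0],
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def wilcoxon_rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "greater",
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of x, p). The p value is exact (full enumeration of
    rank assignments) when n+m <= 20 with no ties, otherwise the normal
    approximation with tie correction and optional continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = x.size + y.size <= EXACT_ENUMERATION_LIMIT and not _has_ties(x, y)
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class CoaccessResult:
    candidate: str
    comparison: str
    n_cells: int
    n_peaks_group: int
    n_peaks_reference: int
    statistic: float
    p_value: float


def coaccessibility_test(
    X: CountMatrix,
    peaks: pd.DataFrame,
    membership: pd.DataFrame,
    candidates: list[str],
    cells: list[str] | np.ndarray,
    family: str = "ETS",
    k: int = DEFAULT_K_NEIGHBORS,
    n_iterations: int = DEFAULT_BACKGROUND_ITERATIONS,
    seed: int = 0,
    compute_on: str = "all",
    backgrounds: BackgroundSets | None = None,
) -> pd.DataFrame:
    """Run the co-occurrence co-accessibility test for each candidate motif.

    Deviation Z scores of the BOTH / CAND_ONLY / ETS_ONLY peak sets are
    computed per cell — on all cells by default (``compute_on="all"``;
    background matching then sees the full accessibility profile) or on the
    subset only (``compute_on="subset"``) — and the one-sided rank-sum tests
    are evaluated over the named cell subset, excluding cells with undefined
    Z pairwise. BH FDR is applied across candidates within each comparison.
    """
    cells = list(cells)
    if len(cells) == 0:
        raise ValueError("cell subset must be non-empty")
    if len(cells) < 2:
        raise ValueError("rank test undefined on a cell subset of size < 2")
    if compute_on not in ("all", "subset"):
        raise ValueError("compute_on must be 'all' or 'subset'")
    if compute_on == "subset":
        X = X.subset_cells(cells)
        peaks = peaks.copy()
        peaks["mean_accessibility"] = X.feature_totals() / X.n_cells
    cell_pos = {c: i for i, c in enumerate(X.cells)}
    try:
        subset_idx = np.array([cell_pos[c] for c in cells])
    except KeyError as e:
        raise KeyError(f"subset cell {e} not in matrix") from None

    if backgrounds is None:
        backgrounds = sample_background_peaks(peaks, k, n_iterations, seed)

    rows: list[CoaccessResult] = []
    for candidate in candidates:
        part = partition_peaks(membership, candidate, family)
        zsets = {}
        for name, idx in (
            ("both", part.both),
            ("cand_only", part.cand_only),
            ("ets_only", part.ets_only),
        ):
            if idx.size == 0:
                zsets[name] = None
                continue
            zsets[name] = deviation_z(X, idx, backgrounds).z[subset_idx]
        for comparison, ref in (
            (COMPARISON_VS_ETS_ONLY, "ets_only"),
            (COMPARISON_VS_CAND_ONLY, "cand_only"),
        ):
            if zsets[ref] is None:
                logger.warning(
                    "candidate %r: empty %s set; comparison skipped", candidate, ref
                )
                continue
            zb, zr = zsets["both"], zsets[ref]
            ok_b, ok_r = ~np.isnan(zb), ~np.isnan(zr)
            if not ok_b.any() or not ok_r.any():
                logger.warning(
                    "candidate %r %s: no defined Z; skipped", candidate, comparison
                )
                continue
            u, p = wilcoxon_rank_sum(zb[ok_b], zr[ok_r], alternative="greater")
            rows.append(
                CoaccessResult(
                    candidate=candidate,
                    comparison=comparison,
                    n_cells=int(min(ok_b.sum(), ok_r.sum())),
                    n_peaks_group=part.both.size,
                    n_peaks_reference=getattr(part, ref).size,
                    statistic=u,
                    p_value=p,
                )
            )
    table = pd.DataFrame([r.__dict__ for r in rows])
    if table.empty:
        raise ValueError("no comparison could be evaluated")
    table["fdr"] = np.nan
    for comparison in table["comparison"].unique():
        mask = table["comparison"] == comparison
        table.loc[mask, "fdr"] = multipletests(
            table.loc[mask, "p_value"], method="fdr_bh"
        )[1]
    return table
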