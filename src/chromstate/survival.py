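"""Bulk signature scoring, ERG labeling, quartile stratification and
Kaplan-Meier / log-rank survival comparison.

Samples are scored as the mean z-scored log expression of a gene signature,
stratified into top/bottom signature quartiles (linear-interpolation
percentiles), and the two quartile groups are compared by the log-rank
(Mantel-Cox) test, by default separately within ERG-positive and
ERG-negative strata. The product-limit and log-rank computations are carried
out with lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .containers import SignatureSet
from .lineage import _zscore_rows

logger = logging.getLogger(__name__)

TOP, BOTTOM, MIDDLE = "top", "bottom", "middle"


def label_erg_status(fraction_erg_positive: np.ndarray | float) -> np.ndarray | str:
    """ERG status per sample: positive iff the fraction of tumor cells that
    are ERG+ is strictly greater than 0.5."""
    frac = np.asarray(fraction_erg_positive, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    labels = np.where(frac > 0.5, "positive", "negative")
    return labels.item() if labels.ndim == 0 else labels


def score_bulk_signature(
    expression: pd.DataFrame, signature: SignatureSet
) -> pd.Series:
    """Per-sample signature score: mean across signature genes of per-gene
    z-scores over samples, on log-scale expression."""
    present = [g for g in signature.genes if g in expression.index]
    if not present:
        raise ValueError(
            f"signature {signature.name!r}: no signature gene present"
        )
    missing = len(signature.genes) - len(present)
    if missing:
        logger.warning("signature %r: %d genes absent", signature.name, missing)
    z = _zscore_rows(expression.loc[present].to_numpy(dtype=float))
    return pd.Series(z.mean(axis=0), index=expression.columns, name=signature.name)


def quartile_stratify(scores: pd.Series | np.ndarray) -> pd.Series:
    """Label samples as top (score >= 75th percentile), bottom (score <= 25th
    percentile) or middle. Percentiles use linear interpolation. Constant
    scores admit no stratification and raise."""
    s = pd.Series(np.asarray(scores, dtype=float), index=getattr(scores, "index", None))
    if len(s) < 8:
        raise ValueError("quartile stratification needs >= 8 samples")
    q25, q75 = np.percentile(s.to_numpy(), [25, 75])
    if q25 == q75:
        raise ValueError("no stratification possible: quartile cutoffs coincide")
    labels = pd.Series(MIDDLE, index=s.index, dtype=object)
    labels[s >= q75] = TOP
    labels[s <= q25] = BOTTOM
    logger.info(
        "quartile stratification: %d top, %d bottom, %d middle",
        int((labels == TOP).sum()),
        int((labels == BOTTOM).sum()),
        int((labels == MIDDLE).sum()),
    )
    return labels


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate at the observed event times."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Censored observations reduce the risk set without introducing steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one sample")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    grid = event_table.index.to_numpy(dtype=float)
    mask = grid > 0  # drop the t=0 anchor row
    return SurvivalCurve(
        times=grid[mask],
        at_risk=event_table["at_risk"].to_numpy(dtype=float)[mask],
        survival=surv.to_numpy(dtype=float)[mask],
    )


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Log-rank (Mantel-Cox) test between two groups.

    Returns (chi-square statistic with 1 df, p value). Requires at least one
    event overall.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _lifelines_logrank(times_a, times_b, events_a, events_b)
    return float(res.test_statistic), float(res.p_value)


def quartile_logrank(
    cohort: pd.DataFrame,
    stratify_by_erg: bool = True,
    quartiles_within_stratum: bool = True,
) -> pd.DataFrame:
    """Top- vs bottom-quartile log-rank comparison of a cohort table.

    ``cohort`` needs columns sample_id, score, time, event and (when
    stratifying) erg_status. Quartiles are computed within each ERG stratum
    by default; set ``quartiles_within_stratum=False`` to compute them on the
    full cohort before stratifying.
    """
    required = {"score", "time", "event"}
    if not required <= set(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    if stratify_by_erg and "erg_status" not in cohort.columns:
        raise ValueError("erg_status column required for stratified analysis")

    if stratify_by_erg and not quartiles_within_stratum:
        cohort = cohort.copy()
        cohort["_quartile"] = quartile_stratify(cohort["score"]).to_numpy()

    strata = (
        [(s, g) for s, g in cohort.groupby("erg_status")]
        if stratify_by_erg
        else [("all", cohort)]
    )
    rows = []
    for name, grp in strata:
        if "_quartile" in grp.columns:
            labels = grp["_quartile"].to_numpy()
        else:
            labels = quartile_stratify(pd.Series(grp["score"].to_numpy())).to_numpy()
        top, bottom = grp[labels == TOP], grp[labels == BOTTOM]
        stat, p = logrank_test(
            top["time"], top["event"], bottom["time"], bottom["event"]
        )
        rows.append(
            {
                "stratum": name,
                "n_top": len(top),
                "n_bottom": len(bottom),
                "chi2": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
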