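"""Motif accessibility deviations with GC/accessibility-matched backgrounds.

For a peak set S (all peaks matching a motif), the raw per-cell deviation is

    y_j = (sum_{i in S} X_ij - sum_{i in S} E_ij) / sum_{i in S} E_ij

where E is the expectation under uniform accessibility (outer product of the
margins over the grand total). Bias correction subtracts the mean deviation of
B background peak sets matched on (GC fraction, log1p mean accessibility);
the Z score divides by the background sample standard deviation. Cells whose
background standard deviation is zero have undefined Z and are flagged as
missing rather than propagated silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .containers import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_NEIGHBORS = 50
DEFAULT_BACKGROUND_ITERATIONS = 50


def expected_counts(X: CountMatrix | np.ndarray) -> np.ndarray:
    """Expected counts under uniform accessibility.

    E_ij = row_total_i * column_total_j / grand_total. Preserves both margins
    exactly. Dense output: intended for small matrices and oracle checks; the
    deviation routines below work from the margins without materializing E.
    """
    dense = X.matrix.toarray() if isinstance(X, CountMatrix) else np.asarray(X, float)
    total = dense.sum()
    if total <= 0:
        raise ValueError("expected_counts requires a matrix with positive total")
    return np.outer(dense.sum(axis=1), dense.sum(axis=0)) / total


def _margins(X: CountMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    row = X.feature_totals().astype(float)
    col = X.cell_totals().astype(float)
    total = row.sum()
    if total <= 0:
        raise ValueError("deviations require a matrix with positive total count")
    return row, col, total


def raw_deviation(
    X: CountMatrix,
    members: np.ndarray,
    _margins_cache: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> np.ndarray:
    """Per-cell raw deviation of a peak set.

    ``members`` holds peak row indices; repeats are counted with multiplicity
    (as arises when background mappings sample with replacement). Cells with
    zero expected member mass get NaN.
    """
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("member peak set must be non-empty")
    row, col, total = _margins_cache or _margins(X)
    observed = np.asarray(X.matrix[members, :].sum(axis=0)).ravel()
    expected = row[members].sum() * col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        y = (observed - expected) / expected
    y[expected == 0] = np.nan
    return y


@dataclass
class BackgroundSets:
    """B sampled background mappings: ``mapping[b, i]`` is the background peak
    drawn for source peak i in iteration b, from the tie-inclusive set of its
    k nearest neighbors (self included) in standardized
    (GC fraction, log1p mean accessibility) space."""

    mapping: np.ndarray  # (B, n_peaks) int
    k: int
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.mapping.shape[0]


def _background_features(peaks: pd.DataFrame) -> np.ndarray:
    feats = np.column_stack(
        [
            peaks["gc_fraction"].to_numpy(dtype=float),
            np.log1p(peaks["mean_accessibility"].to_numpy(dtype=float)),
        ]
    )
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (feats - mean) / sd


def sample_background_peaks(
    peaks: pd.DataFrame,
    k: int = DEFAULT_K_NEIGHBORS,
    n_iterations: int = DEFAULT_BACKGROUND_ITERATIONS,
    seed: int = 0,
) -> BackgroundSets:
    """Sample B background peaks per peak, matched on GC and accessibility.

    Per peak and iteration, one neighbor is drawn uniformly with replacement
    from all peaks whose standardized distance is at most the distance of the
    k-th nearest peak (self included); distance ties beyond k are included so
    that identical peaks are sampled exchangeably.
    """
    n_peaks = len(peaks)
    if n_peaks < 2:
        raise ValueError("background sampling needs at least 2 peaks")
    if n_peaks < k + 1:
        logger.warning(
            "only %d peaks; reducing k from %d to %d", n_peaks, k, n_peaks - 1
        )
        k = n_peaks - 1
    feats = _background_features(peaks)
    tree = cKDTree(feats)
    # distance to the k-th nearest peak with self counted as the 0-distance
    # nearest; column k of a (k+1)-point query
    dists, _ = tree.query(feats, k=k + 1)
    radius = dists[:, k]
    rng = np.random.default_rng([int(seed), 3])
    mapping = np.empty((n_iterations, n_peaks), dtype=np.int64)
    for i in range(n_peaks):
        candidates = np.asarray(
            sorted(tree.query_ball_point(feats[i], radius[i] * (1 + 1e-12)))
        )
        mapping[:, i] = rng.choice(candidates, size=n_iterations, replace=True)
    return BackgroundSets(mapping=mapping, k=k, seed=seed)


@dataclass
class DeviationResult:
    """Per-cell deviations of one peak set: raw y, bias-corrected d, Z."""

    y: np.ndarray
    d: np.ndarray
    z: np.ndarray
    n_iterations: int
    n_undefined: int = 0


def deviation_z(
    X: CountMatrix,
    members: np.ndarray,
    backgrounds: BackgroundSets,
) -> DeviationResult:
    """Bias-corrected deviation and Z score of a peak set.

    For each background iteration b, the background ("reflected") peak set is
    the set of peaks whose matched partner under ``backgrounds.mapping[b]``
    lies in the member set; its raw deviation is recomputed and
    d = y - mean_b(y_b); z = d / sd_b(y_b) with the sample (n-1) standard
    deviation. The reflected form preserves the GC/accessibility matching
    (every source-partner pair is within the k-neighbor radius) and makes the
    all-peaks member set reproduce itself in every iteration, so its
    bias-corrected deviation is exactly zero by construction. sd = 0 yields
    NaN z, counted and logged.
    """
    members = np.asarray(members, dtype=int)
    margins = _margins(X)
    y = raw_deviation(X, members, margins)
    member_mask = np.zeros(X.n_features, dtype=bool)
    member_mask[members] = True
    bg = np.empty((backgrounds.n_iterations, X.n_cells))
    for b in range(backgrounds.n_iterations):
        reflected = np.flatnonzero(member_mask[backgrounds.mapping[b]])
        if reflected.size == 0:
            bg[b] = np.nan
        else:
            bg[b] = raw_deviation(X, reflected, margins)
    d = y - bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = d / sd
    z[sd == 0] = np.nan
    n_undef = int(np.isnan(z).sum())
    if n_undef:
        logger.info("%d cells with undefined deviation Z", n_undef)
    return DeviationResult(
        y=y, d=d, z=z, n_iterations=backgrounds.n_iterations, n_undefined=n_undef
    )


@dataclass
class DeviationSet:
    """Motif x cell deviation matrices plus background metadata."""

    y: pd.DataFrame
    d: pd.DataFrame
    z: pd.DataFrame
    n_iterations: int
    seed: int
    k: int = DEFAULT_K_NEIGHBORS
    undefined: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def compute_deviations(
    X: CountMatrix,
    peaks: pd.DataFrame,
    membership: pd.DataFrame,
    k: int = DEFAULT_K_NEIGHBORS,
    n_iterations: int = DEFAULT_BACKGROUND_ITERATIONS,
    seed: int = 0,
    backgrounds: BackgroundSets | None = None,
) -> DeviationSet:
    """Deviations for every motif column of a peak x motif membership matrix.

    Motifs with no member peak are skipped with a warning. A shared
    BackgroundSets is sampled once (or supplied by the caller).
    """
    if len(peaks) != X.n_features:
        raise ValueError("peak table must align with matrix rows")
    if backgrounds is None:
        backgrounds = sample_background_peaks(peaks, k, n_iterations, seed)
    rows_y, rows_d, rows_z, rows_u, names = [], [], [], [], []
    for motif in membership.columns:
        idx = np.where(membership[motif].to_numpy() != 0)[0]
        if idx.size == 0:
            logger.warning("motif %r has no member peaks; skipped", motif)
            continue
        res = deviation_z(X, idx, backgrounds)
        names.append(motif)
        rows_y.append(res.y)
        rows_d.append(res.d)
        rows_z.append(res.z)
        rows_u.append(np.isnan(res.z))
    mk = lambda rows: pd.DataFrame(rows, index=names, columns=X.cells)
    return DeviationSet(
        y=mk(rows_y),
        d=mk(rows_d),
        z=mk(rows_z),
        n_iterations=backgrounds.n_iterations,
        seed=backgrounds.seed,
        k=backgrounds.k,
        undefined=mk(rows_u),
    )
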