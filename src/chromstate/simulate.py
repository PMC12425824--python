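"""Seeded synthetic multiome generator with planted ground truth.

Emulates the statistical structure of a paired scATAC-seq / scRNA-seq prostate
epithelium experiment plus a bulk-RNA survival cohort: cell-type-specific peak
programs, GC-heterogeneous peaks, motif co-occurrence with amplified
accessibility in one target cell type (the ERG+ intermediate, "IM", state),
Epcam+ epithelial clusters with mitochondrial-fraction variation, and
signature-score-linked hazards. Every downstream stage of the pipeline can
therefore be exercised against known planted structure without any real
accession.

Randomness: each generator builds its own ``numpy.random.Generator`` from
``(config.seed, stream)`` with a fixed per-modality stream id (ATAC=0, RNA=1,
cohort=2), and draws in a fixed documented order, so a given SimConfig is
bit-reproducible and the three modalities are independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

logger = logging.getLogger(__name__)

_ATAC_STREAM = 0
_RNA_STREAM = 1
_COHORT_STREAM = 2

#: probability that a peak carrying a motif is forced to also carry its
#: declared co-occurrence partner (on top of the partner's own Bernoulli draw)
FORCED_COOCCURRENCE_RATE = 0.5


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass(frozen=True)
class MotifSpec:
    """One motif planted in the synthetic peak set.

    amplification_factor multiplies the Poisson rate of peaks carrying both
    this motif and its co_occurrence_partner, in cells of target_cell_type
    only. A factor > 1 therefore requires a partner and a target.
    """

    name: str
    membership_prob: float
    co_occurrence_partner: str | None = None
    amplification_factor: float = 1.0
    target_cell_type: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.membership_prob <= 1.0:
            raise ConfigurationError(
                f"motif {self.name!r}: membership_prob must be in [0, 1]"
            )
        if self.amplification_factor < 1.0:
            raise ConfigurationError(
                f"motif {self.name!r}: amplification_factor must be >= 1"
            )
        if self.amplification_factor > 1.0 and self.co_occurrence_partner is None:
            raise ConfigurationError(
                f"motif {self.name!r}: amplification requires a co_occurrence_partner"
            )
        if self.amplification_factor > 1.0 and self.target_cell_type is None:
            raise ConfigurationError(
                f"motif {self.name!r}: amplification requires a target_cell_type"
            )


def default_motif_specs() -> tuple[MotifSpec, ...]:
    """Default planted motif set.

    ETS-family members (ERG/ETS/ETV/FLI) plus three candidates amplified 2x in
    co-occurrence with ETS inside IM cells — mirroring the factors whose
    co-occurrence signal the co-accessibility test is designed to detect — and
    two null candidates with no planted signal.
    """
    return (
        MotifSpec("ETS", 0.30),
        MotifSpec("ERG", 0.10),
        MotifSpec("ETV", 0.10),
        MotifSpec("FLI", 0.10),
        MotifSpec("STAT3", 0.20, "ETS", 2.0, "IM"),
        MotifSpec("NFKB2", 0.20, "ETS", 2.0, "IM"),
        MotifSpec("NFATC1", 0.20, "ETS", 2.0, "IM"),
        MotifSpec("FOXA1", 0.20),
        MotifSpec("AR", 0.25),
    )


def _default_cells() -> dict[str, int]:
    return {"basal": 50, "L1": 50, "L2": 50, "IM": 50}


@dataclass
class SimConfig:
    """Parameters of the synthetic multiome.

    Defaults reflect a desk-scale version of the study design: 200 cells over
    four epithelial states, 2,000 peaks, a 4x cell-type peak-program
    multiplier, 2x ETS co-occurrence amplification in IM cells, and a survival
    cohort of 200 samples with a log(2.5) hazard increase per signature SD.
    """

    seed: int = 0
    n_cells_per_type: Mapping[str, int] = field(default_factory=_default_cells)
    n_peaks: int = 2000
    n_genes: int = 1000
    gc_range: tuple[float, float] = (0.3, 0.7)
    motif_specs: tuple[MotifSpec, ...] = field(default_factory=default_motif_specs)
    base_rate: float = 0.2
    type_multiplier: float = 4.0
    n_program_peaks_per_type: int = 200
    epcam_fraction: Mapping[str, float] | float = 0.9
    mito_fraction_beta: tuple[float, float] = (2.0, 18.0)
    n_mito_genes: int = 10
    n_marker_genes_per_type: int = 10
    marker_multiplier: float = 4.0
    rna_base_rate: float = 1.0
    n_low_count_cells: int = 0
    n_high_count_cells: int = 0
    n_high_mito_cells: int = 0
    cohort_n: int = 200
    cohort_log_hazard_per_sd: float = math.log(2.5)
    censor_rate: float = 0.3
    baseline_hazard: float = 0.1
    erg_positive_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.n_cells_per_type:
            raise ConfigurationError("n_cells_per_type must name at least one type")
        if any(n <= 0 for n in self.n_cells_per_type.values()):
            raise ConfigurationError("cell counts must be positive")
        if self.n_peaks <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_peaks and n_genes must be positive")
        lo, hi = self.gc_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigurationError("gc_range must be an interval within [0, 1]")
        if self.base_rate <= 0 or self.rna_base_rate <= 0:
            raise ConfigurationError("base rates must be positive")
        if self.type_multiplier < 1 or self.marker_multiplier < 0:
            raise ConfigurationError("multipliers out of range")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError("censor_rate must be in [0, 1]")
        if not 0.0 <= self.erg_positive_fraction <= 1.0:
            raise ConfigurationError("erg_positive_fraction must be in [0, 1]")
        names = [s.name for s in self.motif_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("motif names must be unique")
        for spec in self.motif_specs:
            if spec.co_occurrence_partner is not None and (
                spec.co_occurrence_partner not in names
            ):
                raise ConfigurationError(
                    f"motif {spec.name!r}: unknown partner {spec.co_occurrence_partner!r}"
                )

    @property
    def cell_types(self) -> list[str]:
        return list(self.n_cells_per_type)

    @property
    def n_cells(self) -> int:
        return sum(self.n_cells_per_type.values())


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _cell_type_labels(config: SimConfig) -> np.ndarray:
    return np.repeat(
        list(config.n_cells_per_type), list(config.n_cells_per_type.values())
    )


def program_peaks(config: SimConfig) -> dict[str, np.ndarray]:
    """Disjoint "program" peak indices per cell type (elevated accessibility)."""
    n_types = len(config.n_cells_per_type)
    if n_types * config.n_program_peaks_per_type > config.n_peaks:
        raise ConfigurationError(
            "n_peaks too small for disjoint per-type program peak sets"
        )
    out = {}
    for i, ct in enumerate(config.cell_types):
        start = i * config.n_program_peaks_per_type
        out[ct] = np.arange(start, start + config.n_program_peaks_per_type)
    return out


def generate_atac(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic scATAC modality.

    Returns ``(counts, peak_table, motif_membership, cell_metadata)``. Counts
    follow a Poisson model with rate

        base_rate x program multiplier x co-occurrence amplification,

    where the program multiplier applies to a cell type's disjoint program
    peaks and amplification applies only in peaks carrying both a motif and
    its partner, only in the motif's target cell type.

    Draw order (fixed): GC fractions, per-motif memberships, forced
    co-occurrence, fragment counts.
    """
    for spec in config.motif_specs:
        if (
            spec.amplification_factor > 1.0
            and spec.target_cell_type not in config.n_cells_per_type
        ):
            raise ConfigurationError(
                f"motif {spec.name!r}: unknown target cell type "
                f"{spec.target_cell_type!r}"
            )
    rng = _rng(config, _ATAC_STREAM)
    n_peaks, n_cells = config.n_peaks, config.n_cells
    labels = _cell_type_labels(config)
    barcodes = [f"atac_cell_{i:05d}" for i in range(n_cells)]

    gc = rng.uniform(config.gc_range[0], config.gc_range[1], size=n_peaks)

    membership = {}
    for spec in config.motif_specs:
        membership[spec.name] = rng.random(n_peaks) < spec.membership_prob
    for spec in config.motif_specs:
        if spec.co_occurrence_partner is not None:
            forced = membership[spec.name] & (
                rng.random(n_peaks) < FORCED_COOCCURRENCE_RATE
            )
            membership[spec.co_occurrence_partner] |= forced

    rate = np.full((n_peaks, n_cells), config.base_rate)
    programs = program_peaks(config)
    for ct, peaks_idx in programs.items():
        cols = labels == ct
        rate[np.ix_(peaks_idx, cols)] *= config.type_multiplier
    for spec in config.motif_specs:
        if spec.amplification_factor > 1.0:
            both = membership[spec.name] & membership[spec.co_occurrence_partner]
            cols = labels == spec.target_cell_type
            rate[np.ix_(np.where(both)[0], np.where(cols)[0])] *= (
                spec.amplification_factor
            )

    counts = rng.poisson(rate)
    starts = np.arange(n_peaks) * 1000
    ends = starts + 500
    peak_ids = [f"chr1:{s}-{e}" for s, e in zip(starts, ends)]
    matrix = CountMatrix(sp.csr_matrix(counts), peak_ids, barcodes)

    peak_table = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": ends,
            "peak_id": peak_ids,
            "gc_fraction": gc,
            "mean_accessibility": counts.mean(axis=1),
        }
    )
    motif_df = pd.DataFrame(
        {name: col.astype(np.int8) for name, col in membership.items()},
        index=pd.Index(peak_ids, name="peak_id"),
    )
    meta = pd.DataFrame({"cell": barcodes, "cell_type": labels}).set_index("cell")
    return matrix, peak_table, motif_df, meta


def _gene_names(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Gene identifiers and the mitochondrial mask, in fixed order."""
    required = config.n_mito_genes + 1 + (
        config.n_marker_genes_per_type * len(config.n_cells_per_type)
    )
    if config.n_genes < required:
        raise ConfigurationError(
            f"n_genes={config.n_genes} smaller than the {required} required "
            "mito + Epcam + marker genes"
        )
    names = [f"mt-{i + 1}" for i in range(config.n_mito_genes)]
    names.append("Epcam")
    for ct in config.cell_types:
        names.extend(
            f"{ct}_marker_{k + 1}" for k in range(config.n_marker_genes_per_type)
        )
    names.extend(f"gene_{i + 1}" for i in range(config.n_genes - len(names)))
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[: config.n_mito_genes] = True
    return names, mito_mask


def marker_signatures(config: SimConfig) -> dict[str, list[str]]:
    """The planted marker gene set of each cell type (ground truth)."""
    return {
        ct: [f"{ct}_marker_{k + 1}" for k in range(config.n_marker_genes_per_type)]
        for ct in config.cell_types
    }


def generate_rna(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, np.ndarray]:
    """Generate the synthetic scRNA modality.

    Returns ``(counts, cell_metadata, mito_mask)``. Cluster labels coincide
    with the planted cell types. Marker genes of a cluster are elevated by
    ``marker_multiplier``; Epcam is forced to >= 1 in the per-cluster
    ``epcam_fraction`` of cells and to 0 elsewhere; each cell's mitochondrial
    fraction is drawn from a Beta distribution. The first
    n_low_count / n_high_count / n_high_mito cells (in that order) are
    overwritten with fixed-total multinomial draws that violate the
    corresponding QC rule by construction.
    """
    rng = _rng(config, _RNA_STREAM)
    n_genes, n_cells = config.n_genes, config.n_cells
    labels = _cell_type_labels(config)
    barcodes = [f"rna_cell_{i:05d}" for i in range(n_cells)]
    names, mito_mask = _gene_names(config)
    gene_pos = {g: i for i, g in enumerate(names)}
    epcam_idx = gene_pos["Epcam"]

    n_planted = (
        config.n_low_count_cells + config.n_high_count_cells + config.n_high_mito_cells
    )
    if n_planted > n_cells:
        raise ConfigurationError("more planted QC-failing cells than cells")

    # draw order: mito fractions, Epcam positivity, nuclear counts, Epcam
    # counts, mito counts, planted-cell overwrites
    a, b = config.mito_fraction_beta
    mito_frac = rng.beta(a, b, size=n_cells)

    if isinstance(config.epcam_fraction, Mapping):
        epcam_p = np.array(
            [config.epcam_fraction.get(ct, 0.0) for ct in labels], dtype=float
        )
    else:
        epcam_p = np.full(n_cells, float(config.epcam_fraction))
    epcam_pos = rng.random(n_cells) < epcam_p

    rate = np.full((n_genes, n_cells), config.rna_base_rate)
    for ct, genes in marker_signatures(config).items():
        rows = [gene_pos[g] for g in genes]
        cols = labels == ct
        rate[np.ix_(rows, cols)] *= config.marker_multiplier
    rate[mito_mask, :] = 0.0
    rate[epcam_idx, :] = 0.0

    counts = rng.poisson(rate).astype(np.int64)
    counts[epcam_idx, epcam_pos] = 1 + rng.poisson(2.0, size=int(epcam_pos.sum()))
    counts[epcam_idx, ~epcam_pos] = 0

    # mitochondrial counts scaled so the expected realized fraction matches
    nuclear_expected = rate.sum(axis=0) + 3.0 * epcam_p
    mito_total_rate = nuclear_expected * mito_frac / np.clip(1 - mito_frac, 1e-9, None)
    per_gene = mito_total_rate / config.n_mito_genes
    counts[mito_mask, :] = rng.poisson(
        np.broadcast_to(per_gene, (config.n_mito_genes, n_cells))
    )

    planted_low = np.zeros(n_cells, dtype=bool)
    planted_high = np.zeros(n_cells, dtype=bool)
    planted_mito = np.zeros(n_cells, dtype=bool)
    probs = np.full(n_genes, 1.0 / n_genes)
    cursor = 0
    for _ in range(config.n_low_count_cells):
        counts[:, cursor] = rng.multinomial(250, probs)
        planted_low[cursor] = True
        cursor += 1
    for _ in range(config.n_high_count_cells):
        counts[:, cursor] = rng.multinomial(150_000, probs)
        planted_high[cursor] = True
        cursor += 1
    nuc_probs = np.where(mito_mask, 0.0, 1.0)
    nuc_probs /= nuc_probs.sum()
    mito_probs = np.where(mito_mask, 1.0, 0.0)
    mito_probs /= mito_probs.sum()
    for _ in range(config.n_high_mito_cells):
        # 60% mitochondrial of a 2,000-count cell, fixed split
        counts[:, cursor] = rng.multinomial(800, nuc_probs) + rng.multinomial(
            1200, mito_probs
        )
        planted_mito[cursor] = True
        cursor += 1

    matrix = CountMatrix(sp.csr_matrix(counts), names, barcodes)
    meta = pd.DataFrame(
        {
            "cell": barcodes,
            "cluster": labels,
            "epcam_positive": epcam_pos,
            "mito_fraction_true": mito_frac,
            "planted_low_count": planted_low,
            "planted_high_count": planted_high,
            "planted_high_mito": planted_mito,
        }
    ).set_index("cell")
    return matrix, meta, mito_mask


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate the synthetic bulk survival cohort.

    Signature scores are standard normal; survival times are exponential with
    log-hazard ``cohort_log_hazard_per_sd x score`` on top of a constant
    baseline hazard; censoring is an independent Bernoulli(censor_rate) coin,
    with censored samples observed at a uniform fraction of their event time;
    ERG status is an independent Bernoulli(erg_positive_fraction) label.
    """
    if config.cohort_n < 8:
        raise ConfigurationError("cohort_n must be >= 8")
    rng = _rng(config, _COHORT_STREAM)
    n = config.cohort_n
    score = rng.standard_normal(n)
    hazard = config.baseline_hazard * np.exp(config.cohort_log_hazard_per_sd * score)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censor_rate
    frac = rng.uniform(0.0, 1.0, size=n)
    time = np.where(censored, event_time * frac, event_time)
    time = np.clip(time, 1e-9, None)
    erg = np.where(
        rng.random(n) < config.erg_positive_fraction, "positive", "negative"
    )
    return pd.DataFrame(
        {
            "sample_id": [f"sample_{i:04d}" for i in range(n)],
            "score": score,
            "time": time,
            "event": (~censored).astype(int),
            "erg_status": erg,
        }
    )
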