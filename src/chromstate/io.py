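"""On-disk formats, pipeline configuration and the end-to-end driver.

Formats: Matrix Market (1-based on disk, 0-based in memory) with companion
features/barcodes TSVs; peaks as 0-based half-open BED plus an annotation TSV
(peak_id, gc_fraction, mean_accessibility); motif membership as a 0/1 TSV;
the survival cohort as CSV; configuration as YAML; provenance as a JSON
manifest holding the SHA-256 of every output, all seeds and all thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__
from .coaccess import coaccessibility_test
from .containers import CountMatrix
from .deviations import compute_deviations
from .lineage import (
    assign_cell_type,
    derive_markers,
    epcam_positive_cells,
    flag_epithelial_clusters,
    normalize_cp10k,
    score_signature,
    signature_from_markers,
)
from .motifs import celltype_motif_enrichment, reduce_motif_family
from .qc import AtacQcThresholds, RnaQcThresholds, filter_rna_cells, rna_qc_mask
from .simulate import (
    MotifSpec,
    SimConfig,
    generate_atac,
    generate_cohort,
    generate_rna,
)
from .survival import quartile_logrank

logger = logging.getLogger(__name__)

ETS_FAMILY_MEMBERS = ["ERG", "ETS", "ETV", "FLI"]
ETS_FAMILY_NAME = "ETS_family"


# ---------------------------------------------------------------------------
# sparse matrices


def write_sparse_matrix(matrix: CountMatrix, prefix: Path | str) -> list[Path]:
    """Write MTX + features.tsv + barcodes.tsv under a directory prefix."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    mtx = prefix / "matrix.mtx"
    scipy.io.mmwrite(mtx, matrix.matrix.tocoo(), field="integer")
    feats = prefix / "features.tsv"
    feats.write_text("".join(f"{f}\n" for f in matrix.features))
    bars = prefix / "barcodes.tsv"
    bars.write_text("".join(f"{c}\n" for c in matrix.cells))
    return [mtx, feats, bars]


def read_sparse_matrix(prefix: Path | str) -> CountMatrix:
    """Read MTX + features.tsv + barcodes.tsv; validates dimensions."""
    prefix = Path(prefix)
    mtx_path = prefix / "matrix.mtx"
    try:
        matrix = scipy.io.mmread(mtx_path)
    except ValueError as e:
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {e}") from e
    features = (prefix / "features.tsv").read_text().splitlines()
    cells = (prefix / "barcodes.tsv").read_text().splitlines()
    n_feat, n_cell = matrix.shape
    if n_feat != len(features):
        raise ValueError(
            f"{mtx_path}: header declares {n_feat} features but features.tsv "
            f"has {len(features)} lines"
        )
    if n_cell != len(cells):
        raise ValueError(
            f"{mtx_path}: header declares {n_cell} cells but barcodes.tsv "
            f"has {len(cells)} lines"
        )
    return CountMatrix(sp.csr_matrix(matrix), features, cells)


# ---------------------------------------------------------------------------
# peaks


def write_peaks(peaks: pd.DataFrame, bed_path: Path | str, annot_path: Path | str) -> None:
    peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    peaks[["peak_id", "gc_fraction", "mean_accessibility"]].to_csv(
        annot_path, sep="\t", index=False
    )


def read_peaks(bed_path: Path | str, annot_path: Path | str) -> pd.DataFrame:
    """Read a BED (0-based half-open) and its annotation TSV into a PeakTable."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end", "peak_id"]
    )
    if bed["peak_id"].isna().any():
        bed["peak_id"] = (
            bed["chrom"].astype(str)
            + ":"
            + bed["start"].astype(str)
            + "-"
            + bed["end"].astype(str)
        )
    if (bed["start"] >= bed["end"]).any():
        bad = bed[bed["start"] >= bed["end"]].index[0]
        raise ValueError(f"{bed_path}: interval with start >= end at line {bad + 1}")
    if bed["peak_id"].duplicated().any():
        raise ValueError(f"{bed_path}: duplicate peak identifiers")
    annot = pd.read_csv(annot_path, sep="\t")
    if ((annot["gc_fraction"] < 0) | (annot["gc_fraction"] > 1)).any():
        raise ValueError(f"{annot_path}: gc_fraction outside [0, 1]")
    merged = bed.merge(annot, on="peak_id", validate="one_to_one")
    if len(merged) != len(bed):
        raise ValueError("annotation TSV does not cover every peak")
    return merged


def write_motif_membership(membership: pd.DataFrame, path: Path | str) -> None:
    membership.to_csv(path, sep="\t", index_label="peak_id")


def read_motif_membership(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="peak_id")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with study-default thresholds."""

    seed: int = 0
    outdir: Path = Path("chromstate_out")
    sim: SimConfig = field(default_factory=SimConfig)
    rna_qc: RnaQcThresholds = field(default_factory=RnaQcThresholds)
    atac_qc: AtacQcThresholds = field(default_factory=AtacQcThresholds)
    k_neighbors: int = 50
    background_iterations: int = 50
    candidates: tuple[str, ...] = ("STAT3", "NFKB2", "NFATC1", "FOXA1", "AR")
    coaccess_cell_type: str = "IM"
    run_simulate: bool = True
    run_qc: bool = True
    run_lineage: bool = True
    run_deviations: bool = True
    run_enrichment: bool = True
    run_coaccess: bool = True
    run_survival: bool = True

    def to_yaml(self, path: Path | str) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        Path(path).write_text(yaml.safe_dump(plain(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim_raw = raw.pop("sim", {})
        specs = sim_raw.pop("motif_specs", None)
        if specs is not None:
            sim_raw["motif_specs"] = tuple(
                MotifSpec(**s) if isinstance(s, dict) else MotifSpec(*s)
                for s in specs
            )
        for key in ("gc_range", "mito_fraction_beta"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        rna_raw = raw.pop("rna_qc", {})
        atac_raw = raw.pop("atac_qc", {})
        if "candidates" in raw:
            raw["candidates"] = tuple(raw["candidates"])
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        return cls(
            sim=SimConfig(**sim_raw),
            rna_qc=RnaQcThresholds(**rna_raw),
            atac_qc=AtacQcThresholds(**atac_raw),
            **raw,
        )


# ---------------------------------------------------------------------------
# pipeline driver


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> qc -> lineage -> deviations -> enrichment -> coaccess
    -> survival, writing every stage's outputs plus a provenance manifest.

    Returns the manifest dict (also written to ``outdir/manifest.json``).
    Rerunning with an identical config reproduces identical file hashes.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
        written.append(path)

    sim = config.sim
    logger.info("stage simulate: seed=%d", sim.seed)
    atac, peak_table, membership, atac_meta = generate_atac(sim)
    rna, rna_meta, mito_mask = generate_rna(sim)
    cohort = generate_cohort(sim)
    if config.run_simulate:
        written += write_sparse_matrix(atac, out / "atac")
        written += write_sparse_matrix(rna, out / "rna")
        write_peaks(peak_table, out / "peaks.bed", out / "peaks_annot.tsv")
        written += [out / "peaks.bed", out / "peaks_annot.tsv"]
        write_motif_membership(membership, out / "motifs.tsv")
        written.append(out / "motifs.tsv")
        cohort.to_csv(out / "cohort.csv", index=False)
        written.append(out / "cohort.csv")
        emit(atac_meta, "atac_cells.tsv", index=True)
        emit(rna_meta, "rna_cells.tsv", index=True)

    if config.run_qc:
        logger.info("stage qc")
        kept_rna = filter_rna_cells(rna, mito_mask, config.rna_qc)
        pd.Series(kept_rna).to_csv(
            out / "kept_rna_barcodes.tsv", sep="\t", index=False, header=False
        )
        written.append(out / "kept_rna_barcodes.tsv")
        rna = rna.subset_cells(kept_rna)
        rna_meta = rna_meta.loc[kept_rna]

    calls = None
    if config.run_lineage:
        logger.info("stage lineage")
        expr = normalize_cp10k(rna)
        epcam_pos = epcam_positive_cells(rna)
        flagged = flag_epithelial_clusters(rna_meta["cluster"], epcam_pos)
        markers = derive_markers(expr, rna_meta["cluster"].to_numpy())
        emit(markers, "markers.tsv")
        scores = {}
        for ct in sorted(rna_meta["cluster"].unique()):
            sig = signature_from_markers(markers, ct)
            if len(sig):
                scores[ct] = score_signature(expr, sig)
        score_df = pd.DataFrame(scores)
        in_flagged = rna_meta["cluster"].isin(flagged).to_numpy()
        calls = assign_cell_type(score_df, in_flagged)
        emit(calls, "lineage_calls.tsv", index=True)

    devs = None
    if config.run_deviations or config.run_enrichment or config.run_coaccess:
        logger.info("stage deviations")
        membership_fam = reduce_motif_family(
            membership,
            [m for m in ETS_FAMILY_MEMBERS if m in membership.columns],
            ETS_FAMILY_NAME,
        )
        devs = compute_deviations(
            atac,
            peak_table,
            membership_fam,
            k=config.k_neighbors,
            n_iterations=config.background_iterations,
            seed=config.seed,
        )
        emit(devs.z, "deviation_z.tsv", index=True)
        emit(devs.undefined.astype(int), "deviation_undefined.tsv", index=True)

    if config.run_enrichment:
        logger.info("stage enrichment")
        enrich = celltype_motif_enrichment(
            devs.z, atac_meta["cell_type"].to_numpy()
        )
        emit(enrich, "motif_enrichment.tsv")

    if config.run_coaccess:
        logger.info("stage coaccess")
        subset = [
            c
            for c, ct in zip(atac.cells, atac_meta["cell_type"])
            if ct == config.coaccess_cell_type
        ]
        candidates = [c for c in config.candidates if c in membership.columns]
        coaccess = coaccessibility_test(
            atac,
            peak_table,
            membership_fam,
            candidates,
            subset,
            family=ETS_FAMILY_NAME,
            k=config.k_neighbors,
            n_iterations=config.background_iterations,
            seed=config.seed,
        )
        emit(coaccess, "coaccessibility.tsv")

    if config.run_survival:
        logger.info("stage survival")
        surv = quartile_logrank(cohort, stratify_by_erg=True)
        emit(surv, "survival_logrank.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "sim_seed": sim.seed,
        "thresholds": {
            "rna_qc": dataclasses.asdict(config.rna_qc),
            "atac_qc": dataclasses.asdict(config.atac_qc),
            "k_neighbors": config.k_neighbors,
            "background_iterations": config.background_iterations,
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
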