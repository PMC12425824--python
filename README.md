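# chromstate

Single-cell chromatin-state analysis of an oncogene-driven epithelial cell
program, built around the question: *when a transcription factor such as ERG
rewires chromatin in a rare intermediate (IM) epithelial state, which other
factors act within that rewired landscape?* The package reimplements, as a
tested and reusable pipeline, the analysis chain used to characterize the
ERG⁺ IM state in prostate epithelium:

1. **QC filtering** of scRNA-seq cells (< 500 or > 100k transcripts, ≥ 40%
   mitochondrial reads removed) and scATAC-seq cells (TSS enrichment < 4,
   < 1,000 unique fragments, > 1M reads removed).
2. **Epithelial lineage assignment**: clusters with ≥ 50% Epcam⁺ cells are
   flagged epithelial; cells are scored against basal/L1/L2/L3 gene
   signatures (mean z-score of log-normalized expression) and take the
   argmax label; signatures are derived from labeled cells by Wilcoxon
   rank-sum marker testing (padj < 0.05, fold change > 2).
3. **Motif accessibility deviations** (chromVAR-style): for a peak set *S*
   with observed counts *X* and margin-product expectation *E*,
   per cell *j*

   y_j = (Σ_{i∈S} X_ij − Σ_{i∈S} E_ij) / Σ_{i∈S} E_ij,

   bias-corrected against *B* background peak sets matched on GC content and
   mean accessibility: d_j = y_j − mean_b(ỹ_j⁽ᵇ⁾) and
   z_j = d_j / sd_b(ỹ_j⁽ᵇ⁾).
4. **Cell-type motif enrichment**: upper-tail hypergeometric test of
   motif-accessible cells (z > 0) per cell type, BH-corrected, with an
   FDR < 10⁻²⁰ display rule plus the two retention filters (normalized mean
   gene expression > 1 per cell type; positive Spearman correlation between
   deviation z and the motif's gene score).
5. **ETS co-occurrence co-accessibility test**: ERG/ETS/ETV/FLI motifs are
   collapsed into one ETS family identifier; peaks carrying a candidate
   motif and/or ETS are partitioned into BOTH / candidate-only / ETS-only
   sets, and per-cell deviation z of BOTH is compared with each exclusive
   set by a one-sided Wilcoxon rank-sum ("greater"), FDR-corrected across
   candidates.
6. **Signature-quartile survival stratification**: bulk samples scored by a
   gene signature, labeled ERG⁺ when > 50% of tumor cells are ERG⁺, split
   into top/bottom score quartiles within each ERG stratum, and compared by
   the log-rank (Mantel–Cox) test.

No accession is required: a seeded **synthetic multiome generator** emulates
the statistical structure of the study data (cell-type-specific peak
programs, GC-heterogeneous peaks, motif co-occurrence amplified 2× in the IM
state, Epcam⁺ epithelial clusters with mitochondrial-fraction variation, and
a survival cohort with signature-linked hazards), so every stage can be
validated against planted ground truth.

## Worked example

Generate a synthetic multiome at the default study conditions (200 cells
over basal/L1/L2/IM, 2,000 peaks, 2× ETS co-occurrence amplification in IM
cells) and run the co-accessibility test inside IM cells:

```python
import chromstate as cs
from chromstate.motifs import reduce_motif_family

cfg = cs.SimConfig(seed=1)
atac, peaks, membership, meta = cs.generate_atac(cfg)
fam = reduce_motif_family(membership, ["ERG", "ETS", "ETV", "FLI"], "ETS_family")
im_cells = [c for c, ct in zip(atac.cells, meta["cell_type"]) if ct == "IM"]
result = cs.coaccessibility_test(
    atac, peaks, fam, ["STAT3", "NFKB2", "FOXA1"], im_cells,
    family="ETS_family", seed=1,
)
print(result[["candidate", "comparison", "n_peaks_group",
              "statistic", "p_value", "fdr"]].to_string(index=False))
```

prints

```
candidate        comparison  n_peaks_group  statistic      p_value          fdr
    STAT3  both_vs_ets_only            301     2491.0 6.060045e-18 9.649429e-18
    STAT3 both_vs_cand_only            301     2496.0 4.492598e-18 6.738897e-18
    NFKB2  both_vs_ets_only            349     2490.0 6.432953e-18 9.649429e-18
    NFKB2 both_vs_cand_only            349     2498.0 3.984406e-18 6.738897e-18
    FOXA1  both_vs_ets_only            281     1033.0 9.331158e-01 9.331158e-01
    FOXA1 both_vs_cand_only            281     2308.0 1.547309e-13 1.547309e-13
```

STAT3 and NFKB2 are planted with 2× amplification where they co-occur with
ETS in IM cells, and both comparison directions reach FDR ≪ 0.05: peaks
carrying the candidate *and* ETS are more accessible in IM cells than peaks
carrying either motif alone — the signature of a factor acting inside the
ETS-rewired chromatin. FOXA1 carries no planted signal and is not
significant in both directions (its candidate-only comparison picks up the
genuine amplification present in the shared ETS peaks, which is why the call
requires both directions).

The same analysis is available from the shell:

```bash
chromstate run --outdir out --seed 1      # full pipeline on synthetic data
chromstate simulate --outdir data --seed 1
chromstate qc rna --matrix data/rna --out kept.tsv
chromstate survival --cohort out/cohort.csv --out logrank.tsv
```

Every run writes `manifest.json` with the SHA-256 of each output, the seeds
and the thresholds; reruns with the same config are byte-identical.

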