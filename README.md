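# epispatial

Tools for dissecting **epidermotropic Merkel cell carcinoma (MCC)** — tumor
cells growing inside the epidermis rather than in the usual dermal nodules —
from high-definition (2 µm bin) spatial transcriptomics and independent
single-cell RNA-seq. The package is aimed at computational biologists who
want a tested, reusable implementation of the full analysis chain:

1. **Bin-to-cell reconstruction** — nuclear labels are expanded to nearby
   2 µm bins (nearest-seed assignment within a distance cap `d_max`, ties to
   the smaller label id) and bin counts are summed per cell; cells are then
   QC-filtered on genes/UMIs.
2. **Histomorphological selection** — cells are assigned to annotated tissue
   regions (epidermis, dermal tumor core, perivascular disk, follicle) by
   polygon containment, and tumor cells are kept by `CCER2 > 0`.
3. **Pooled, keratin-excluded PCA** — selected cells from all samples are
   depth-normalized (counts-per-10k, log1p), keratin (`^KRT`) genes are
   excluded, and a gene-centered SVD yields scores `S = UΣ`, unit-norm
   loadings `V` and explained-variance ratios `σ_k²/Σσ²`. Batch structure is
   reduced by per-sample centering of scores. Each cell-type cluster gets a
   95% confidence ellipse of a fitted bivariate t (EM, fixed ν = 4), with
   boundary `(x−μ)ᵀΣ⁻¹(x−μ) = 2·F⁻¹(0.95; 2, ν)`.
4. **Loading enrichment** — a one-sided Mann–Whitney test asks whether a
   marker panel (e.g. cutaneous SCC markers) sits high in the PC1 loading
   ranks; a hypergeometric ORA with Benjamini–Hochberg adjustment covers
   arbitrary gene-set collections.
5. **Zero-preserving imputation (ALRA-style)** — rank-k SVD approximation,
   per-gene thresholding at the magnitude of the most negative reconstructed
   entry, and per-gene rescaling to the original non-zero moments; the rank
   is picked from singular-value spacings (largest gap above mean + 6 sd of
   the noise-tail spacings).
6. **AUCell / regulon specificity** — per-cell gene-set activity as the
   normalized area under the recovery curve over the top 5% of each cell's
   expression ranking; regulon specificity score RSS = 1 − √JSD between the
   normalized activity distribution and a cell-class indicator.
7. **Rule-based subtype gating** — raw-count boolean rules call the three
   MCC subpopulations (epiMCC: `CCER2>0 & KRT5>0 & (CALML3>0|CALML5>0)`;
   vasMCC: `CCER2>0 & KRT20>0 & (COL3A1>0|COL1A1>0)`; cMCC: `CCER2>0 &
   KRT20>0` without collagens or KRT5), followed by balanced subsampling,
   per-gene Wilcoxon differential expression ranked by fold change, and
   intersection of upregulated genes with enhanced-TF regulon targets.

A first-class **synthetic generator** (`epispatial.synthio`) emulates the
study design with known ground truth — an epidermis band with basal and
suprabasal keratinocytes and intraepidermal tumor nests, a dermal tumor
nodule, a perivascular disk and a follicle; negative-binomial counts split
multinomially over each cell's bin footprint — so every stage is testable
without any data download.

## Worked example

```python
from epispatial import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1))
print(report["gate"]["per_class"])
print({k: round(v, 2) for k, v in report["pca"]["pc1_centroids"].items()})
print(f'{report["enrich"]["cscc_pc1_p"]:.3g}')
```

prints (seed 1):

```
{'epiMCC': {'gated': 300, 'precision': 1.0, 'recall': 1.0}, 'cMCC': {'gated': 998, 'precision': 1.0, 'recall': 0.998}, 'vasMCC': {'gated': 499, 'precision': 1.0, 'recall': 0.998}}
{'epiMCC': 6.89, 'keratinocyte': 9.63, 'cMCC': -8.81, 'vasMCC': -9.62}
3.89e-08
```

Reading: the boolean gates recover the planted subtypes essentially
perfectly at scRNA-seq depth; on the spatial arm the epidermotropic-MCC
cluster centroid sits on PC1 *between* the tumor-core and keratinocyte
clusters (an intermediate, keratinocyte-shifted phenotype); and the
cutaneous-SCC marker panel is strongly enriched among the top PC1 loadings
(rank-sum p ≈ 4·10⁻⁸). The same objects are available from the command
line (`epispatial simulate / segment / annotate / pca / enrich / impute /
score / gate / dge / run`).

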