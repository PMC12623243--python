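# Methods

## The synthetic tissue and count model

The generator (`epispatial.synthio`) emulates a skin tumor with
epidermotropic Merkel cell carcinoma on a 2 µm bin lattice. The tissue plan
is deterministic given the grid shape: an epidermis band across the top
(about one sixth of the grid height, with the basal third of the band as
the basal monolayer), a circular dermal tumor nodule (radius one third of
the smaller grid dimension), a perivascular disk inside the nodule, a
follicle strip, and dermal background. Cells are placed on a jittered
lattice inside their home region with spacing `2·r_max + 3` bins, so
footprints of distinct cells never overlap and every bin of a cell is
closer to its own nucleus than to any other; this is what makes the
bin-to-cell step exactly invertible on clean simulations and is a
deliberate simplification of real, crowded tissue.

Counts follow the standard sparse-UMI model: for a cell of type *t* with
library size `L_t`, gene *g* is drawn negative-binomial with mean
`L_t · p_{t,g}` and shared dispersion θ (default 2), where the type-specific
proportions `p_{t,g}` come from a common baseline (log-normal weights for
filler genes) multiplied by `exp(effects)`. Planted programs mirror the
biology being modeled: an MCC core program (CCER2, SOX2, HES6, ATOH1,
CHGA), KRT20 for the classical tumor cytokeratin, a keratinocyte program
(KRT5, KRT1, KRT10, CSTA), an epidermal/cSCC-like differentiation program
(SFN, S100A2/A8/A9/A16, CALML3/5, FABP5, SPRR1B, KRT6A/B, PERP) and an
EMT/collagen program (COL1A1, COL3A1, VIM). Defining programs get
`+marker_effect` (default 3 log-units, ~20-fold), secondary programs half
that, and actively silenced programs `−3·marker_effect`. Silencing is
finite rather than exact zero so that a zero marker effect makes all types
statistically exchangeable — a property the tests exploit.

Each cell's gene counts are then split over its disk footprint by assigning
every UMI a uniformly random bin, so bin sums reproduce the cell draw
exactly (conservation is asserted in tests). Ambient background adds
Poisson(λ) per bin per gene with λ = 0.001; at 300 genes this is ~0.3
ambient UMIs per bin, small against the 150–650 UMI/cell libraries of the
spatial arm but enough to exercise QC. The dissociated scRNA-seq arm uses
the same programs at a deeper default of 2,000 UMIs/cell.

**What the generator does not emulate:** overlapping and irregularly shaped
cells, segmentation errors, spatially varying ambient contamination,
batch/sample effects beyond a sample id, doublets, and any H&E appearance.
Tests passing on these simulations therefore validate the *algorithms'
contracts* (conservation, calibration, recovery of planted structure), not
their robustness to every artifact of real Visium HD data.

## Bin-to-cell reconstruction

`expand_labels` assigns every unlabeled bin within Euclidean distance
`d_max` of a nuclear seed bin the label of the nearest seed bin, with exact
integer-arithmetic distances and ties broken toward the smaller label id —
fully deterministic and order-independent. Note that the operation is not
idempotent: re-applying it treats previously expanded bins as seeds and
grows the labels further, exactly as with scikit-image's `expand_labels`.
Aggregation sums counts per label and takes the unweighted centroid of the
label's bins. QC defaults (min 20 genes, min 50 UMIs, no upper cap) are a
permissive floor chosen for shallow segmented data where per-cell means of
only a few hundred UMIs are expected; all thresholds are arguments. Sample
exclusion for insufficient depth is a reporting decision — `qc_report`
prints per-sample medians and the analyst drops a sample by configuration.

## Selection, rank-sum testing

Region assignment uses polygon containment of the centroid (boundary
inclusive); a centroid covered by nested annotations takes the
smallest-area polygon, which resolves e.g. the perivascular disk inside
the tumor nodule. Marker positivity (`CCER2 > 0`) is decided on raw
counts, making the selection invariant to any normalization choice.
`rank_sum_compare` is the Mann–Whitney U test: exact null distribution for
combined n ≤ 25 without ties, tie-corrected normal approximation
otherwise; two identical constant groups return p = 1 by convention since
the ranks carry no information.

## Pooled PCA and t ellipses

Normalization is counts-per-10,000 + log1p — the dominant single-cell
convention, used because zero-preserving downstream steps (ALRA, AUCell)
expect a normalized non-negative matrix. Keratin exclusion removes every
`^KRT` gene *before* the SVD, so no keratin can appear in any reported
loading. The PCA is a gene-centered SVD with a fixed sign convention (each
loading column's largest-magnitude entry is positive) so loadings are
comparable across runs; explained variance is relative to the total
variance of the centered matrix. Batch correction is per-sample centering
of the score matrix, recorded as such in the result metadata — it removes
per-sample location shifts in the embedding and nothing else; it is not an
integration method. In the pipeline, PC1 is additionally oriented so the
keratinocyte pole is positive before enrichment, a pure sign choice.

The per-cluster ellipse is the level set of a bivariate t-distribution
fitted by the standard fixed-ν EM (weights `(ν+2)/(ν+δᵢ)`, δ the squared
Mahalanobis distance), ν = 4 by default as a conservative heavy-tailed
choice for embeddings with outlying sparse cells. The boundary uses
`r² = 2·F⁻¹(level; 2, ν)`: because `δ/2 ~ F(2, ν)` under the fitted t, the
ellipse is an exact quantile region of the fitted model and Monte-Carlo
coverage calibrates to the nominal level (tested at 0.95 ± 0.01 with
10,000 draws). The alternative `F⁻¹(level; 2, n−2)` radius familiar from
normal-theory plotting under-covers a ν = 4 fit by roughly ten points and
is deliberately not used.

## Enrichment

The PC1/cSCC comparison is a one-sided Mann–Whitney test of marker
loadings against all other loadings — threshold-free, direction-aware and
matching a ranked-loading display; its p-values are uniform under random
marker placement (calibration-tested). Over-representation is the plain
hypergeometric upper tail on user-supplied GMT sets with BH adjustment
across sets; no ontology databases are bundled.

## Imputation

`alra` computes the rank-k SVD approximation, zeroes per gene every entry
below the magnitude of that gene's most negative reconstructed value (the
symmetric-error argument for preserving biological zeros), rescales the
surviving entries per gene to the original non-zero mean/sd, and clips
residual negatives to zero. Genes that were all-zero stay all-zero by an
explicit guard. Rank selection takes the largest singular-value spacing
exceeding mean + 6 sd of the last 20 spacings; on spectra whose noise tail
has smooth spacing statistics this recovers a planted rank exactly, while
on full spectra of small Gaussian-noise matrices the edge of the noise
bulk can push the choice one or a few ranks high — a characteristic of the
spacing rule worth knowing; the rank can always be fixed explicitly.

## Scoring

AUCell ranks each cell's genes by expression descending with a seeded
random tie-break (a fixed shuffled gene order as the secondary sort key,
so scores are invariant to monotone transforms and reproducible), takes
the top 5% of ranks by default, and normalizes the cumulative hit count by
its maximum. Regulon activity scores a regulon's positive targets only;
repressed targets are excluded as the least-assumption default. The RSS is
`1 − sqrt(JSD(P, Q))` with base-2 logs (P the activity normalized over
cells, Q the class indicator distribution), so scores live in [0, 1] and
equal 1 exactly when activity matches the class indicator. "Enhanced"
regulons for a class must both maximize RSS in that class and differ in
activity from the remaining cells at rank-sum p < 0.05.

## Gating and differential expression

Gate atoms are evaluated on raw counts (`non-zero ⇔ count > 0`). Rules are
tested in precedence order epiMCC → vasMCC → cMCC; the first two rules are
not mutually exclusive as written (a KRT5⁺/CALML⁺/collagen⁺ cell satisfies
both), and the epidermal call wins as the rarer, more specific phenotype,
whereas epiMCC/cMCC are provably disjoint (cMCC requires `KRT5 == 0`).
Balanced subsampling draws each class down to the smallest class size
without replacement, seeded. Differential expression runs the rank-sum
test per gene on normalized expression with BH adjustment; fold change is
the log2 ratio of group means with a 10⁻⁹ pseudocount, robust for sparse
data; "significant" defaults to adjusted p < 0.05 and is configurable.

## Problem sizes and determinism

Default study conditions: a 200×300-bin grid with 220 spatial cells across
six types, 300 genes, and a 3,000-cell scRNA-seq arm (300 epiMCC / 1,000
cMCC / 500 vasMCC plus keratinocytes and stroma). The test suite and the
acceptance script run these sizes end-to-end in well under a minute each;
larger grids are a config change. Every stochastic step derives its seed
deterministically from one global seed (crc32-salted `SeedSequence`), so
pipeline reports and acceptance JSON are bit-reproducible per seed. Known
limitations beyond the generator's scope: Harmony-style integration is
intentionally absent (per-sample centering is a labelled surrogate), the
gating counts of the public scRNA-seq deposit can only be reproduced with
that deposit on disk, and the rank-selection overshoot noted above.
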