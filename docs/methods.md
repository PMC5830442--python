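# Methods

## The replicability score

The question the package answers is operational: if cell type *t* has a
transcriptional identity that is real rather than an artifact of one
laboratory's pipeline, then a classifier trained on *t*'s cells in some
studies should retrieve *t*'s cells in a study it has never seen. The
classifier is deliberately simple and parameter-free — neighbor voting on a
rank-standardized Spearman network — so the score measures the data, not
the model's capacity.

**Network.** For gene set *S* (intersected with the shared gene universe;
fewer than two usable genes is an error), each cell's profile over *S* is
rank-transformed (average ranks for ties) and the Pearson correlation of
rank vectors taken — Spearman's rho. The full matrix, diagonal included, is
then jointly replaced by rank / max(rank). Joint (whole-matrix) ranking
keeps the matrix symmetric; dividing by the maximum *attained* rank rather
than the entry count makes the top weight exactly 1 even when several
entries tie there (the diagonal always does). Correlations are rounded to
12 decimals before ranking so that mathematically tied similarities (e.g.
duplicate cells) are treated as ties instead of being ordered by float
noise. A cell with zero variance over *S* has undefined correlations; they
are set to 0 with a warning so the network stays total. The network is
dense O(cells²); inputs above a configurable ceiling (default 50,000 cells)
are refused outright.

**Voting and scoring.** Node degree (row sum, self-edge included) is the
null predictor: dividing the vote **W y** by it downweights cells that are
generically similar to everything. One study at a time is the test set; its
labels are zeroed in **y**, so training positives pool across the remaining
studies and a hidden cell cannot vote for itself. Scores are compared only
within the test study — cross-study score offsets (experiment identity)
therefore cannot inflate performance — and summarized by the analytic
rank-sum AUROC. A fold where the test study lacks positives or negatives,
or where no training study labels the type, is undefined (NA) and excluded
from the mean rather than scored 0. Iteration order (sorted studies, sorted
types, gene sets in input order) is fixed, so outputs are byte-reproducible.

## Data handling

Studies are merged onto an explicit gene universe (default: union of study
genes in order of first appearance); genes a study lacks are zero-filled,
duplicate gene rows are averaged beforehand, and cell ids are namespaced
`study|cell` because barcode reuse across studies is routine. Cell-level QC
removes cells expressing fewer than 1000 genes at a raw value > 0 (the
threshold is a parameter; the count is taken before any transformation).
Cells without a metadata row are kept but never enter training labels. The
original probe-array gene universe used in early published analyses is not
reconstructible from public text, which is exactly why the universe is an
argument here rather than a constant.

## Gene-set selection

GO-style collections are consumed as GMT and filtered to 20–1000 genes
after intersection with the universe (both bounds inclusive). Random sets
are size-matched to a template distribution. CV centile sets rank each
gene's coefficient of variation within each study, average ranks across
studies over the shared genes, and split into equal-count bins; the top bin
is flagged because extreme-CV genes are noise-dominated and empirically
uninformative. HVG selection bins genes into expression deciles (equal
count, by mean expression; ties at edges broken by gene id), drops the
most highly expressed bin, and takes the top 25% most variable genes per
remaining bin — ceil, so small bins contribute at least one gene. Variance
is used as the variability statistic: binning by expression level already
controls the mean–variance trend, making plain variance the simplest
defensible choice (CV would double-penalize high-mean genes within a bin).
Per-study lists combine by intersection, or by strict majority (> half of
studies) when intersection grows too stringent with many datasets. Whether
decile binning should use mean or total expression per gene is a genuinely
open choice; mean is used because it is invariant to cell count.

## Subtype matching

When label vocabularies differ, every study-qualified subtype is used both
as training positive and as test positive: entry (A, B) of the matching
matrix is the mean of the A→B and B→A AUROCs, where the A→B direction
trains on all of A's cells and evaluates B's cells against the other cells
of B's study. Within-study entries are filled by seeded 2-fold
cross-validation inside the study; the diagonal is fixed at 1. Candidate
edges are cross-study reciprocal best hits plus all cross-study pairs with
AUROC ≥ 0.95 (the union — a strict mode requiring both is available), and
putative replicate groups are the connected components of that edge graph,
discarding singletons. Components are the minimal closure rule consistent
with multi-study groups; co-maximal ties are flagged rather than broken
silently. One HVG set computed on the compared studies is the default
matching feature set.

## The rarity/subtlety model

Rarity: of the *n* analyzed cells per dataset, round(*r*·*n*) are positives
(half-up, so *r* = 1% at *n* = 100 leaves a single positive), drawn without
replacement, along with one extra held-out negative per positive, disjoint
from the analyzed cells (asserted every replicate). Subtlety: one gene
subset of size round(*s*·genes) is drawn per replicate — from the whole
transcriptome, not the scoring set, since subtlety is a property of the
cell's profile — and applied identically to all positives across all
datasets of the replicate; each positive's values on those genes are
replaced by its paired donor's values, so every modified cell is a splice of
two real cells. The donor pairing is a fresh random bijection per dataset.
Whether the swapped subset should be redrawn per dataset within a replicate
is unstated by the framework's design; sharing it is the stricter,
more-correlated choice and is what is implemented. Scoring uses a fixed
gene set or HVGs re-selected from the subsampled data ("varying" mode).
Replicate seeds derive from the master seed by counter, so any single
replicate is reproducible in isolation. At *s* = 1 positives are resampled
negatives and the score must return to 0.5 — a built-in self-check the
acceptance script exercises.

## Marker discovery

Per contributing dataset, each gene is tested with a one-sided Wilcoxon
rank-sum test (target type vs. all other labeled cells of the dataset;
"greater" direction, since markers are enrichments). Exact enumeration is
used for tie-free pooled samples of ≤ 20, otherwise the tie-corrected
normal approximation with continuity correction — the two agree to about
0.011 in the worst case at the crossover sizes, the intrinsic accuracy of
the normal approximation there. P-values combine by Fisher's method
(−2Σln p on 2k df; zeros clamped to the smallest positive float with a
warning) and are BH-adjusted across genes separately for each replicated
type, matching how per-type marker lists are read. Fold changes are
log2((mean_in + 1)/(mean_out + 1)); the pseudocount of 1 guards against
dropout-heavy zeros and is disclosed in the output. Markers require meta
FDR < 0.001 and log2FC > 2 in *every* contributing dataset, ranked by the
minimum fold change.

## Synthetic data

The generator plants *K* types across *J* studies: log-normal baseline gene
means (heavy-tailed, like real transcript abundance), disjoint marker sets
per type shifted 2^effect_size-fold, per-study per-gene multiplicative
batch factors exp(N(0, batch_sd)), gamma-Poisson counts (gamma shape =
dispersion), and independent dropout. Defaults (3 studies, 2 types, 50
cells/type/study, 500 genes, 50 markers/type, effect 2, batch_sd 0.5,
dropout 0.3, dispersion 2) describe a well-powered two-type comparison with
visible batch structure. What it does **not** emulate: gene–gene
co-expression beyond type membership, library-size gradients, cell-state
continua, or UMI sampling — so passing tests show the pipeline's mechanics
and calibration are right, not that any particular real tissue will score
highly. A separate disjoint-support generator builds the limiting case
where two types share no expressed genes, for which cross-dataset AUROC
must be exactly 1.

## Numerical and scale choices

Acceptance-style checks run at deliberately modest sizes — 300–600 cells,
300–500 genes, 100 model replicates — chosen so the full suite completes in
well under a minute while Monte Carlo error on calibration quantities stays
near ±0.01 AUROC. The analytic AUROC is validated against a brute-force
pairwise oracle to 1e-12 including ties; equality-to-1 assertions allow
1e-9 for accumulated float error in the rank-sum formula. All stochastic
stages take explicit seeds and are byte-reproducible under them.

## Known limitations

Dense networks cap practical size at tens of thousands of cells; there is
no approximate or low-rank variant, no alternative similarity kernels, and
no trainable classifier — all deliberate, since interpretability of the
score is the point. Scores depend on the chosen out-group: an unreasonable
control makes any classification look good, and the closest out-group is
the most informative. Group construction by connected components can chain
distinct types through an intermediate; chains and ties are flagged in the
output rather than resolved automatically.
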