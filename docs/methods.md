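# Methods

This note documents the models behind `sctumor`, the parameters that matter,
what the synthetic generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Expression layers and QC

Expression lives in an `ExpressionMatrix` with three aligned layers:

- **TPM** (raw, non-negative; columns of the simulator sum to 10⁶),
- **log**: TPM values below 1 are treated as unreliable and set to zero
  *before* the `log2(TPM+1)` transform (threshold-then-transform; the
  operation is order-preserving on TPM ≥ 1),
- **centred**: per-gene mean-centred log values. Several analyses
  deliberately read the *un-centred* log layer instead: spike-in ratio
  checks, intratumoral correlation, chromosomal-pattern detection, and the
  self-normalising scorers (rank-based signature scoring, centroid
  classification — centring would fabricate apparent receptor positivity in
  cells with zero receptor expression).

Cell QC consumes a metrics table (total reads, mapping rate, detected genes,
intergenic fraction) computed upstream by an aligner-level tool; a cell must
pass all four thresholds. The defaults (10⁶ reads, mapping ≥ 0.5, ≥ 1000
genes, intergenic ≤ 0.3) are a reasonable operating point for full-length
IFC/plate protocols and are configuration, not dogma.

The gene filter removes genes under-expressed across all tumour groups.
"Expressed in < 10% of all tumour groups" admits two readings; the default
**max-over-groups** rule (keep a gene expressed in ≥ 10% of the cells of at
least one group) preserves group-restricted genes, which downstream
subtype-marker analyses need; the stricter mean-over-groups reading is
available via `QcThresholds(gene_rule="mean")`. Spike-ins and unannotated
genes are exempt from the filter and excluded from CNV inference.

## CNV inference

For each gene, a bulk normal-tissue reference supplies mean and standard
deviation of log expression; single-cell values become Z-scores. Choices:

- **sd floor 0.1** (log2 units): near-invariant reference genes otherwise
  produce explosive Z-scores.
- **Z clamp ±3**: a single dropout event (observed 0 against a mean of ~5)
  would otherwise contribute a Z of −15 and dominate a 150-gene window.
  Clamping trades a mild saturation nonlinearity for dropout robustness; see
  limitations.

Genes are sorted by chromosome and start position and smoothed with a
**moving average of window 150**, computed per chromosome (windows never
span a boundary). At chromosome ends the window shrinks rather than dropping
genes, so the profile keeps one value per gene — required for clustering
cells on equal-length profiles. The smoothed track is then centred by
subtracting each cell's genome-wide mean ("centred values across genes" read
as per-cell centring; per-gene centring is available via `centre="gene"`).

Concordance with DNA evidence: WES segments shorter than 10 kb are discarded
on load; both the truth/WES track and the cell-averaged inferred track are
placed on a 10 Mb half-open grid (0-based internally, BED-compatible on
disk). A segment bin's value is the overlap-length-weighted mean log2 ratio
with uncovered genome counted as diploid (ratio 0); a profile bin is the
mean smoothed value of genes starting in the bin, missing if empty. Pearson
r is computed over shared non-missing bins (≥ 3 required; constant tracks
raise rather than returning NaN).

## Marker-free cell typing

Cells are Ward-clustered (Euclidean distance) on their smoothed profiles;
neither metric nor linkage is canonical, Ward/Euclidean is the standard
default for this kind of dense low-noise profile. `n_clusters` is a required
analysis choice, with an optional silhouette-based auto-select.

The carcinoma decision combines two pieces of evidence, both needed:

- **profile energy** `mean(smoothed²)` — diploid cells have flat profiles;
- **sample dominance** — carcinoma clusters are patient-specific while
  normal cell types co-cluster across patients.

A cluster is carcinoma iff its median energy exceeds `t_cnv` *and* at least
`f_dom` of its members come from one tumour group. Remaining cells are
labelled immune if their immune signature score clears `t_immune`, else
stromal if the stromal score clears `t_stromal`, else flagged unclassified
(counted as stromal when the epithelial score is also low, configurable).

The signature scorer is a single-sample rank-based enrichment statistic
(ssGSEA family): per cell, genes are ranked (average ties), and the score
sums, over the descending-rank list, the difference between the
rank-weighted (`rank^α`, α = 0.25) in-set ECDF and the uniform out-set ECDF,
normalised by the gene count. It is invariant under any strictly increasing
per-cell transform. It stands in for the published two-list
(stromal/immune) purity scorer; the combined-purity regression constants of
that tool are out of scope.

Threshold defaults (`t_cnv = 0.05`, `f_dom = 0.6`, `t_immune = 0.12`,
`t_stromal = t_epithelial = 0.2`) were calibrated once on the generator's
default conditions, where the two sides of each cut are separated by an
order of magnitude (e.g. median profile energy 0.19 for carcinoma vs 0.02
for normal cells; immune score ≥ 0.18 in immune populations vs ≤ 0.06
elsewhere). On real data they should be re-examined against the score
distributions.

Intratumoral correlation structure is reported per tumour group as the
median/IQR of pairwise cell–cell Pearson r on the un-centred log layer,
before and after restricting to carcinoma cells.

## Subtype classification

ER and HER2 module scores are signed weighted averages
`Σ wᵢxᵢ / Σ|wᵢ|` over measured module genes of the centred log layer. The
ER+/HER2+/TNBC decision uses two axis-aligned thresholds with **HER2
precedence** (HER2 amplification dominates clinic-style calling; a cell
positive for both is called HER2+ with its ER score kept as evidence).
Thresholds are fitted by accuracy-maximising grid search over candidate
boundaries (midpoints of sorted scores, thinned by selection rather than
interpolation so true separating boundaries survive; ties resolve to the
smallest thresholds).

TNBC subgrouping correlates each cell (un-centred log, genes never expressed
anywhere removed) against reference centroids by Spearman rho; a cell is
assigned every subtype with rho > 0 and p < 0.05 — possibly several,
possibly none. P-values use the t-approximation; below 12 intersecting genes
a seeded Monte-Carlo permutation p (default 9999 resamples) replaces it —
exact enumeration at n = 10–11 would cost 10⁶–10⁷ permutations per cell for
no practical gain. Fewer than 10 intersecting genes is an error.

Aggressiveness profiling scores arbitrary GMT sets per cell, reports their
pairwise Pearson correlations across cells, and flags cells at or above the
95th percentile on both members of a pair as candidate rare co-activated
subpopulations.

## Immune profiling

NMF uses multiplicative updates for the Frobenius objective, written in the
package because the best-of-`n_restarts` bookkeeping and the per-iteration
error trace (the updates never increase the error — asserted in tests) are
part of the contract; agreement with a standard library implementation is
cross-checked in the test suite. Cells are assigned to the argmax component
of H. Input is the non-negative log layer restricted to an immune signature
panel supplied as GMT (a synthetic stand-in ships for tests).

The zero-inflated LRT models each group's values as
`P(x = 0) = 1 − π`, `x > 0 ~ Normal(μ, σ)` on the log scale. The alternative
frees (π, μ) per group with σ pooled over both groups' positives; the null
shares (π, μ, σ). All MLEs are closed-form, the statistic `Λ = 2(ℓ₁ − ℓ₀)`
is non-negative by nesting and referred to χ²(2). This parameterisation
tests detection-rate and location shifts, which is what the marker rule
needs; a free-σ variant (df = 3) is available via `pooled_sigma=False`.
Groups with no positive values sit at the π boundary and contribute only
the binomial part; with fewer than two positives overall the test reduces
to a detection-only binomial LRT (df = 1). σ estimates are floored at 10⁻³.
Under a null zero-inflated model (π = 0.6, 50 vs 50 cells) the empirical
rejection rate at nominal 0.05 is ≈ 0.055 (Monte-Carlo, 2000 genes).

ROC AUC is the rank-statistic identity `U/(n₊n₋)` with half-credit for
ties. A cluster marker must satisfy all of: mean log difference > 1 (fold
> 2), AUC > 0.7, LRT p < 0.05. Over-representation uses the upper-tail
hypergeometric survival function with zero-overlap terms reported at p = 1.
T-cell (or B-cell) functional states are scored with the same rank-based
scorer and hierarchically clustered on the score vectors.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes:

- per-gene baseline log2 means drawn once from Normal(3, 1.5);
- carcinoma clones with non-overlapping aneuploid segments (CN ∈ {0,1,3,4},
  0.25–0.5 of a chromosome each) shifting expression by
  `cnv_attenuation · log2(CN/2)` with CN 0 mapped to 0.1 copies so a
  homozygous deletion yields a finite signal; default attenuation 0.8
  (dosage propagates to mRNA with modest buffering);
- disjoint 40-gene marker modules per population (T, B, macrophage,
  stromal, epithelial), shifted +4 log2 and deliberately scattered across
  the genome so markers never mimic a CNV footprint;
- per-cell Normal noise (sd 1.0, a field added so cells are not clones of
  their population mean) and mean-dependent logistic dropout
  `P(drop) = expit(slope·(midpoint − mean))`, midpoint 1.0, slope 1.0 — the
  common scRNA-seq assumption; the original protocol states no dropout
  model;
- TPM renormalisation to 10⁶ per cell including three spike-ins at copies
  proportional to 12,200 / 912 / 62;
- bulk normal references sharing the same baseline with sd 0.3 and no
  dropout (bulk averaging);
- ground truth: per-cell population, clone, tumour group, per-clone CN
  track.

Carcinoma cells of clone *k* belong to tumour group *k*; non-carcinoma
cells are spread across groups — this encodes the patient-specificity
assumption the carcinoma rule relies on. Default population sizes are 300
carcinoma (3 clones), 150 immune (60 T / 45 B / 45 macrophage), 30 stromal,
with 3000 genes on six 100 Mb chromosomes — small enough for minutes-scale
test runs, large enough for a 150-gene smoothing window to make sense
(≥ 500 genes per chromosome).

**What the generator does not emulate:** read-level noise, UMIs, batch
effects, doublets, cell-cycle structure, subclonal CNV gradients,
covariance between genes beyond the planted modules, and ambient RNA.
Passing tests therefore demonstrate that the pipeline recovers the signal
it models under its own assumptions — not that those assumptions hold in
any particular real data set.

## Numerical choices and degenerate inputs

- Smoothing uses cumulative sums (exact agreement with the brute-force
  windowed mean is asserted, not approximated).
- Pearson/Spearman on constant vectors raise informative errors instead of
  propagating NaN.
- Hierarchical clustering and NMF are deterministic given their inputs and
  seeds; NMF restarts derive from a single spawning seed sequence.
- The ssGSEA-style score is undefined when the set covers every measured
  gene (no out-set) — an error, as is an empty or unmeasured set.
- Tie handling: average ranks everywhere (scoring, AUC); marker tables sort
  by (cluster, AUC desc, gene id) so output is invariant to cell and gene
  order.

## Known limitations

- The ±3 Z-clamp saturates very strong events: a CN 0 segment (true log2
  ratio −4.3) is compressed toward the clamp, so concordance with the true
  track plateaus — and can dip slightly — once `cnv_attenuation` exceeds
  ~0.5, and single-clone recovery r varies (≈ 0.74–0.97 across clone draws
  at default conditions) depending on which CN states the clone samples.
  Inferred CNV is a relative, not calibrated, copy-number estimate.
- Discrete copy-number calling, SNP/LOH evidence and doublet detection are
  out of scope.
- The immune signature panel, subtype modules and TNBC centroids are
  user-supplied tables; the bundled versions are synthetic stand-ins for
  testing, not biological resources.
- Cell-QC metrics are consumed, not computed; alignment-level QC belongs to
  upstream tools.
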