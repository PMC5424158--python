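# sctumor

Marker-free tumour and immune cell profiling from single-cell RNA-seq.

Single-cell RNA-seq of a solid tumour captures a mixture of carcinoma cells,
tumour-infiltrating immune cells and stromal cells. Surface-marker gating is
often unavailable or unreliable for separating them. `sctumor` instead
exploits the genome: carcinoma cells carry large chromosomal copy-number
aberrations that leave a coherent regional footprint on expression, while
normal cells do not. The package implements the full downstream analysis as
a reusable pipeline:

1. **Expression QC** — four-criterion cell filtering (total reads, mapping
   rate, detected genes, intergenic fraction), `TPM < 1 → 0` thresholding,
   `log2(TPM+1)`, removal of genes expressed in fewer than 10% of cells of
   every tumour group, per-gene mean centring, and spike-in consistency
   checks.
2. **CNV inference** — per-gene Z-scores against a bulk normal-tissue
   reference, clamped to ±3, sorted by genomic position and smoothed with a
   **moving average of 150 genes per chromosome**; the re-centred track is
   the inferred CNV. Concordance with WES segments (> 10 kb) is measured by
   Pearson correlation on a common **10 Mb grid**.
3. **Cell typing** — Ward clustering of the inferred-CNV profiles; clusters
   with high profile energy `mean(smoothed²)` that are dominated by a single
   tumour are called carcinoma (tumour cells are patient-specific, normal
   cells mix across patients); remaining cells are labelled immune or
   stromal by rank-based (ssGSEA-style) signature scores.
4. **Subtyping** — ER/HER2 module scores with two fitted thresholds (HER2
   precedence) split carcinoma cells into ER+ / HER2+ / TNBC; TNBC cells are
   assigned to transcriptional subgroups by Spearman correlation against
   reference centroids (`p < 0.05`, multiple or no memberships allowed);
   EMT/stemness/angiogenesis/proliferation signature scores flag rare
   co-activated cells at top-5% cutoffs.
5. **Immune profiling** — NMF clustering of non-carcinoma cells over an
   immune signature panel; cluster markers by **fold change > 2, ROC AUC >
   0.7 and zero-inflated LRT p < 0.05**; hypergeometric over-representation
   of marker sets; T-cell functional-state scoring (naive, costimulatory,
   regulatory, exhaustion, cytotoxicity).
6. **Synthetic data** — a seeded generator producing expression matrices
   with clone-specific CNV segments (expression shift
   `attenuation · log2(CN/2)`), population marker modules, mean-dependent
   logistic dropout, TPM renormalisation, fixed-copy spike-ins, matched
   normal references, and complete ground truth for every stage.

The zero-inflated likelihood-ratio test models expression in each group as
a point mass at zero (detection probability π) plus a Normal(μ, σ) on the
log scale for positive values; the alternative frees (π, μ) per group with
a pooled σ and the statistic `2(ℓ₁ − ℓ₀)` is referred to χ² with 2 df.

## Worked example

```python
from sctumor import simulate, cnv, celltype, scoring

# default study conditions: 300 carcinoma cells in 3 clones, 150 immune,
# 30 stromal, 3000 genes on 6 chromosomes, with a matched normal reference
exp = simulate.simulate_experiment(simulate.SimulationConfig(seed=1))

ref = cnv.build_reference(exp.normal)
z = cnv.zscore(exp.matrix, ref)
profiles = cnv.smooth_chromosomal(z, exp.annotation)          # inferred CNV

clusters = celltype.cluster_profiles(profiles, n_clusters=4)
scores = scoring.score_gene_sets(exp.matrix.log,
                                 simulate.signature_sets(exp.marker_sets))
labels = celltype.assign_cell_types(clusters, profiles, scores,
                                    exp.matrix.groups)
print(labels["call"].value_counts())

out = celltype.correlation_structure(exp.matrix, labels)
print(out[["median_before", "median_after"]].round(3))
```

prints

```
call
carcinoma    300
immune       150
stromal       30

      median_before  median_after
BC01          0.478         0.572
BC02          0.496         0.528
BC03          0.481         0.567
```

Every cell of the simulated mix is recovered into its true compartment
without using a single marker gene for the carcinoma calls, and restricting
each tumour to its carcinoma cells raises the median within-tumour cell–cell
correlation — the apparent intratumoral heterogeneity contributed by normal
cells disappears.

The same pipeline is scriptable from a shell:

```sh
sctumor simulate --config sim.yaml --outdir data/
sctumor qc --matrix data/expression.tsv --annotation data/annotation.bed \
           --groups data/groups.tsv --outdir qc/
sctumor infer-cnv --matrix data/expression.tsv --annotation data/annotation.bed \
                  --groups data/groups.tsv --normal data/normal_reference.tsv \
                  --outdir cnv/
sctumor classify-cells --matrix data/expression.tsv --annotation data/annotation.bed \
                       --groups data/groups.tsv --profiles cnv/cnv_profiles.tsv \
                       --signatures data/signatures.gmt --n-clusters 4 \
                       --out labels.tsv
```

(plus `cnv-concordance`, `subtype`, `tnbctype`, `immune-cluster`, `markers`,
`ora`, `tcell-states`).

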