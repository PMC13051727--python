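# scqflow

Subpopulation analysis for single-cell qPCR experiments, plus the image and
caliper morphometry that typically accompanies them in wound-healing studies.

Microfluidic dynamic arrays measure ~96 genes in hundreds of sorted single
cells, reporting a cycle threshold (Ct) per reaction — the PCR cycle at which
fluorescence crosses detection, so one cycle lower means roughly twice the
transcript — with some reactions failing to amplify altogether. `scqflow`
implements the standard analysis chain for such data:

1. **Normalization.** Each gene is centered on its pooled median Ct across
   all cells and converted to log2 relative expression,
   `expr[c,g] = clip(median_g(Ct) − Ct[c,g], −B, +B)` with `B = 5` cycles by
   default (a maximal 2⁵ = 32-fold change). Failed reactions
   ("non-expressers") are excluded from the median and floored at `−B`.
2. **Subpopulation discovery.** k-means partitioning minimizing the
   within-cluster sum of squared Euclidean distances (best of 50 seeded
   restarts), complete-linkage Euclidean clustergrams for heatmap ordering,
   and a mean-silhouette selector for the number of clusters.
3. **Differential expression.** Per-gene two-sample Kolmogorov–Smirnov tests
   (cluster-vs-rest or group-vs-group) with Bonferroni correction over the
   gene panel at a strict p < 0.05; significant genes export as a "seed"
   list for downstream pathway tools.
4. **Cross-group comparison.** Clusters fitted independently in two groups
   (e.g. wild-type vs a conditional knockout) are matched one-to-one in
   centroid space by exact Hungarian assignment, and each cluster is called
   *present*, *depleted* (abundance ratio < 0.5) or *absent* in the second
   group.
5. **Immunofluorescence quantification.** RGB micrographs are split by
   channel; nuclei are counted as 8-connected DAPI components above a
   15-pixel size filter under an automated (Otsu) threshold; red/green stain
   areas are binarized at a fixed 0.30 threshold and normalized per cell.
6. **Morphometry.** Caliper tumor volume `V = 0.5·L·W·H` and density
   `D = M/V`; wound-closure fraction-open curves; reference-gene-normalized
   relative expression `2^−ΔCt`.

A seeded synthetic-data generator emulates the 384-cell, four-plate,
96-gene design with planted subpopulations, group-specific cluster presence
and per-reaction dropout, so the whole pipeline is testable end to end
without any instrument export. See `docs/methods.md` for the model details
and design choices.

## Worked example

```python
import scqflow

m, truth = scqflow.generate_ct(seed=1)          # 384 cells x 96 genes
res = scqflow.analyze_groups(m, "WT", "eKO", k_a=4, k_b=3, seed=1)
print(res.report)
```

prints

```
 cluster_a matched_b  centroid_distance  abundance_a  abundance_b  abundance_ratio   status
         1         1           3.732553     0.276042     0.494792         1.792453  present
         2         3           5.706416     0.234375     0.093750         0.400000 depleted
         3      <NA>                NaN     0.255208     0.000000         0.000000   absent
         4         2           4.155019     0.234375     0.411458         1.755556  present
```

Reading this: the Ct matrix was pooled-median normalized, each group was
clustered separately (4 clusters in WT, 3 in eKO), and the WT clusters were
matched to their nearest eKO counterparts. WT cluster 3 found no counterpart
within the match radius and its matched abundance is zero — it is called
absent from eKO — while cluster 2's eKO counterpart holds only 40% of its WT
share, i.e. depleted. The marker genes of the absent subpopulation then fall
out of a cluster-vs-rest K–S comparison:

```python
wt = scqflow.subset_expression(res.expression, res.expression.group_mask("WT"))
diff = scqflow.cluster_vs_rest(wt, res.model_a, 3)
print(diff.significant_genes)   # 12 genes, led by the planted markers G09..G16
```

The same steps are scriptable from a shell via the `scqflow` command
(`scqflow synth ct`, `ingest`, `normalize`, `cluster`, `diff`, `crossgroup`,
`ifquant`, `tumor`, `wound`).

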