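# pleioscan

Parallel genomic divergence scans and pleiotropy contrasts for replicate
ecotype pairs.

When independent population pairs adapt to the same environmental contrast
— say, 16 stream–lake pairs of threespine stickleback — the genomic
windows that diverge in *several* pairs at once ("parallel" windows) point
at loci evolution reuses. `pleioscan` asks whether those reused windows
are distinguished by **pleiotropy**: do they contain more mapped QTL
traits and more highly connected genes than windows that diverge in one
pair or none? The package is aimed at population genomicists working with
replicate-pair designs who want the full chain — genome scan, parallelism
classification, window annotation, permutation inference — as tested,
scriptable pieces.

## What it computes

1. **Window F_ST per pair.** Weir–Cockerham per-SNP variance components
   (θ̂ = a / (a + b + c)), aggregated into fixed 50-kb windows by the
   ratio of sums: F_ST(w) = Σ aᵢ / Σ (aᵢ + bᵢ + cᵢ) over the window's
   variable sites (≥ 3 required by default).
2. **Parallelism.** Per pair, outliers are windows above the genome-wide
   95% F_ST quantile; a window is *parallel* when it is an outlier in ≥ 2
   independent pairs. A continuous companion metric averages each
   window's within-pair F_ST rank (ties averaged) across pairs.
3. **Pleiotropy proxies per window.** Distinct mapped QTL traits (records
   placed by confidence-interval midpoint, duplicates of a trait counted
   once, mean PVE averaged within trait then across traits), and mean
   gene coexpression connectivity kTotal_i = Σ_{j≠i} |cor(xᵢ, xⱼ)|^β from
   an unsigned weighted network (soft power β chosen at scale-free-fit
   saturation or fixed).
4. **Covariates.** Gene density, recombination rate (cM/Mbp interpolated
   from a genetic map), and a precomputed per-window dS mutation proxy.
5. **Inference.** For each metric: the parallel-vs-nonparallel difference
   in class means against a 10,000-iteration label-shuffling permutation
   null (missing windows held in place), and the Pearson correlation with
   mean F_ST rank.

A synthetic-data generator (`pleioscan.simulate`) produces genotypes
(Balding–Nichols divergence), QTL tables, expression matrices, gene
annotation and tracks with known implanted effects plus a ground-truth
table, so the whole pipeline can be exercised and validated without
controlled-access sequence data. See `docs/methods.md` for the model and
every default.

## Worked example

A small end-to-end run — simulate a 4-pair survey, scan, classify,
annotate, and test all six contrasts:

```python
from pleioscan import pipeline
from pleioscan.inference import report_to_frame
from pleioscan.simulate import SimConfig

config = SimConfig(n_pairs=4, n_chromosomes=2, chromosome_length=10_000_000,
                   n_genes=1200, n_modules=12, seed=42)
result = pipeline.end_to_end(config, n_iter=2000, seed=7)
frame = report_to_frame(result["report"])
cols = ["metric", "mean_parallel", "mean_nonparallel", "diff", "perm_p", "r", "assoc_p"]
print(frame[cols].round(3).to_string(index=False))
n_par = int((result["calls"]["status"] == "parallel").sum())
print(f"\nparallel windows: {n_par} of {len(result['calls'])}")
```

prints

```
           metric  mean_parallel  mean_nonparallel   diff  perm_p      r  assoc_p
      trait_count          3.200             1.648  1.552   0.005  0.343    0.000
         mean_pve          8.978             9.684 -0.706   0.678  0.066    0.458
mean_connectivity          1.307             0.978  0.329   0.008  0.178    0.001
       gene_count          3.100             3.321 -0.221   0.615  0.042    0.405
recomb_cm_per_mbp          4.470             4.017  0.453   0.233 -0.002    0.964
               ds          0.913             0.919 -0.005   0.658 -0.039    0.433

parallel windows: 20 of 400
```

Reading the table: parallel windows carry about twice the mapped-trait
count of nonparallel windows (3.20 vs 1.65, permutation p = .005) and
higher mean connectivity (p = .008) — these are the implanted effects the
generator planted, recovered through the full scan-and-classify chain.
The covariates (gene count, recombination, dS), which were simulated with
no class difference, correctly come back non-significant. `perm_p` is the
two-sided add-one permutation p-value; `r` / `assoc_p` are the Pearson
correlation of each metric with mean F_ST rank and its t-test p-value.

## Command line

The same pipeline is scriptable from a shell via one YAML config
(simulation block and/or real-data input paths):

```sh
pleioscan simulate --config run.yaml   # write fixture files + manifest
pleioscan scan     --config run.yaml   # window F_ST, outliers, parallelism
pleioscan annotate --config run.yaml   # QTL/connectivity/track annotation
pleioscan analyze  --config run.yaml   # permutation contrasts -> report.json
pleioscan all      --config run.yaml   # everything in memory
```

Real data enters as a VCF per pair (samples prefixed by population) or a
genotype-count TSV, a QTL TSV (a loader profile for curated QTL-database
exports is included), a genes × samples FPKM TSV with a gene BED, a
genetic-map TSV and a per-window dS TSV. Exit codes: 0 success, 2
configuration error, 3 data error.

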