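# screg

Model-based reconstruction of cis-regulatory element (CRE) activity from
sparse single-cell ATAC-seq data.

Per-cell scATAC-seq counts on 200-bp genome bins are too sparse to read
the activity of an individual regulatory element. `screg` recovers a
continuous per-element activity estimate by combining three sources of
information under one Poisson count model:

1. **A bulk regulome compendium.** Each element's cell-type-independent
   baseline mean and SD (`m`, `s`, on log scale) are estimated from many
   bulk open-chromatin samples by method of moments under a
   Poisson-lognormal model, and elements are clustered by their
   cross-sample co-activation pattern at many granularity levels.
2. **Co-activated elements.** Within a cell, elements of one cluster
   share a latent activity `beta ~ N(0, 1)`; the observed counts are
   `y ~ Poisson(L * exp(h(m + s * beta)))`, where `h` is a monotone
   I-spline technical-bias function fitted per cell on elements whose
   bulk activity is nearly constant. The cluster number `K` is chosen
   adaptively by cross-validation on held-out elements, so the analysis
   resolution grows with sequencing depth.
3. **Similar cells.** Cells are clustered on quantile-normalized
   cluster-level features (PCA, 2-D stochastic-neighbor embedding,
   Gaussian-mixture BIC) and pooled into pseudo-cells before the model is
   applied.

Reconstructed activities are extended to non-catalog bins with
gradient-boosted trees, and peaks are called by a moving-average
empirical-FDR procedure. A generative simulator (`screg.simulate`)
produces compendium and single-cell data from the exact model, so every
estimator has a closed-loop recovery test.

## CLI

```sh
screg --seed 0 simulate --scale tiny --out fx            # synthetic fixture suite
screg --seed 0 compendium --counts fx/compendium.mtx \
      --bin-bed fx/compendium.bins.bed --out-dir arts    # catalog, effects, clustering
screg --seed 0 fit --cells fx/cells.mtx \
      --bin-bed fx/cells.bins.bed --artifacts arts \
      --out-dir out                                      # cluster cells, reconstruct tracks
screg --seed 0 callpeaks --track out/cluster0.bedgraph \
      --bin-bed fx/compendium.bins.bed --out peaks.bed
screg tfbs --track out/cluster0.bedgraph \
      --bin-bed fx/compendium.bins.bed \
      --motif-bins motifs.bed --out ranked.bed
```

`segment` and `count` build bin indices and count matrices from
chromosome sizes and read BEDs; `cluster-cells` runs the cell-clustering
stage alone. All randomness flows from the global `--seed`.

## Library layout

| module | contents |
| --- | --- |
| `screg.genome` | bin index, region sets, read counting |
| `screg.io` | BED/bedGraph/MTX/TSV readers and writers |
| `screg.compendium` | normalization, signal bins, locus effects, low-variability set, 3-stage multi-resolution clustering |
| `screg.model` | bias spline, cluster-activity posterior modes, CV over `K`, reconstruction |
| `screg.cells` | cell features, quantile normalization, filtering, cell clustering, pseudo-cell pooling, pipeline driver |
| `screg.postprocess` | non-catalog bin prediction, track assembly |
| `screg.peaks` | peak calling, sensitivity-FDR curves, TFBS ranking |
| `screg.simulate` | generative simulator and fixture suites |

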