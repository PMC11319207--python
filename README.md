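# crossacd

Statistics for quantifying **cross-domain gene coactivation in single
cells**, built around the observation that acute loss of the cohesin
complex (degradation of its RAD21 subunit) increases coordinated
fluctuation of gene activity across accessible chromatin domains (ACDs)
without changing population-average expression.

The package is aimed at researchers analysing single-cell genomics and
imaging readouts of chromatin perturbations.  It reimplements, as a
tested and reusable library + CLI, the full statistical chain:

* **ACD segmentation** — ATAC signal binned at 200 kb; local maxima with
  topographic prominence above the genome-wide mean signal seed a
  domain, extended over the contiguous above-mean run; plus annotation
  enrichment (500-bp windows, fold change vs genome) and mean Hi-C
  contact per ACD pair.
* **Cross-ACD coexpression** — per gene pair, the tied-rank Spearman
  correlation over cells

  $$S_{x,y} = \frac{\sum_i (x_i-\bar x)(y_i-\bar y)}
      {\sqrt{\sum_i (x_i-\bar x)^2 \sum_i (y_i-\bar y)^2}}$$

  applied to average ranks; per ACD pair the mean $\bar S_{\mathrm{RNA}}$,
  the differential matrix
  $\Delta S_{\mathrm{RNA}} = S_{\mathrm{RNA,RAD21^-}} - S_{\mathrm{RNA,Ctrl}}$,
  and the sign-count coexpression coefficient
  $\Delta C_{\mathrm{RNA}}(i,j) = (n_{\Delta S+} - n_{\Delta S-}) /
  (n_{\Delta S+} + n_{\Delta S-})$, with distance-decay curves and
  chromosome-wise cis/trans summaries.
* **Cross-ACD coaccessibility** — scATAC counts aggregated per ACD
  (ceiling 1,000), 50% binomial downsampling in 10 paired repetitions,
  normalization to the global matrix mean with removal of poorly
  sequenced cells, Spearman per ACD pair and
  $\Delta S_{\mathrm{ATAC}} = S_{\mathrm{ATAC,RAD21^-}} - S_{\mathrm{ATAC,Ctrl}}$.
* **FISH co-bursting** — pseudocolor barcode decoding of multi-round
  spots (1-pixel xyz cutoff, robust to one dropped round), bursting
  frequency $F = N_b/N$, distance-gated (1 µm) co-bursting and the
  normalized co-bursting frequency
  $F_{\mathrm{co}} = N_{\mathrm{co}} / (F_A F_B N)$ (1 = independence).
* **3D pair cross-correlation** — shell-normalized
  $c_0(r)$ with $\Delta r = 50$ nm and $C(r) = c_0(r)/c_r(r)$ against a
  uniform reference with matched density and volume.
* **Confined-diffusion RoC** — per-track MSD fitted with
  $\mathrm{MSD} = \mathrm{RoC}^2\,(1 - e^{-4 D t/\mathrm{RoC}^2}) +
  \mathrm{offset}$, the standard fit-quality filters, and differential
  cumulative RoC distributions
  $\Delta C(r) = C_{\mathrm{Ctrl}}(r) - C_{\mathrm{RAD21^-}}(r)$.
* **Synthetic data** — generators with known ground truth for every
  stage (correlated negative-binomial/Poisson counts with a tunable
  "cohesin state" coupling, two-territory burst geometries, Thomas
  point processes, reflected Brownian tracks), so each statistic has a
  recovery test without any external download.

## Worked example

Simulate a control/cohesin-depleted contrast over 12 ACDs on two
chromosomes (cis activity coupling raised from 0.1 to 0.5 in the
depleted condition) and run the coexpression contrast:

```sh
crossacd simulate expression --acd-bed acds.bed --n-cells 300 \
    --coupling-cis 0.1 --decay-length-bp 6e6 --seed 11 --label ctrl  --out ctrl.tsv
crossacd simulate expression --acd-bed acds.bed --n-cells 300 \
    --coupling-cis 0.5 --decay-length-bp 6e6 --seed 12 --label rad21 --out rad21.tsv
crossacd coexpr --ctrl ctrl.tsv --depleted rad21.tsv --acd-bed acds.bed \
    --min-genes-per-cell 0 --min-mean-count 0 --out-prefix coex
```

which prints

```
30 quantifiable cis pairs, 36 trans -> coex.*
```

and writes the pair matrices plus summaries.  The chromosome-wise
summary (`coex.chrom_summary.tsv`) for this run is

```
          chr1      chr2
chr1  0.407407  0.061728
chr2  0.061728  0.407407
```

— the diagonal (cis) mean ΔC is strongly positive in both chromosomes
(raising cis coupling pushed most gene-pair correlations up, so the
sign counts tip positive) while the trans mean stays near zero, the
cis-biased signature the statistic is designed to detect.  The
distance-decay table (`coex.decay.tsv`) shows the same effect
concentrated at short genomic distances, where the simulated coupling
kernel is strongest:

```
 distance_bp    mean    sem  n
   6500000.0  0.9111 0.0679 10
  12500000.0  0.3611 0.1703  8
  18500000.0 -0.1481 0.3415  6
  24500000.0  0.5000 0.2103  4
  30500000.0 -0.4444 0.1111  2
```

(ΔC per pair is a sign-count over a 3×3 gene-pair matrix here, so
individual values are coarse multiples of 1/9; the bins hold 10, 8, …
pairs.)

The other stages follow the same pattern: `coaccess` for scATAC
matrices or fragment BEDs, `fish-decode` + `burst-stats` for multi-round
spot tables, `paircorr` for two-channel localization CSVs, `roc` for
track CSVs, each with a matching `simulate` generator.

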