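# Methods

This note documents the statistical models implemented in `crossacd`,
the defaults they use, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the procedure was
genuinely open.

## ACD segmentation

ATAC signal is binned at 200 kb (`Config.bin_size`); the large bin
keeps the downstream cell × domain matrices dense, which is what makes
rank-correlation statistics stable.  Binning is pro-rata: an interval
overlapping several bins contributes weight proportional to overlap
length, so total weight is conserved exactly.

Domains are called in two steps.  First, local maxima of the binned
signal are screened by **topographic prominence** — peak height minus
the higher of the two side minima, each minimum taken along the path to
the nearest strictly higher point or the signal edge, with flat
plateaus collapsed to their middle bin.  The prominence threshold is
the mean of all bin values genome-wide (`prominence_mode="global_mean"`;
a per-chromosome variant is provided).  Second, each retained peak is
extended to the maximal contiguous run of bins whose value strictly
exceeds the same threshold; runs containing several retained peaks are
emitted once.  The peak→interval extension rule is a design choice of
this package: prominence screening alone yields point calls, and the
above-threshold-run rule reproduces the expected ~0.5–2.5 Mb domain
scale on planted landscapes while remaining fully oracle-testable.
`scipy.signal.find_peaks` provides the prominence computation; an
independent O(n²) brute-force implementation in the test suite agrees
with it exhaustively on small signals.

Annotation enrichment divides the genome into 500-bp windows; a window
counts as a "peak window" if it overlaps an ATAC peak by ≥ 1 bp, and a
group's fold change is its peak-window fraction divided by the
genome-wide fraction (enriched ⇔ fold change > 1).  The normalized
contact frequency of an ACD pair is the arithmetic mean of all Hi-C
matrix entries in the bin rectangle spanned by the pair.

## Cross-ACD coexpression

Cells with ≤ 2,600 detected genes are removed (the threshold is
strict: exactly 2,600 detected genes is filtered out), then genes with
mean count < 1 over retained cells are removed.  The boundary of the
gene filter (mean ≥ 1 kept) is configurable; the keep-at-boundary
convention was fixed once and documented because the verbal rule is
ambiguous.

The per-gene-pair statistic is the tied-rank Spearman correlation:
average ranks with ties, then the product-moment correlation of the
ranks.  Constant vectors have no defined correlation and propagate as
missing (NaN) — never as 0, because the downstream coefficient counts
signs and a silent zero would corrupt it.

Per ACD pair (i, j), S̄ is the mean of the gene-pair correlation matrix
(cross-ACD pairs only; self-pairs and the pair diagonal are excluded
from all summaries).  The differential matrix is ΔS = S_depleted −
S_control, computed over the intersection of genes surviving the filter
in both conditions (the set rule is a package choice; the filters are
applied per condition).  The coexpression coefficient is
ΔC = (n₊ − n₋)/(n₊ + n₋) over the signs of ΔS; zero and missing
entries belong to neither count, and a pair with an empty denominator
has no quantifiable value and is excluded from every summary.

Distance-decay curves bin same-chromosome pair values by genomic
midpoint distance (default bin width 1 Mb; the bin width is a
presentation choice, not part of the statistic) with per-bin mean and s.e.m.,
followed by a centred five-point moving average truncated at the
edges.  Chromosome-wise summaries average ΔC within a chromosome (cis)
and per chromosome pair (trans).

"Active ACD" is implemented as an ACD containing at least one gene that
survives the expression filter; genes map to the ACD containing their
midpoint, and ACD pair distance is midpoint distance (midpoints are
scale-stable under boundary changes).

## Cross-ACD coaccessibility

Fragments are assigned to ACDs by fragment midpoint, aggregated per
cell with a ceiling of 1,000 counts per entry, and fragments without a
cell id go to a logged "unassigned" bucket outside the matrix.  To
match read-depth distributions between conditions, both matrices are
thinned by independent Binomial(count, 0.5) draws in 10 repetitions;
the two conditions share each repetition's child seed ("paired"
thinning), which makes the contrast exactly zero for identical inputs.
Plain binomial thinning implements the 50% downsampling; no
histogram-matching step is applied beyond it.

Each thinned matrix is normalized by its global scalar mean and cells
whose mean normalized count falls below 1 (equivalently, mean raw count
below the global mean) are dropped — the poorly-sequenced-cell filter.
The threshold is evaluated per repetition on the post-downsampling
matrix.  Normalization is provably a no-op for the rank correlations
(verified in tests with the filter held fixed); it exists to define the
filter threshold.  Per repetition, the ACD × ACD tied-rank Spearman
matrix is computed across retained cells; repetition matrices are
averaged elementwise over defined entries (matrix-level averaging, not
cell pooling), then ΔS_ATAC = S_depleted − S_control, missing wherever
either side is undefined.

## FISH decoding and co-bursting

Each gene carries a four-round pseudocolor barcode (pseudocolors 1–9);
valid codebooks have unique barcodes differing in ≥ 2 rounds, so any
single dropped round still decodes uniquely.  Spots are clustered
greedily in (round, position) order: a spot joins the nearest cluster
whose centroid lies within the 1-pixel xyz cutoff, which lacks a spot
from that round, and whose members all remain within the cutoff of the
updated centroid.  Clusters covering all rounds must match a barcode
exactly; clusters missing exactly one round match the unique consistent
barcode or are discarded; everything else (ambiguous or mixed clusters)
is discarded.  Decoded positions are centroids converted to nm via the
required `px_nm` pixel size.

Bursting frequency is F = N_b/N (sites per cell; up to ~4 alleles, so
F may exceed 1).  Co-bursting pairs one gene-A site with one gene-B
site per cell by greedy nearest-first matching under the 1-µm 3D gate
(each site used at most once — this prevents double counting with two
alleles; the handling of multiple co-bursts per cell is a package
choice).  The 1-µm gate is the only homolog/territory separation
mechanism; no explicit territory segmentation is performed.  F_co = N_co/(F_A·F_B·N) normalizes
to the independence expectation; condition differentials subtract
control from depleted values elementwise.

## Pair cross-correlation

Shells are half-open, [k·Δr, (k+1)·Δr) with Δr = 50 nm, and the
density denominator uses the exact shell volume
(4π/3)((r+Δr)³ − r³) with r the shell lower edge.  A one-sided shell indicator (counting every pair with
r − r_ij ≤ Δr) would be inconsistent with a shell-volume denominator,
so the standard half-open shell is used.  The reference c_r(r) is the
mean raw correlation over 20 uniform draws (child-seeded) with the same
localization counts in the same volume; C(r) = c0/c_r is undefined
where the reference vanishes.  The bounding volume defaults to the
axis-aligned bounding box of the union cloud; explicit boxes (e.g. a
nuclear mask volume) may be supplied.  Self-pair exclusion is available
for autocorrelation use.  Blinking/photophysics corrections are out of
scope and should be applied upstream.

## Confined-diffusion RoC

Per-track MSD uses all overlapping displacement pairs per frame lag
(lags from frame-index differences, so tracker gaps land on the correct
lag).  The fit model is MSD(t) = RoC²(1 − exp(−4Dt/RoC²)) + offset with
all parameters bounded non-negative; initial guesses are offset₀ = MSD
at the first lag, RoC₀ = √(max MSD − offset₀), D₀ from the initial
slope; fitting uses `scipy.optimize.curve_fit` and non-convergence
yields a flagged fit.  Fits run per track, with at most
min(track length − 1, 20) lags.

Fit-quality filters: tracks shorter than 5 frames are
dropped before fitting, and fits with squared residual norm above 1e-5
(µm⁴, MSD in µm²) or RoC above 500 nm are discarded.  The residual
threshold is a bare number whose natural units here are µm⁴; on noisy
per-track MSDs
the squared residual norm typically exceeds 1e-5 by orders of
magnitude, so the parameter-recovery analyses in this package are
reported on converged fits before the residual cut, and the filter
remains available (and configurable) for data on its original scale.

The condition comparison is ΔC(r) = C_ctrl(r) − C_depleted(r) on
empirical RoC CDFs over a shared grid; positive ΔC means the depleted
condition shifted RoC toward larger radii.

## Synthetic-data generators

The generators produce data with the statistical structure the analysis
assumes, with recorded ground truth; they are fixtures, not claims
about the real data-generating process.

The central construction is a per-cell latent activity vector over
ACDs: zero-mean, unit-variance Gaussian with correlation
ρ₀·exp(−d/λ) within a chromosome and a constant trans coupling between
chromosomes, sampled through a Cholesky factor (a diagonal jitter up to
1e-8 is permitted for numerically semi-definite cases; anything worse
is an error).  A "cohesin-depleted" condition is emulated by raising
ρ₀.  RNA counts are negative binomial around baseline·exp(a − ½)
(Gamma–Poisson, dispersion 5 by default — the standard overdispersion
choice for count data, configurable).  ATAC counts are Poisson with the latent damped by
an activity scale of 0.5 — per-domain accessibility fluctuates less
than transcriptional bursting, and the damping keeps cell totals tight
enough that the depth-based cell filter separates the planted 20%
low-depth (10×-reduced) cells from normal ones.

Default study-scale conditions: 400 cells per condition for expression
(the plate-based assay analysed ~400 cells per condition), 1,500–3,000
cells for accessibility (the droplet assay analysed ~3,000), 24 ACDs on
4 chromosomes spaced 6 Mb with a 6-Mb coupling decay length for the
statistical fixtures, 3 genes per ACD.  The multi-chromosome layout and
the short decay length (relative to ACD spacing) are deliberate: gene
pairs within an ACD share one latent, so per-pair ΔC values are coarse
and correlated, and trans-pair sign statistics only average out when
many effectively independent chromosome pairs contribute.

Burst geometry: two spherical territories of radius 1 µm per cell with
centres 4 µm apart (the spacing keeps chance cross-territory captures
strictly outside the 1-µm gate).  `freqs` are cell-level (N_b/N-scale)
bursting frequencies; each territory bursts a gene with probability
F/2, and each listed pair jointly with F_A·F_B·ψ/2 per territory
(feasible iff F_A·F_B·ψ ≤ min(F_A, F_B)).  Jointly drawn bursts place
the partner within 0.8 territory radii of the first site, inside the
gate, so the measured normalized co-bursting frequency recovers ψ:
ψ = 1 is independence (F_co ≈ 1), ψ = 0 makes the pair mutually
exclusive per territory (N_co ≈ 0).  At ψ = 0 the two genes never
co-occupy a territory — a maximally anti-correlated fixture rather
than a merely unco-bursting one.

Readout spots emit one spot per round per true burst with the codebook
pseudocolor, Gaussian pixel jitter, and either independent per-round
dropout or exactly one forced dropout per burst (for
dropout-robustness fixtures).

Point clouds: homogeneous Poisson ("uniform") or a shared-parent
Thomas process (parents uniform, Gaussian offspring with σ = 100 nm by
default, both channels drawing from the same parents), giving
cross-channel clustering at scales up to ~2σ.

Tracks: 2D Brownian increments (per-axis std √(2DΔt)) radially
reflected at the confinement circle, plus Gaussian localization noise.
`loc_error_nm` is the radial (2D rms) uncertainty, so a static emitter
has an MSD floor of 2·loc_error²; the reflected walk's long-time
plateau equals RoC² (two independent uniform points in a disc of radius
R have mean squared separation R²), which is why the confined-model
refit recovers the generator radius.

What the generators do **not** emulate: read-level sequencing noise,
batch structure, cell-cycle covariation, chromatin-polymer physics,
optical PSFs and detection noise beyond Gaussian jitter, and state
switching in tracks.  Passing recovery tests therefore demonstrates
correctness of the statistics under the stated assumptions, not
robustness to every artefact of real data.

## Reproducibility

One global seed expands to per-stage child seeds through
`numpy.random.SeedSequence` keyed on (seed, crc32(stage label)); every
stochastic operation (downsampling repetitions, reference draws,
generators) draws from its own labelled stream, so pipelines are
bit-reproducible for a given configuration.

## Problem sizes

Test-suite and acceptance-script fixtures use the scales above (hundreds
of cells, tens of ACDs, hundreds of tracks, 1,500-point clouds).  These
sizes put Monte-Carlo error comfortably inside the asserted tolerances
(3·SE bands for calibration nulls, 15% for RoC recovery) while keeping
the whole suite fast; all statistics scale to larger inputs without
structural change.

## Known limitations

* The ACD boundary rule (above-mean run around a prominent peak) is one
  reasonable reading of an under-specified procedure; alternative
  extension rules would shift domain edges by single bins.
* ΔC on small gene sets is coarse (multiples of 1/(n₊+n₋)) and its
  per-pair variance is dominated by the shared latent of each ACD;
  summaries should always pool many pairs.
* The residual-norm track filter assumes MSDs on the µm² scale; apply
  it only to data with comparable noise magnitude.
* The pair-correlation reference assumes a homogeneous bounding volume;
  strongly anisotropic or masked volumes should supply an explicit
  bounding box (or expect edge bias at large r).
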