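# Methods

## Scope and data model

The package analyses a hybrid trio — two inbred parents (P1, P2) and their
F1 — from two data layers: whole-genome Hi-C contact matrices at a fixed
bin resolution and replicate FPKM expression tables. Coordinates are
0-based half-open throughout; bins tile each chromosome with dense,
(chrom, start)-ordered ids, and every per-bin track (PC1, compartment
label, DI) lives on that coordinate system. Matrices are held dense in
memory — a crucifer-sized genome at 40 kb is a few thousand bins — and
exchanged on disk as sparse upper-triangle triplet TSV next to a BED4 bin
table. Duplicate triplet pairs, including an (i, j)/(j, i) mirror pair, are
rejected rather than summed: a mirrored duplicate is almost always a sign
the file already contains both triangles, and silently summing would
double those counts.

## Matrix normalization

Balancing is iterative correction (ICE): each iteration divides the matrix
by the outer product of its relative row marginals until the non-masked
row sums agree to a relative tolerance of 1e-5 (at most 200 iterations;
non-convergence returns the best iterate with a flag and a warning). The
exact likelihood-based standardization used by some Hi-C pipelines is not
reproducible from published descriptions; marginal equalization is the
standard, well-characterized stand-in and is a fixed point on any matrix
that is already balanced. Bins with a zero raw marginal are masked and
excluded from every downstream statistic rather than imputed. cis/trans
summaries are computed on raw counts (normalization rescales marginals and
would distort the genome-wide ratio); the diagonal counts once, to cis.

## Compartment calling

Per chromosome, on the balanced cis block: observed/expected with E(d) the
mean contact at diagonal offset d over unmasked bins (an all-zero diagonal
has E = 0, flagged, and contributes O/E = 0); Pearson correlation of O/E
rows; first principal component of the correlation matrix (scikit-learn
PCA, full SVD, deterministic). Bins whose O/E row has zero variance are
masked before correlating. A chromosome is masked entirely when fewer than
10 informative bins remain or when the correlation matrix is degenerate
(top explained variance ≤ 1e-12) — a constant matrix has no compartment
signal to find, and reporting an arbitrary eigenvector would be noise.

Sign orientation uses gene density: genes are assigned to bins by midpoint
(a midpoint exactly on a boundary goes to the lower bin — a documented,
deterministic tie-break), and the PC1 sign is flipped if the positive side
is not the gene-denser side, A compartments being the gene-dense,
transcriptionally active fraction. An exact density tie keeps the PCA's
native sign with a warning. Orientation is idempotent.

Trio states are written parents-first, `P1-to-P2-to-F1`. This order makes
the standard aggregates read naturally: `A-to-B-to-A` and `B-to-A-to-A`
are the two "parents disagree, hybrid resolves to A" states whose sum is
the hybrid's A-gain, while `B-to-B-to-A` / `A-to-A-to-B` are the rare
states where the hybrid opposes both parents. Percentages are reported to
2 decimal places over bins unmasked in all three samples; aggregate
categories are sums of the printed state percentages, re-rounded.

## TAD calling and comparison

The directionality index contrasts each bin's upstream (A) and downstream
(B) contact sums within a window (a multiple of the resolution, at least
one bin): DI = sign(B−A)·((A−E)²/E + (B−E)²/E), E = (A+B)/2, and DI = 0
when A = B or E = 0. Windows truncated by a chromosome end are computed but
flagged, and flagged bins are excluded from boundary correlation.

The boundary caller smooths DI with a 3-bin running mean and places a
boundary at the first bin of a sustained-positive sign run (≥ 3 bins) that
follows a sustained-negative run of the same minimum length; domains are
the intervals between consecutive boundaries, dropped below 5 bins. The
caller is deterministic and invariant to positive rescaling of the matrix
(DI scales linearly, signs are unchanged). This replaces multi-scale
hierarchical domain callers with the classical DI statistic; it produces
flat, non-nested domains and is validated by planted-structure recovery
(all planted 16-bin boundaries at 40 kb recovered within ±1 bin in the
test fixture).

A reference domain is *conserved* iff some domain of the other sample
matches both boundaries within ±1 bin (configurable), else *specific*.
Conserved domains containing at least one scored gene are ranked by the
mean log₂ fold change of their genes for the parent-vs-F1 contrast with F1
as reference (fold change = parent/F1); the top floor(10 % · n) are
*activated*, the bottom the same number *repressed*, the rest *other*.
Ties are broken by genomic order, making the ranking total and
deterministic; domains without genes are NA, and fewer than 10 rankable
domains yields no tails (all *other*, warned). The fraction of member
genes with fold change > 1 is reported alongside for stacked-bar style
summaries. Boundary sharing between two samples is the Pearson r of their
DI tracks over boundary ± 12 bins by default (the pipeline preset uses ± 4
bins, matched to its simulated domain sizes): shared iff r ≥ 0.75;
zero-variance or truncated windows are unclassifiable and flagged. In the
pipeline the probed boundaries come from the first sample of each pair —
F1 for the parent–hybrid pairs — so hybrid-specific boundaries are tested
directly.

## Expression statistics

Active genes have mean FPKM across replicates ≥ 1 (inclusive; the mean, not
any-replicate, is used). A SEG of a sample is active there and in neither
other sample. Correlation uses squared Pearson r on log2(FPKM + 1), at
replicate and sample-mean level. The built-in two-group test is Welch's t
on log2(FPKM + 1) with Benjamini–Hochberg adjustment and
log2fc = log2((mean_a + 1)/(mean_b + 1)); it exists so synthetic data can
be scored end to end and is *not* equivalent to a count-based
negative-binomial DE model — real DE tables should be supplied for real
data. A gene is a DEG iff padj < 0.05 and |log2fc| > 1 (strict
inequality); the adjusted p is used even where a raw-p criterion is
sometimes quoted, since the adjustment is what the multiple-testing
correction is for. Genes with zero variance in both groups get p = 1 when
the means agree.

Trio DEGs (significant against both parents) split into Up (F1 ≥ both
parent means), Down (≤ both) and B2P (strictly between); with equal parent
means B2P is impossible and the gene is classed against the common value.
MPH and HPH are percent deviations of the F1 trait mean from the
mid-parent and better-parent means; parent means must be positive, and
both statistics are invariant under positive rescaling.

## Candidate integration

Candidates are DEGs with structural evidence: membership in a parent→F1
A-to-B / B-to-A compartment-shift bin, or in an activated/repressed
conserved TAD (genes in *other* TADs are excluded). Concordance follows
the activity convention above: B-to-A with up-in-F1, A-to-B with
down-in-F1, activated (parent-high) TAD with down-in-F1, repressed with
up-in-F1. Discordant genes are retained and flagged — both counts are
scientifically informative. Both parent contrasts are processed with
per-contrast provenance; genes carrying both evidence types get source
`both`, and the summary satisfies
|compartment-only| + |TAD-only| + |both| = |candidates|.

## Synthetic trio generator

Expected cis intensity is
base · (1+|i−j|)^(−α) · c_comp(same compartment) · c_tad(same domain),
trans intensity base · w_trans, with Poisson counts (the simplest noise
model that exercises every caller; real Hi-C is over-dispersed, so the
generator understates count noise). Defaults: 2 chromosomes × 200 bins at
100 kb, base 50, α = 1, 20-bin compartment blocks with contrast 2.0,
10–20-bin TADs with contrast 2.5, trans weight 0.02, ~5 % of bins carrying
planted trio compartment shifts. These intensities were calibrated once,
when the fixtures were designed, so that planted structure sits in the
recoverable regime for the callers above; they are study conditions, not
free dials. Genes (2000 of 2 kb) are placed with 2× density in A bins;
expression is 2^N(μ, 1) with μ = 5 (A) or 3 (B) plus per-replicate
N(0, 0.25) noise, so the planted A-vs-B contrast is +2 log₂.

The heterosis preset additionally gives the hybrid a boosted trans
background (0.045 vs 0.02), an extra boundary splitting every other
sufficiently large TAD, planted ±4-log₂ F1 effects on genes whose
compartment label changes (the 3-vs-3 Welch test needs effects of that
size for reliable detection — a weaker planted effect would test the
power of a deliberately simple test, not the integration logic), planted
sample-specific genes (80/75/50 for P1/P2/F1, low baseline boosted in one
sample) and 120 parent-divergent genes (±3 log₂ in opposite directions,
hybrid left at mid-parent, yielding B2P calls). Phenotype means encode
fresh-weight heterosis of MPH ≈ 159 % / HPH ≈ 150 % with 3 % replicate CV.
Truth tables (labels, boundaries, planted effects, SEG lists) are recorded
with every bundle, and a fixed seed yields byte-identical files.

What passing recovery tests shows — and what it does not: the callers
recover block-structured, Poisson-sampled planted signal; real chromatin
has fuzzier compartment boundaries, nested domains, over-dispersed counts
and mapping artifacts, none of which the generator emulates. Recovery
rates here bound what the pipeline can do under clean conditions, not its
field performance.

## Numerical choices and degenerate inputs

- Balancing: tol 1e-5 relative on row sums, 200 iterations, warn + flag on
  non-convergence; masked bins excluded everywhere downstream.
- PCA: full SVD, no PC2 fallback — ambiguous chromosomes are masked, not
  guessed.
- All tie-breaks (gene midpoint on a bin border → lower bin; activity
  ranking ties → genomic order; density tie → native PCA sign) are fixed
  and documented so reruns are bit-reproducible.
- Percentages are rounded to 2 dp at the report layer only; internal
  computation is in full precision.
- Empty inputs are legal where they are meaningful: an empty triplet file
  is a zero matrix, an empty TAD set has count 0 and NaN mean length.

## Known limitations

- The DI caller produces flat domains; nested/hierarchical TADs are out of
  scope, as are loops and insulation-score methods.
- The built-in DE test is underpowered at 3 replicates relative to
  count-model alternatives; its results on real data should not be
  interpreted, only its wiring.
- cis/trans ratios are computed on raw counts by design; pipelines that
  normalize first will report different absolute ratios.
- Sub-compartments and compartment-strength (saddle) analyses are not
  implemented.
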