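# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `xdosage`.

## Dosage model

Expression is modeled per gene as doses × per-allele rate. An autosomal gene
carries two doses in both sexes. An X-linked gene carries two doses in
hermaphrodites, repressed `dcc_repression`-fold by the dosage compensation
complex, and one unrepressed dose in males. A mixed-sex pool with male
fraction `f` has expectation `(1-f)·herm + f·male`. Consequences used as
analytic anchors throughout:

- `dcc_repression = 2` (full compensation): hermaphrodite/mixed = 1,
  log2 ratio 0.
- `dcc_repression = 1` (none), `f = 0.5`: hermaphrodite/mixed = 4/3,
  log2 ratio ≈ 0.415.

`estimate_single_sex_expression` inverts the same mixing identity to infer
a male level from hermaphrodite and pooled measurements; negative inferences
are clamped to zero and flagged. The male fraction is an explicit argument
because real pools can deviate from 50%.

## Synthetic-data generator

`SimulationConfig` defaults describe the study design the package is built
around:

| parameter | default | units | rationale |
|---|---|---|---|
| `n_genes` | 20,000 | genes | genome scale |
| `x_fraction` | 0.13 | — | ≈2,700 X genes of ≈20,000 |
| `baseline_log2_mean` / `sd` | 3.0 / 2.0 | log2 FPKM | wide, realistic FPKM spread (≈0.5–200) |
| `replicate_sd_log2` | 0.25 | log2 units | typical biological replicate scatter for well-correlated replicates |
| `dcc_repression` | 2.0 | fold | wild-type, fully compensated |
| `male_fraction` | 0.5 | — | obligate outcross pool |
| `maternal_fraction` | 0.5 | — | large maternal contribution in early embryos |
| `maternal_decay` | 0.5 | per stage | geometric decay, simplest mechanism for retained transcripts |
| `late_activation_fraction` | 0.3 | — | zygotic genes switching on only at the comma stage |
| `sex_bias_fraction` / `sex_bias_log2` | 0.05 / 1.0 | — / log2 | minority of sex-biased genes, two-fold magnitude |
| `n_replicates` | 3 | — | at least three biological replicates |

Replicate noise is lognormal with the configured SD in log2 units, so the
mean of per-replicate log2 values is an unbiased estimator of the log2 of
the expected level — chromosome medians converge exactly to the analytic
anchors. Maternal transcripts form a pool shared between sexes that decays
geometrically per stage; zygotic transcription switches on at a gene's
activation stage. Silent genes are floored at 1e-3 FPKM (removed by the
expressed-gene filter; the floor only keeps logarithms finite).

The spike-in RNA generator mixes a second species at a fixed mass fraction
(default 1/11, i.e. 10,000 target to 1,000 spike organisms of comparable RNA
content) and sequences every library to a fixed depth, which is precisely
the mechanism that makes a uniform global change invisible to within-library
normalization. The target population is hermaphrodite, so X genes contribute
half the autosomal per-gene mass under full compensation. The ChIP generator
places gene-body enrichment plus an additive X-wide component on expected
coverage, multiplies the mutant ChIP expectation by per-chromosome-group
gains, and applies Poisson sampling last; the input and the spike extract
are unaffected by the gain.

What the generator does **not** emulate: read-level artifacts (GC/length
bias, mapping ambiguity), count overdispersion beyond
lognormal-times-Poisson, correlated genes, cell-lineage structure, and any
quantitative model of maternal decay or activation timing (the stage
parameters are placeholders for property tests, not biology). Passing tests
therefore validates the statistical machinery, not those aspects of real
data.

## Ratio statistics and confidence intervals

Per-gene log2 ratios are differences of mean per-replicate log2 values (not
the log2 of a ratio of means): this makes the CI construction symmetric and
direction-equivariant. The default CI family is the pooled equal-variance
two-sample *t* (df = nA+nB−2). Under the generator's noise model per-gene
variances are equal across conditions, and the pooled interval attains
nominal coverage at three replicates per side (measured 95.2% on a
10,000-gene null), whereas the Welch/Satterthwaite interval is conservative
at such small n (measured ≈96.6%). Welch remains available via
`ci_family="welch"` for variance-heterogeneous data. Genes with fewer than
two replicates on either side get NaN intervals and are *not assessable* —
a third output category, never silently dropped and never called similar.

The equivalence rule maps a maximum relative change `c` to the symmetric
log2 bound ±log2(1+c) (0.30 → ±0.3785); symmetry in log2 makes the call
invariant to which condition is the numerator. Zero-variance genes are fine
(width-0 intervals); exact-zero FPKM reaching the ratio step is an error —
the strictly-greater-than-1-FPKM filter belongs upstream. All FPKM
thresholds are strict inequalities (">1", "<1", ">10"); boundary values fail.

## Rank-sum and enrichment tests

For `min(n, m) ≤ 10` the Wilcoxon rank-sum p-value is exact and tie-aware:
midranks are doubled to integers and the conditional distribution of the
rank sum over all n-subsets is built by dynamic programming (equivalent to
exhaustive enumeration, verified against one in tests). The observed value
is included in the tail; two-sided p is `min(1, 2·min(tails))`. Larger
groups use the normal approximation with tie and continuity corrections.
Per-autosome p-values are reported raw; a Benjamini–Hochberg column is
available but off by default. Enrichment of up/down-regulated genes per
chromosome is the one-sided hypergeometric tail of the 2×2
(on-chromosome × up) table.

## Clustering and newly-expressed genes

Profiles are transformed log2(FPKM+1) then z-scored per row before
clustering — clustering on shape — while the newly/highly-expressed
thresholds (FPKM < 1 earlier, > 10 later) apply to raw stage means —
filtering on level. The clustering contract is Lloyd iterations from
k-means++ starts, best of `n_starts = 10` by total within-cluster SSE, with
the SSE asserted non-increasing at every iteration (empty clusters are
re-seeded at the worst-fit point, which may transiently break monotonicity
and is exempted). Labels are canonicalized by lexicographic center order, so
output is invariant to row order. This is deliberately not a Hartigan–Wong
implementation; agreement with any particular implementation's cluster
boundaries is not claimed, and recovery is validated against simulator
ground truth instead. The rising cluster is the one maximizing the
later-minus-earlier center rise, subject to a minimum rise of 1.0 on the
standardized scale (ties break to the lowest index).

## Mixture model

Standard EM for K-component normal mixtures with unequal variances; a
variance floor (σ ≥ 1e-3) prevents collapse onto single points. Restarts
(10) initialize means at quantile-spread positions with seeded jitter; the
best final log-likelihood wins, and the log-likelihood sequence is asserted
non-decreasing. Model size is chosen by minimum BIC over converged fits
(K = 2 vs 3 by default — "better fit" needs an explicit criterion and BIC is
the conventional one). Interpretation uses a ±0.1 log2 zero band: a
component below the band together with one above it ⇒ distinct
downregulated class; any component inside ⇒ distinct unaffected (escaper)
class; all above ⇒ the whole distribution shifted up (continuous
regulation). Precedence down > unaffected > up; an all-below case is
reported as shifted down.

## Spike-in corrections

RNA: per-sample scaling uses the total read mass of the *target* species as
the library size. A common per-sample scale is required — normalizing each
species by its own total would force spike ratios to 1 and erase the signal
— and the target genome dominates the library, matching what standard
pipelines compute. After per-condition medians across replicates, OLS of
mutant on wild-type log2 values over spike genes above the median of
wild-type spike expression (the cutoff is configurable; "highly expressed"
needs one) yields slope/intercept; the inverse transform is applied to the
mutant so wild type is the fixed reference. On log2 scale a pure
library-size artifact is exactly an intercept, which is the artifact being
removed. The regression estimator carries mild attenuation from noise in
the wild-type covariate (slope slightly below 1 shifts corrected medians by
~0.02 log2 at default noise), which is inherent to the method, not a bug.

ChIP: each library is normalized to its total reads (which cancels in the
ratio-of-ratios, making the factor depth-invariant by construction), then
`factor = [E_target/E_spike]_mut / [E_target/E_spike]_wt` with
`E = ChIP/input`. Per-chromosome factors restrict target masses to one
chromosome but keep genome-wide spike masses — the spike genome has no
X-dosage structure. The companion `standard_chip_factor` computes the same
construction against the target genome itself: any genome-wide change
cancels exactly, so under injected gains of 10× (autosomes) and 6× (X) it
reports ≈1.08 for autosomes and ≈0.65 for X — only the relative X/A change
survives, and the true global increase is fully masked. That masked X value
is analytic (gain_X divided by the mass-weighted genome gain), not noise.

ΔΔCt: `ΔCt = mean Ct(mutant) − mean Ct(wt)` per gene; raw fold `2^−ΔCt`;
ΔΔCt subtracts the mean reference-gene ΔCt (spike-species references),
fold `2^−ΔΔCt`. A gene used as its own sole reference returns fold 1
exactly.

## Coverage processing

Tracks are fixed-bin (default 10 bp for profile work, 200 bp in the ChIP
simulations); bin size 1 reproduces per-base processing exactly.
Normalization divides ChIP and input by their own genome-wide median over
non-mitochondrial bins and subtracts input from ChIP; MtDNA bins are carried
through but never influence the median. Z-standardization uses all bins
outside the supplied peak intervals as background (genome-wide by default;
per-chromosome optional — which one published pipelines use is often
unstated, so both exist). Consensus peaks require ≥1 bp overlap with peaks
in a strict majority of replicate sets (both of two). Metagene windows are
strand-oriented (TSS = annotated start on +, end on −); genes near
chromosome edges contribute their in-bounds positions with position-wise n
accounting rather than being dropped. Intergenic anchors are midpoints of
gaps longer than twice the minimum distance (default 5 kb), so every base of
the gap is far from any gene. The included threshold peak caller exists only
to make the pipeline self-contained on synthetic data; it is not a
MACS replacement.

## Reported recovery conditions

The acceptance computations use: 15,385 genes (≈2,000 on X) × 3 replicates
with no maternal pool for median recovery (the analytic anchors 0.415/0
describe purely zygotic two-sex expression; a maternal pool pulls X ratios
toward zero by design — that masking is itself a modeled phenomenon);
10,000 genes × 3v3 for null coverage; 12,000 genes with a uniform 0.8×
autosomal shift for the spike-RNA masking experiment; 1 Mb-scale
chromosomes at 200 bp bins for the ChIP studies; and n = 10,000 draws from
0.8·N(−0.37, 0.3²) + 0.2·N(+0.69, 0.3²) for mixture recovery.

## Known limitations

- FPKM is taken as given; no within-package conversion from counts, and no
  differential-expression testing (DE flags are inputs).
- The equivalence caller reports no formal TOST p-value and no FDR over
  calls.
- The spike-RNA regression assumes spike material is identical across
  conditions and ambiguous cross-species reads were removed upstream.
- Exact Wilcoxon switches to the normal approximation above group size 10;
  p-values there are approximate (tie/continuity corrected).
- Peak calling, alignment and GO analysis are out of scope by design.
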