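# Methods

`poolscan` re-implements, as a tested pipeline over synthetic data, a
pool-seq transcriptome genome scan for parallel ecotype divergence: the kind
of design where two locally adapted forms ("crab" and "wave" shore snails)
are sampled in several distant locations, RNA from ~40 individuals per pool
is sequenced, and the question is whether the same loci are differentiated
between ecotypes in every location.

## The analysis chain

**Input.** popoolation2-style `sync` allele counts (per sample, per
position: `A:T:C:G:N:del`) plus a design table mapping sync columns to
(country, ecotype ∈ {crab, wave}, replicate ∈ {1, 2}). Upstream read
filtering, mapping and pileup generation are out of scope; the sync file is
the contract.

**Site filtering and subsampling.** Positions with any deletion-supporting
reads are removed. Because RNA-seq depth varies enormously across loci,
every sample is subsampled *with replacement* (a multinomial draw over the
observed base counts) to one even target coverage, default 20. Sites where
any sample has observed coverage below `min_coverage` (default 10) are
dropped entirely, so all pools share a single site set; the floor bounds
the extra resampling noise that with-replacement subsampling adds at
shallow sites. Subsampling is frequency-unbiased by construction, which
the tests verify over a grid of input counts.

**SNP calling.** Allele counts are summed over all 12 samples; the two
top-total nucleotides become major/minor (ties broken A<T<C<G). A site is a
SNP iff the total minor count is ≥ `min_minor_count` (default 24, i.e. 10%
of 12 × 20 subsampled reads — both shared and population-specific SNPs
qualify, and sequencing errors do not). Rare residual third-allele reads in
a sample are removed by redrawing that sample's counts to target coverage
from a binomial over the two retained alleles, keeping the downstream
biallelic model exact.

**FST.** For a pool pair with major-allele frequencies p1, p2 at a SNP,

    hw = (2·p1(1−p1) + 2·p2(1−p2)) / 2,   ht = 2·p̄(1−p̄),  p̄ = (p1+p2)/2.

Both are averaged over a contig's SNPs first and FST = (Ht̄ − Hw̄)/Ht̄ — a
ratio of averages, which is the numerically stable choice and integrates
signal over linked SNPs (contigs here are short transcript fragments,
~660 bp, essentially one exon). Contigs with Ht̄ = 0 for a pair are
excluded for that pair and counted. No pool-size correction is applied:
this is a plain Nei-style estimator on even subsampled counts, so absolute
FST values carry a depth-dependent upward noise bias (identical for every
pair, hence harmless for outlier ranking; documented limitation).
Comparisons: between-ecotype (crab_r vs wave_r, two replicate estimates per
country), within-ecotype (crab1 vs crab2, wave1 vs wave2 — pure-noise
controls), and between-country (mean over the four ecotype/replicate-matched
cross-country pairs, keeping ecotype composition balanced).

**Outliers and sharing.** Within a country, a contig is an outlier at
quantile q iff *both* replicate FST estimates are strictly above their own
empirical q-quantile (linear interpolation); replicate consistency guards
against pool-composition and expression noise. q defaults span 0.94–0.98.
Sharing between two countries is the intersection of their outlier sets on
the common contig universe, compared with the overlap K of two random
subsets: K ~ Hypergeometric(N, n_a, n_b), expectation n_a·n_b/N, and a
discrete central 95% CI [largest k with CDF(k−1) ≤ 0.025, smallest k with
CDF(k) ≥ 0.975]. The CI conditions on the realised set sizes. The
within-ecotype tables provide a negative control (their top tails should
overlap only by chance). Sharing is reported as shared/|focal set| plus the
Jaccard index; the triple intersection is reported per quantile.

**SNP-level parallelism.** For each SNP the crab-minus-wave frequency
difference of one globally fixed reference allele (the grand-total major
allele) is computed per replicate and averaged, per country. For contigs
with >2 SNPs, the two countries' difference vectors are correlated
(Pearson); zero-variance vectors are excluded and counted. Positive r means
the same alleles track the crab ecotype in both countries, negative r the
opposite; with only three SNPs |r| near 1 arises frequently by chance, so
only the distribution of r over shared outlier contigs vs all contigs is
interpreted. Two tests compare those distributions: a bootstrap of the mean
(B = 10,000 samples of the outlier-set size drawn with replacement from the
all-contig r values; two-tailed with continuity correction,
p = (1 + #{|mean_b − mean_all| ≥ |mean_obs − mean_all|})/(B+1)), and a
chi-square over r bins (edges −1, −0.5, 0, 0.5, 1; expected counts from
all-contig proportions; bins with expected < 5 merged into their smaller
adjacent neighbour; df = bins − 1; not computed if fewer than 2 bins
survive).

## The synthetic-data generator

The generator emulates the study design so every stage is testable without
the unavailable raw reads. Per SNP:

1. ancestral frequency π ~ Beta(0.8, 0.8), clamped to [0.02, 0.98];
2. per-country frequency = logistic(logit π + ε), ε jointly normal with SD
   `drift_sd` (default 0.5) and optional correlation `country_corr` for one
   designated country pair (emulating shared post-glacial history; 0 by
   default so nulls stay clean);
3. ecotype frequencies = country frequency ± δ/2 by the contig's label,
   with the pair slid inside the clamp bounds so the full difference δ
   (default 0.3) is always realised. Labels: `shared_selected` (same
   direction everywhere), `country_specific:<c>`, and
   `sign_flipped:<a>-<b>` (opposite directions in one designated pair,
   default SP–UK). Selection is completely linked within a contig: every
   SNP of a selected contig shifts. Selected contigs carry ≥ 3 SNPs so
   SNP-level tests apply to them;
4. each replicate pool draws 2 × 40 allele copies binomially (individuals
   are represented only as allele-count draws; expression noise is
   subsumed into the coverage model);
5. coverage per sample ~ NB(k = 10, mean 50 × e_c), where e_c ~ Gamma(2,
   mean 1) is a per-contig expression multiplier shared by all samples —
   the RNA-seq signature that makes low-expression contigs drop out whole
   at the coverage filter rather than deleting sites independently; reads
   are binomial at the pool frequency with a 0.001 per-read miscall rate
   spread uniformly over the other three nucleotides.

SNP counts per contig are truncated-geometric (mean ≈ 3, range 1–20);
positions are evenly spaced within 660 bp contigs. The truth table (label +
signed per-country δ per contig) is the key for recovery experiments.

What the generator does **not** model: coalescent/migration history (so no
realistic linkage between contigs or gene-flow-induced cross-country
correlation beyond the optional knob), allele-specific expression,
reference bias, mapping artefacts, and any between-contig variance in true
differentiation beyond the binary selected/neutral labels. The last point
matters for interpretation: in the real study replicate FST estimates
correlate at 0.8–0.9 because true per-contig differentiation varies
continuously; here neutral contigs are exchangeable, so replicate
correlations on synthetic data are noise-dominated (~0.3) and passing tests
say nothing about that aspect of real data.

## Standard experiment sizes

Repeated-simulation experiments use, as the package's standard sizes: 1,000
neutral runs at 2,000 contigs for null calibration; 200 runs for
power/recovery (5% shared-selected, δ = 0.3, q = 0.94); 200 runs at 4,000
contigs (5% shared + 5% sign-flipped) for direction recovery. Direction
recovery is evaluated at q = 0.92, the least stringent threshold of the
scanned range: shared sets at q = 0.94 have a median of ~3 contigs per
class, too few for the mean-r bootstrap to resolve, and the larger scan
size serves the same purpose.

## Numerical and procedural choices

- **Quantiles/ties**: empirical quantiles use linear interpolation;
  "outlier" means strictly greater than the threshold (ties at interpolated
  thresholds are practically impossible for continuous FST).
- **Seeds**: one top-level seed spawns independent per-stage generators
  (simulation, subsampling, SNP calling, bootstrap) via `SeedSequence`, so
  any stage can be re-run in isolation; the run manifest records the seed
  and every filter-chain count.
- **Calibration pseudo-outliers**: p-value uniformity under the null is
  checked by drawing a random outlier-sized subset of the all-contig r
  values each run. The subset is capped at 5% of the pool (floor 25):
  because it is drawn without replacement from the same finite pool that
  defines the reference distribution, test statistics deflate by roughly
  (1 − n/N), which is negligible only for small sampling fractions.
- **Degenerate inputs**: empty sync files yield empty streams; empty
  outlier sets make the bootstrap an error and the sharing CI [0, 0];
  correlations with n < 3 or zero variance are reported missing, never 0.

## Known calibration limitations

Two properties of the sharing null are worth knowing when reading results
on synthetic (and, by the same arguments, real) data:

- the discrete hypergeometric CI **over-covers** when outlier sets are
  small (expected overlap < 1): the smallest interval holding ≥ 95% of the
  mass often holds ~99%, so "inside the CI" occurs in ~98–99% of neutral
  runs rather than 95%;
- contigs share structure across FST tables (SNP count, diversity,
  expression level), so the noisiest contigs are enriched in *every*
  table's tail and null overlap runs slightly **above** hypergeometric —
  most visible in the within-ecotype control, which lands inside the CI in
  ~90% of neutral runs. The original study reports the same qualitative
  behaviour for its control ("within or slightly above" expectation).

Likewise, recovery of truth-labelled shared contigs into the shared-outlier
set at δ = 0.3 is intrinsically low (~7%): at 20× coverage the 94% FST
threshold (≈ 0.13–0.17, set by the noise tail of 1-SNP contigs) exceeds the
true contig FST of a 0.3 frequency shift at intermediate frequencies
(≈ 0.09–0.15), so most truly selected contigs cannot rank above it in all
four replicate estimates at once. Detection of *excess* sharing is far
easier than exhaustive recovery: sharing exceeds the chance CI in ~97% of
such runs.
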