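# Methods

This note documents the models, conventions and design choices behind
`mthet`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and the package's known
limitations. All coordinates are 1-based closed intervals on the 16,569-bp
rCRS circle; the analysed fragment runs 15978 → 16569 → 1 → 261 (853 bp),
enumerated explicitly as an arc rather than via modular arithmetic so
region boundaries stay auditable. Regions: HV1 = [15978, 16364] (387 bp),
intermediate = [16365, 72] (277 bp, crossing the origin), HV2 = [73, 261]
(189 bp).

## Heteroplasmy calling

Input is a strand-resolved count table per sample: A/C/G/T counts per
fragment position and strand, assumed post-alignment and post-quality
filtering (read mapping and base recalibration are upstream of this
package). Conventions:

- The major allele is the most frequent base over both strands *in that
  sample*; the minor allele is the second most frequent. Heteroplasmy is
  intra-individual variation, so homoplasmic differences from the rCRS
  reference are not calls. Count ties break alphabetically (A < C < G < T),
  deterministically.
- MAF = minor-allele count / total A+C+G+T depth at the site. Only the four
  canonical bases exist at the count-table level (the fragment is treated
  as SNV-only; indels are out of scope).
- Detection threshold 0.2% (`threshold = 0.002`), inclusive: a site exactly
  at threshold is called.
- Double-strand validation: the *same* minor allele must reach
  `threshold × per_strand_multiplier` independently on each strand
  (multiplier default 1.0). A strand with zero depth fails validation.
  This suppresses strand-specific artefacts, which dominate false positives
  at this depth; the per-strand rule is this package's documented
  formalisation of the double-strand criterion.
- Sample QC: mean combined depth over all 853 positions (uncovered
  positions count as 0) must be ≥ 10,000×; exactly 10,000 passes. QC-failed
  samples carry no calls.

## Replicate concordance

With n ≥ 2 replicate PCR libraries per sample (canonically 3), the
consensus truth set is the positions called in ≥ k replicates (k = 2
default; k = 1 is the union, k = n the intersection). Each replicate is
scored against the consensus over all 853 positions, so
tp + fp + fn + tn = 853 always. Sensitivity and specificity with zero
denominators are *undefined*: they are excluded from means and counted,
never imputed as 0 or 1. Replicate-level values are averaged within sample
first and then across samples (a `pooled` aggregation over all
replicate-level values is available, since the aggregation order is a
convention). Concordance is judged on site identity; MAF agreement across
replicates is a separate diagnostic (`replicate_maf_dispersion`, the mean
pairwise absolute MAF difference).

## Cohort statistics

All group-level statistics operate on the MAF matrix (QC-passing samples ×
853 positions, zeros at uncalled sites, column order = fragment order).

- **Region enrichment.** Per region, the 2×2 table (heteroplasmic /
  non-heteroplasmic positions, inside / outside the region; cells sum
  to 853) is tested with the two-sided Fisher exact test (hypergeometric
  enumeration). The odds ratio is the sample cross-product with a Woolf
  log-normal 95% CI; the Haldane–Anscombe 0.5 correction is applied to all
  cells when any cell is zero. When the heteroplasmic set is empty or
  covers the whole fragment there is no contrast: OR = 1, p = 1, CI
  undefined, flagged degenerate (a literal continuity correction of the
  double-zero table would produce an arbitrary non-unit ratio).
- **Mutation-rate analyses.** Rates are consumed as a user-supplied
  relative-rate table covering every position (their estimation from
  phylogenetic data is out of scope). Occurrence–rate association is plain
  Pearson correlation over the 853 positions, per group. The mean-rate
  comparison contrasts heteroplasmic-site rates against all-site rates per
  stratum (whole fragment and each region) with a two-sided Mann–Whitney
  test; the two sets overlap deliberately, matching the conventional
  presentation of this comparison.
- **Per-site ANOVA.** Classical one-way ANOVA of MAF across groups at each
  position, including zeros for samples without a call — excluding them
  would leave most positions untestable (`het_only=True` provides the
  alternative). Zero-variance positions report F = 0, p = 1. Family-wide
  adjustment across the 853 positions is Bonferroni by default
  (Benjamini–Hochberg behind `adjust="bh"`); pairwise contrasts use Tukey
  HSD at nominal 0.05, computed where the omnibus p is below 0.05.
- **Age correlations.** Pearson r (two-sided t-test p) of each position's
  MAF against age, plus one correlation of per-sample heteroplasmic-site
  count against age. Constant columns are flagged undefined.
- **Clustering.** Complete-linkage agglomeration on Euclidean distances
  between sample MAF vectors; samples are sorted by id first so ties
  resolve deterministically. Output includes Newick serialisation with
  branch lengths derived from merge heights.

## Transmission statistics

- **Total heteroplasmy** is Σ MAF over called sites × 100 (percent); it
  summarises an individual's mutation load on the fragment.
- **Pair correlation** is Pearson r over (mother, offspring) values,
  requiring ≥ 3 pairs and non-degenerate variance.
- **TNCS** (total number of common sites) sums |mother ∩ offspring| site
  sets over pairs.
- **Site distance** for positions heteroplasmic in *both* members:
  100·|m₁−m₂|/max(m₁,m₂) ∈ [0, 100], symmetric, 0 iff equal.
- **Public/private classification**: a position jointly heteroplasmic in at
  least half the pairs (`public_fraction = 0.5`, a documented default — the
  qualitative definition is "shared by most families") is public; shared by
  at least one pair, private; otherwise absent.

### Reshuffling nulls

Each null replicate applies an independent uniform random permutation to
the offspring side and recomputes the statistic (Pearson r of totals, or
TNCS via a precomputed pair-sharing matrix). The identity permutation is
allowed (probability 1/29! — negligible; `exclude_identity` exists). The
empirical p uses the add-one convention
p = (1 + #{replicate ≥ observed}) / (1 + R) for these upper-tail
statistics, so p is never exactly 0; R defaults to 2000. Cross-group nulls
(CENT–ONLL, CO–ONLL) pair the two groups uniformly at random without
replacement per replicate, truncated to the smaller group size (28); they
have no observed pairing, so only the null mean and sd are reported.

A note on the exhaustive permutation mean: for any fixed vectors, the mean
of Pearson r over *all* n! permutations is exactly 0 — permutation leaves
both marginal means and variances unchanged, and the centered permuted
values sum to zero, so the numerator averages to zero identically. (The
constant −1/(n−1) sometimes quoted in this context is the correlation of
two draws without replacement from a finite population, a different
quantity.) The test suite verifies the Monte-Carlo null mean against this
brute-force enumeration. Degenerate replicates cannot arise for the
built-in statistics (permutation preserves variance), but non-finite
replicate values would be resampled and counted, per the error contract.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
full truth bookkeeping (planted MAFs, shared-site counts, totals). Defaults
describe a cohort of 29 mother–offspring pairs plus 28 unrelated controls
at ~50,000× combined coverage.

Generative model, per cohort:

1. **Rate table.** Gamma-distributed relative rates (shape 0.4) with
   region-level means 4.7 (HV1), 1.6 (intermediate), 6.2 (HV2) — the
   hypervariable regions are faster. Designated hotspot positions (the
   public sites 146, 204, 16129) are set above the largest drawn rate:
   recurrent public positions are modelled as the fragment's
   fastest-mutating sites, which also makes occurrence counts track the
   rate table (r ≈ 0.5–0.8 at defaults).
2. **Mothers and controls** carry each public site with probability
   `public_prob` (default 1.0: public positions recur in essentially every
   individual) with MAF from a truncated exponential (scale 0.02, minimum
   0.01 — recurrent sites sit well above threshold), plus
   Poisson(`de_novo_rate` = 2.0) de novo sites placed proportionally to the
   rate table with MAF from Exp(0.004) truncated to [0.002, 0.5]. This
   yields ≈ 5 sites and ≈ 10% total heteroplasmy per individual, ≈ 120
   distinct heteroplasmic positions per cohort, and the characteristic
   occurrence/level shape in which frequent sites are low-level and
   high-MAF sites are rare.
3. **Offspring** inherit each maternal site with probability `retention`
   (0.8), multiplying the MAF by a mean-one lognormal jitter
   (`maf_jitter_sd` = 0.3 on the log scale) — a phenomenological stand-in
   for germline-bottleneck drift, whose size is deliberately not modelled.
   They then draw their own public sites (if not inherited) and their own
   de novo sites. At these defaults the planted mother–offspring
   total-heteroplasmy correlation has median ≈ 0.73 across seeds with ≈ 95%
   of seeds in [0.5, 0.95], and the expected TNCS is ≈ 130. The free
   parameters (`de_novo_rate`, `public_prob`, the public-site MAF law) were
   fixed once by a pre-build Monte-Carlo calibration against those cohort
   descriptors and are not tuned per run.
4. **Counts.** Per site and strand: depth ~ Poisson(mean_depth/2)
   (gamma-mixed negative binomial when `overdispersion` > 0); minor reads
   ~ Binomial(depth, MAF); error reads ~ Binomial(remaining, 5×10⁻⁴ per
   strand), split uniformly over the three non-major bases.
   Strand-asymmetric error (`error_rate_minus`) exists specifically to
   exercise double-strand validation. The reference sequence is synthetic
   (a deterministic position-derived base; the minor allele is its
   transition partner) — calling is reference-free, so this affects only
   cosmetic realism.
5. **Replicates** are independent count realisations from the same truth;
   optional per-replicate lognormal MAF perturbation models PCR drift
   (default off).

Everything is a pure function of (config, seed); the pipeline derives
independent child seeds per stage from one master seed, so full-study runs
are byte-deterministic.

What the generator does *not* emulate: read-level artefacts (PCR chimeras,
alignment error, index hopping), nuclear mtDNA insertions (numts), clonal
haematopoiesis structure in blood, linkage between sites on single
molecules, and any explicit germline-bottleneck population dynamics.
Passing recovery tests on this cohort therefore demonstrates that the
statistical machinery is correct at realistic depths and error rates, not
that the caller is robust to every artefact class in real libraries.

## Numerical conventions and degenerate inputs

- Ratios with zero denominators are undefined and flagged, never imputed.
- Zero-depth sites are skipped with a log message; a zero-depth strand
  fails double-strand validation.
- MAF is written with 6 decimal places; statistics tables use 6 significant
  digits; distances 4 decimals.
- Empirical p-values use the add-one convention (minimum 1/(R+1)).
- Exit codes: 0 success, 2 schema error (with the offending line number),
  3 empty post-QC cohort, 4 statistical degeneracy.

## Problem sizes

Default analyses run the full 86-sample cohort, 853 positions, 2000
reshuffles. Simulation-based checks in the test suite use 50–200 cohort
seeds for transmission recovery and 100 single-sample seeds for calling
recovery; these sizes give stable pass/fail behaviour for the assertions
made while keeping the default suite quick to run.

## Known limitations

- The double-strand rule is a per-strand threshold criterion; other
  formalisations (e.g. strand-bias exact tests) are not implemented.
- The MAF denominator counts A/C/G/T reads only; if upstream filters pass
  other symbols they must be removed before import.
- ANOVA on mostly-zero MAF columns is conservative and approximate; the
  Bonferroni default is deliberately strict, and the calibration guarantee
  (type-I ≈ 5% nominal) is established on Gaussian nulls.
- `public_fraction = 0.5` is a convention, not an estimate; sensitivity of
  the public/private split to this choice is the user's to explore.
- No plotting: outputs are plain tables (and Newick for the dendrogram)
  intended for downstream tools.
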