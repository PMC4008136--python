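# Methods

## The statistical model

The pipeline treats a CpG island (CGI) as the unit of analysis. Each
island's methylation level in one sample is the unweighted mean over
its qualifying CpGs (read coverage ≥ 10) of the per-CpG fraction
methylated reads / coverage. Mean-of-fractions (rather than the pooled
read fraction) is deliberate: the pooled, read-weighted view is exactly
what the complementary count-based test (HBA) contributes, so the two
calls carry partly independent information and their intersection is
stricter than either alone.

### Entropy statistic (QDMR)

Given levels *m₁ … m_N* for a region, the statistic stack is Shannon
entropy H₀ of the normalized levels, a one-step Tukey biweight robust
mean T_br, the entropy H_P of the normalized distances |m_s − T_br|,
the log-range weight w_r = |log₂((max − min)/(MAX − MIN) + ϵ)| with
MAX = 1 and MIN = 0, and the adjusted entropy H_Q = H_P · w_r. H_Q is
zero when exactly one sample deviates from the robust mean and grows
without bound as the levels become uniform; a region is differential
when H_Q is *small*.

Numerical conventions:

- 0 · log₂ 0 ≡ 0 everywhere; an all-zero level vector is treated as
  uniform (H₀ = log₂ N).
- ϵ = 10⁻⁴ (configurable). It only regularizes the log at zero range.
- One-step biweight: center = median, scale = the raw median absolute
  deviation, u = (m − median)/(c·MAD + 10⁻⁴) with c = 5, weights
  (1 − u²)² for |u| < 1 and 0 otherwise. At least half the samples
  always receive positive weight, so the weighted mean is defined. For
  N = 2 the construction is symmetric and reduces to the arithmetic
  mean of the pair.
- Exactly uniform regions (all levels equal) get H_Q = +∞ as an
  explicit sentinel: they are maximally non-differential and must never
  fall below any finite threshold. This case has positive probability
  for two replicas with boundary clipping.

### Threshold calibration

The cutoff on H_Q is the empirical low-tail percentile (default 5%) of
H_Q over simulated uniformly methylated regions: a true level
μ ~ Uniform(0,1) observed in each of N samples as
clip(Normal(μ, SD), 0, 1). SD = 0.03 is the assumed intrinsic
biological variation for two-replica comparisons; SD = 0.015 — the
most conservative setting offered for this statistic — is used for the
cross-cell-line (ICDM) call. The default null size is 10⁵ regions.
Note the direction of the SD effect: a larger assumed SD shifts the
null H_Q distribution *down*, lowering the cutoff and calling fewer
regions; calls at SD = 0.015 are therefore a superset of calls at any
larger SD (verified empirically in the tests).

For N = 2 the whole statistic collapses: H_P = 1 whenever the levels
differ, so H_Q = |log₂(|m₁ − m₂| + ϵ)|, strictly decreasing in the
absolute difference. Thresholding H_Q is then identical to calling
|m₁ − m₂| > δ with δ = 2^(−threshold) − ϵ (≈ 0.082 at SD = 0.03), i.e.
a semi-difference of ≈ 0.041. The tests verify exact call-set equality
of the two rules.

### Read-count test (HBA)

Per island and replica, methylated and unmethylated read counts of all
qualifying CpGs are summed; the 2×2 table (replica × methylation
state) is tested with the two-sided Fisher exact test under the
point-probability convention (sum of all tables at the observed
margins whose probability does not exceed the observed one — the
dominant software convention, and the one an exact rational-arithmetic
enumeration oracle reproduces to 10⁻¹² in the tests). Benjamini–
Hochberg FDR at 0.05 is applied across the tested islands of one cell
line; each cell-line comparison is treated as its own experiment, so
FDR is not pooled genome-wide across cell lines.

### Sharing across cell lines

The IRDM set of a cell line is the intersection of the entropy and
count calls. The overlap degree of an island is the number of cell
lines calling it; "common" means degree ≥ 2, and "most common" is the
top 5% of the autosomal common-degree distribution, realized as the
smallest integer degree d with tail mass ≤ 5% (with heavy ties no such
d may exist and the tier is empty). The chance expectation is obtained
by 100 Monte Carlo relabelings that reassign each cell line's call
count uniformly at random (without replacement) over the islands
having data in *every* cell line; the shared-vs-singleton 2×2 Fisher
table compares observed degree-1 vs degree-≥2 counts against the
counts *summed* over all simulations (summing rather than averaging
keeps the table integral and stabilizes it).

### Characterization

- Chromosome distribution: 10⁴ bootstrap draws of |call set| islands
  without replacement from the universe (implemented as a multivariate
  hypergeometric draw of per-chromosome counts, which is the same
  distribution). Empirical p = (1 + #{sims ≥ observed})/(n_boot + 1),
  never exactly zero.
- Gene regions: each island is classified by its midpoint into 5′
  (3 kb upstream of the translational start through the first intron),
  intragenic (internal exons/introns), 3′ (final intron/exon), or
  intergenic (≥ 3 kb from every gene). Midpoint classification
  guarantees exactly one class per island. When overlapping genes
  disagree, precedence is 5′ > 3′ > intragenic (the promoter call is
  the biologically privileged one). The strip within 3 kb of a gene
  that matches no other rule (e.g. just downstream) is assigned to 3′.
  Class counts are compared with Pearson's chi-square against the
  proportions of all islands.
- Structural features (G+C fraction, length, observed/expected CpG
  ratio) are compared between called and uncalled islands with Welch's
  two-sided t-test; per-group counts across cell-type categories with
  Welch's one-way analysis of means (p reported as 1 when every
  observation is identical and the statistic is undefined).
- ICDM: the per-cell-line level is the mean of the two replica levels,
  restricted to the islands present in all cell lines; the entropy
  machinery runs unchanged across the N cell lines at SD = 0.015, and
  enrichment of each IRDM tier in the ICDM set is a 2×2 Fisher test.

### Gene association and expression

Regulatory domains follow the basal+extension rule: basal = TSS − 5 kb
to TSS + 1 kb (strand-aware); extension up to 1 Mb per side, truncated
at the nearest neighboring basal domain and at chromosome ends, never
below the gene's own basal domain. Curated regulatory domains (hosted
annotation data) are not modeled. A region associates with every gene
whose extended domain it intersects; a gene reachable from both
differential and non-differential regions is assigned to the
differential side so the two gene groups stay disjoint. Term
enrichment runs the binomial test over regions (hit probability = the
genomic fraction covered by the term's domains, here the fraction of
the simulated genome) and the hypergeometric test over genes, BH
corrects each family, and requires both q ≤ 0.05. The expression
analysis scores each gene with DR = |expr1 − expr2|/(expr1 + expr2)
(genes with zero total expression are excluded and counted), splits
both gene groups at the merged median, and applies the two-sided
Fisher test to the resulting 2×2 table.

## The synthetic data generator

The generator emulates RRBS-style inputs, not sequencing itself (no
reads, no alignment, no bisulfite-conversion error):

- Island geometry: CpG count ~ max(3, Poisson(15)) per island, CpG
  spacing 20–60 bp, inter-island gaps 2–20 kb; G+C ~ Normal(0.70,
  0.05), observed/expected CpG ratio ~ Normal(0.84, 0.08). These give
  realistic CGI tracks (mean length ≈ 600 bp) without modeling
  sequence.
- True island level μ from a bimodal Beta mixture (half Beta(1,19),
  mean ≈ 0.05; half Beta(18,2), mean ≈ 0.9) — the strongly bimodal
  marginal real CGIs show.
- Observation model: each CpG of each replica observes level =
  clip(μ + Normal(0, SD), 0, 1) with SD = 0.03 by default, coverage ~
  negative binomial (mean 30, dispersion 5; RRBS depth is
  overdispersed), methylated reads ~ Binomial(coverage, level). The
  Normal perturbation is drawn *per CpG*, mirroring the island-level
  null simulation in aggregate while keeping replica island means
  concentrated; the Normal+clip law itself is a modeling choice, not
  an inference from data.
- Planting: 10% of islands per cell line are truly differential, with
  replica levels separated by exactly Δ = 0.4 (hot replica random). A
  shared pool (sampled first, with chromosome weights defaulting to
  8× on chrX) supplies 80% of each line's planted quota; the rest is
  line-private. Susceptible islands carry a −0.02 G+C shift by
  default. These defaults are the study conditions every end-to-end
  test runs under.
- Gene models: 1–6 exons, exon lengths 100–500 bp, introns 0.2–2 kb,
  random strand, translational start inside the strand-first exon;
  non-overlapping per chromosome. Expression: log-normal around a
  per-gene baseline with replica noise SD 0.2, inflated by ×1.5 for
  genes whose regulatory domain touches a planted island.

What passing tests on these data do **not** show: robustness to
per-CpG dependence along an island, coverage biases correlated with
G+C, partially methylated domains, strand asymmetries, or cell-line-
specific baseline methylation — none of which the generator produces.
Calibration results (the 5% null call rate; Fisher's conservatism)
transfer to real data insofar as the noise there is no heavier-tailed
than the assumed Normal.

## Known limitations and open choices

- The exact TSV dialects stand in for the browser-track extracts real
  studies parse; coordinates are 0-based half-open throughout, and
  CpGs are assumed strand-collapsed.
- No minimum CpG count per island is imposed beyond ≥ 1 qualifying CpG
  in every sample.
- The Fisher table of the sharing test uses simulation-summed counts;
  averaging would be the main alternative and gives near-identical
  conclusions at n_sim = 100.
- The dual-route term enrichment uses the simulated genome length as
  the analyzable genome; on real data this should be the mappable,
  assayable fraction.
- Problem sizes used by the default tests and the calibration script
  (10⁵ null regions, 10⁴ islands, 10⁴ bootstrap draws, 100 overlap
  simulations, 5 cell lines × 2000 islands) were chosen as the
  smallest sizes at which Monte Carlo error is negligible relative to
  the tested effects.
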