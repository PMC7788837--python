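# Methods

## Model and test procedure

The null hypothesis is mutual independence of all markers in a diploid
panel: no non-random association among any subset of loci, a strictly
stronger property than pairwise linkage equilibrium. Two summary statistics
compress the panel into one-dimensional distributions with exactly
computable nulls.

**Number of heterozygous loci (K).** For individual *i*, K is the count of
loci carrying two distinct allele labels. Under independence, K is a sum of
independent Bernoulli(h_m) indicators — Poisson-binomial — and its pmf over
0..m is built by the forward recurrence

    P(K=r | m) = P(K=r | m−1)·(1−h_m) + P(K=r−1 | m−1)·h_m,   P(K=0 | 0) = 1.

The per-locus heterozygosity h_m is either the HWE expectation 1 − Σ p_i²
from the estimated allele frequencies (default, matching the analysis
pipeline this package follows) or the observed column mean of the
heterozygosity indicator matrix.

**Number of shared alleles (X).** For a pair of individuals, each locus
contributes the size of the multiset intersection of the two allele pairs
(identity by state: {A,B} vs {B,B} share 1). Under independence X follows
the trinomial convolution

    P(X=r | m) = P(r | m−1)·p0_m + P(r−1 | m−1)·p1_m + P(r−2 | m−1)·p2_m

over support 0..2m. The per-locus probabilities (p0, p1, p2) are either the
Weir unrelated-pair probabilities — both genotypes drawn independently from
HWE, enumerated over all unordered genotype pairs — or the observed sharing
proportions; the default is the Weir expectation. Pairs are formed once per
dataset, without replacement: a random permutation cut into ⌊n/2⌋ disjoint
pairs, so every pair is a row shared across markers. Exhaustive all-pairs
and with-replacement pairings are available but are not used by the test.

**Goodness of fit against a simulated null.** Observed counts (individuals
for K, pairs for X) are compared to n·pmf with Pearson's X² after binning.
The binning contract: contiguous bins built greedily from both tails inward
toward the mode until every bin's expected count is at least 5; residual
deficient bins merge toward the mode; the identical partition is applied to
the observed counts and every null replicate. Because the trial
probabilities are locus-specific, the χ²_{bins−1} asymptote is not relied
on; instead B replicate count vectors are simulated from the expected
distribution, each yielding one X² value. The critical value at level α is
the empirical quantile of that set chosen so that "observed > critical"
coincides with "p < α" on the simulated support (for α below 1/B it is the
set's maximum), and the p-value is the ECDF exceedance 1 − F̂(X²_obs); an
add-one variant (1 + #{null ≥ obs})/(B+1) is available by flag.

Null replicates are generated as one multinomial(n, pmf) draw per
replicate. This is distributionally identical to simulating n individuals
locus-by-locus (i.i.d. draws from a pmf produce multinomially distributed
category counts) and two orders of magnitude faster; the tests verify the
replicate moments against the Poisson-binomial/trinomial identities.

**Hardy–Weinberg testing.** Per marker, observed unordered-genotype counts
against HWE probabilities over the union support; Monte-Carlo p-value from
B multinomial tables with the add-one estimator (default), or the
asymptotic tail with df = categories − 1. The df convention treats the
expected probabilities as fixed; the Monte-Carlo branch, which the main
pipeline uses, is unaffected by that choice.

## Missing-data policy

A cell that cannot be parsed into two allele labels is missing. A missing
cell at marker j excludes that individual from marker j's allele, genotype
and heterozygosity counts, and excludes any pair containing it from marker
j's sharing counts. The distributions of K and X use complete cases only
(individuals/pairs observed at every marker), keeping the support fixed at
0..m and 0..2m; the number of exclusions is reported on the distribution
object.

## Synthetic panels

The generator emulates the study conditions of the power design grid, not
any particular evolutionary history.

- **Unlinked loci**: genotypes drawn i.i.d. from HWE at each locus; loci
  mutually independent. SNPs draw a minor-allele frequency from
  U(0.1, 0.5) (matching the MAF ≥ 0.1 filter typical of pruned panels);
  STRs draw 5–10 alleles with flat-Dirichlet frequencies re-sampled until
  heterozygosity ≥ 0.5, reflecting the high polymorphism of forensic
  microsatellites.
- **Linked block**: one latent haplotype-class variable with
  `n_hap_classes = 6` Dirichlet(1) class frequencies; each individual draws
  two class indices i.i.d.; every locus in the block maps classes to
  alleles through a fixed random map (SNP: balanced 2-partition of the
  classes; STR: surjection onto min(k, 6) of its alleles — a surjection
  onto more alleles than classes is impossible). All block loci are
  deterministic functions of the same latent pair, giving strong LD, while
  the i.i.d. class pair keeps every single locus in exact HWE.
- **Design grid**: panels have an even size x, half SNPs and half STRs;
  linkage levels Unlinked, OnePair (2 linked), HalfQuarter (0.125x),
  Quarter, Half, ThreeQuarter, Almost (x−2) and Fully, each biased toward
  SNPs, STRs, or split evenly ("Both"; undefined for OnePair/Almost, and
  the only option for Unlinked/Fully). Below half linkage the biased type
  carries all linked markers; above it the bias type is saturated first.
- **Power study defaults**: n = 500 individuals per trial, 1000 trials,
  B = 500, α = 0.05, one linked block per panel.

What the generator does *not* emulate: coalescent genealogy, mutation
models, recombination gradients, population structure, genotyping error or
missingness. Its linked blocks are far stronger than LD produced by finite
recombination distance. Consequently, calibration results (type-I error
under independence + HWE) transfer to real data directly, and power at
*full* linkage is a ceiling check; power at *intermediate* linkage levels
is meaningful only ordinally (more linkage ⇒ more power), not as a numeric
forecast for any specific genomic panel.

## Operating points and numerical choices

- Discrete pmfs are exact forward convolutions (O(m²) for K, O(m·2m) for
  X); no normal or saddlepoint approximation at any m.
- The worked-example panel bundled in code (`synthetic_reference_panel`)
  is a synthetic stand-in shaped like an LD-pruned mixed reference panel:
  2504 individuals, 94 SNPs + 6 STRs, independent HWE loci. Being simulated
  under the null, it can show the nominal 5% rejection rate across
  re-pairings — exactly the test's type-I error, not evidence of
  dependence. In the bundled analysis the pairing is drawn once (it is part
  of the analysis) and the null simulation is reseeded.
- The ordinal linkage-trend check runs at panel size 32 with n = 60
  individuals per trial. With the near-deterministic linked block, n = 500
  drives every level from Quarter upward to power 1.0 and the dose-response
  ordering is unobservable; n = 60 keeps the X statistic's power inside its
  dynamic range across all five levels. At such small n the test runs on
  ~30 pairs and a handful of bins and is mildly anti-conservative (observed
  unlinked rejection ≈ 0.1); the calibration claims of the package are made
  at the study scale (n = 500), where measured type-I error is 0.04–0.05.
- Acceptance-scale simulation sizes: type-I calibration uses 1000 trials at
  B = 500 in the acceptance script and a 300-trial, B = 200 configuration
  in the test suite; full-linkage power uses 200 trials. Tolerances on rate
  estimates are 3 binomial standard errors.
- Ties and degenerate inputs: a degenerate expected distribution (point
  mass) or a support that cannot hold two bins of expected count ≥ 5
  raises an error rather than returning a vacuous test; markers with all
  cells missing raise naming the marker; odd-n pairing silently drops one
  random individual.
- Determinism: every stochastic routine accepts a seed (or a numpy
  Generator); identical seeds give bit-identical results end to end,
  including the power study's per-design/per-trial seed-sequence tree.

## Known limitations

- The test conditions on estimated per-locus parameters (frequencies,
  heterozygosities, sharing probabilities) as if fixed; the slight
  conservatism this induces is visible as type-I error marginally below
  nominal at large panel sizes.
- K and X are panel-level summaries: a rejection says the panel is not
  mutually independent but does not localize which markers drive it.
- Pairing without replacement uses each individual once, so the X test
  runs on ⌊n/2⌋ effective observations; for small samples the K statistic
  is the more powerful choice.
- XLSX is read but not written; phase in VCF GT fields is discarded by
  design.
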