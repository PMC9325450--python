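# Methods

## Setting

The package implements the population-genomic analysis chain used in
domestication resequencing studies: a panel of diploid accessions grouped
into subpopulations (wild and cultivated), genotyped at biallelic SNPs,
is scanned for genomic regions where domestication purged diversity in a
cultivated group while differentiating it from the wild group. The two
signals are combined: windows simultaneously in the top 5% of pairwise
F_ST and of log₂(π_wild/π_cultivated) are called sweep candidates.

## Estimators

**Per-site π.** For a site with `ref` and `alt` called allele copies
(n = ref + alt ≥ 2), π = 2·ref·alt / (n(n−1)) — the unbiased mean
pairwise difference among called alleles. Sites with n < 2 are skipped
(they carry no information, not zero diversity). Window π divides the sum
of site values by the full window length in bp, which puts subgroup
diversity on the per-bp scale (order 10⁻³ for typical resequencing
panels). An accessible-sites denominator was considered and rejected as
default: with a SNP-only VCF the full-length denominator is the
convention that produces comparable per-bp magnitudes across windows.

**Hudson F_ST.** Per site, N = (p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1) and
D = p₁q₂ + p₂q₁ with sample frequencies p and called allele counts n;
windows accumulate the ratio of averages ΣN/ΣD, which is robust to rare
variants and unbiased for small samples. For two populations drifted from
a shared ancestral pool with parameter F (Balding–Nichols), E[N] = 2F·p̄q̄
and E[D] = 2p̄q̄ per site, so ΣN/ΣD estimates F — this is the closed-form
target the recovery tests use. Negative window values are retained (not
clamped): clamping would distort the empirical percentiles that the sweep
rule consumes. Sites with n < 2 in either group are excluded from the
pair's sums; windows with ΣD = 0 or no usable sites are NaN and excluded
from ranking, never silently zeroed. The estimator choice is recorded in
the run manifest; a Weir–Cockerham alternative was deliberately left out
of scope to keep one well-tested path (the manifest makes the choice
auditable).

**Heterozygosity.** Per accession, the fraction of called genotypes that
are heterozygous; subgroup values are means over members. Accessions with
zero called genotypes get NaN and are flagged.

## Sweep calling

Percentiles use mid-rank ties: pct(v) = 100·(#less + 0.5·#equal)/n over
rankable (non-NaN) windows, which is permutation-invariant and stable. A
window is selected iff both percentiles are ≥ 100(1−q), q = 0.05 by
default; with continuous statistics the selected fraction is ≤ q by
construction, and under independent statistics the expected joint rate is
q². The threshold is inclusive, so heavy ties can push the set slightly
past q·n; ties are visible in the percentile columns.

π-ratio zero-denominator policy: π_cult = 0 with π_wild > 0 maps to +∞,
which ranks above every finite value — total diversity loss is the
strongest sweep evidence. Both-zero windows are undefined and unranked. A
pseudocount mode (ε = half the smallest nonzero window π added to both)
is available for users who prefer finite statistics.

Selected windows merge into regions when they overlap or are book-ended
(gap 0 by default; configurable). Region statistics are maxima over
member windows. Genes overlap a region when their 1-based closed spans
share ≥ 1 bp (adjacency is not overlap); totals deduplicate genes hit by
several regions.

## Windows

Window size and step are free parameters declared in every output header
and in the run manifest. The library default is 100 kb windows sliding by
10 kb (step = size/10), a common geometry for ~10× resequencing panels.
The 2 Mb synthetic benchmark uses 4 kb windows tiled end-to-end
(step = size) so that its ten 12 kb planted sweeps each span exactly
three grid-aligned windows: with 500 windows the 30 sweep-interior
windows roughly fill the top-5% budget (25 windows), which is the regime
in which a joint top-percentile rule can flag every sweep while honoring
its ≤ 5% selection bound. (With sweeps covering a much larger fraction of
windows than the budget, the rule provably cannot mark them all — a
property of the method, not a defect of the implementation.)

## QC semantics

A site passes iff depth ≥ 4 AND RMS MQ ≥ 20 AND MAF ≥ 0.05 AND
missingness ≤ 0.1, all inclusive. Depth and MQ are site-level covariates
(the thresholds describe per-site summaries carried in INFO); MAF is
computed over all called alleles of the combined panel; missingness is
the fraction of uncalled genotypes at the site. The filter is idempotent.
SNP region classification applies the precedence exonic > intronic >
flank (strand-aware upstream/downstream, default flank 0) > intergenic.
Subgroup SNP "presence" means ≥ 1 called genotype carrying ≥ 1 alt
allele; a polymorphic-within-group mode is available.

## Structure

p-distance between two diploids is mean(|dosage_i − dosage_j|)/2 over
sites called in both (allele-sharing distance; pairwise deletion). It is
not guaranteed metric under heavy missingness; triangle-inequality
violations can be counted (`check_triangle_inequality`) but are never
repaired. A genotype-mismatch variant was considered; allele-sharing was
chosen because it weights het/hom differences half as much, matching
dosage geometry. NJ is the classic Saitou–Nei agglomeration with the
deterministic tie-break "lowest index pair on equal Q"; on additive
matrices it recovers the generating tree exactly (Atteson), which the
tests verify by path-length equality at 1e-9. Negative branch lengths
(possible on non-additive input) are clamped to zero only at
serialization. PCA mean-imputes missing dosages per site, drops sites
monomorphic among called genotypes, applies Patterson normalization
(center 2p̂, scale √(2p̂(1−p̂))) and takes the SVD; component signs are
fixed by making each component's first nonzero loading positive.

## Synthetic cohorts

The simulator draws an ancestral frequency per site (uniform on
[0.05, 0.95] by default, or a 1/x neutral-like spectrum truncated to
[0.01, 0.99]) and per-population frequencies from the Balding–Nichols
Beta distribution with drift F (F = 0 reproduces the ancestral frequency
exactly; Var = F·p(1−p)). Sweeps move the target population's frequency
toward fixation inside an interval: p' = p(1−s) + round(p)·s with
round(0.5) = 1 (deterministic tie toward the alt allele), so s = 1 fixes
every site. Genotypes are Binomial(2, p) dosages (Hardy–Weinberg within
population), masked missing independently per genotype. Site depth is
negative-binomial with mean 11 (matching ~11× panel coverage) and
dispersion 5; RMS MQ is Normal(45, 5) truncated at 0; the missing rate is
0.02. These defaults were chosen once as realistic resequencing
covariates under which most sites pass the QC filter.

The standard benchmark is one 2 Mb chromosome with 20 000 SNPs, wild (WL)
and cultivated (SL) populations of 21 diploids each at F = 0.05, and ten
12 kb sweeps at s = 0.95 in SL.

What the simulator does **not** model: linkage disequilibrium,
recombination maps, demographic history, per-genotype depth, genotyping
error correlated with depth. Passing tests therefore demonstrate
estimator and pipeline correctness under exchangeable-site conditions,
not robustness to LD-induced window autocorrelation or to call-set
artifacts in real data.

## Determinism and numerics

All randomness flows from one integer seed through per-stage
`numpy.random.Generator` streams; identical configs give byte-identical
outputs, which the manifest's SHA-256 checksums make checkable. Window
accumulations are cumulative-sum based and agree with per-site loops to
1e-9 relative (exact summation order is not guaranteed). Floats in TSVs
are written with 10 significant digits.

## Limitations

- Region counts from real studies depend on unreported window/merge
  geometry and are not comparable across choices; the manifest records
  the geometry for exactly this reason.
- The +∞ ratio sentinel makes the ranking well-defined but means the
  log-ratio column is not finite-valued; downstream consumers should use
  the percentile columns.
- p-distance pairs with zero co-called sites abort the structure stage;
  panels with extreme missingness need upstream filtering.
- The VCF reader loads the full dosage matrix into memory
  (int8 ≈ samples × sites bytes), adequate for panels up to a few hundred
  samples × a few million sites.
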