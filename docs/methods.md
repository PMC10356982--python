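# Methods

This note documents the models and procedures implemented in `rohmap`,
the choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## ROH detection

The caller reproduces the PLINK `--homozyg` window logic. For each animal
and chromosome, a window of `window_snp` markers (default 50) slides one
marker at a time; a window is *homozygous* when it contains at most
`window_het` heterozygous (default 1) and at most `window_missing` missing
(default 1) calls. Only complete windows are formed: a chromosome with
fewer markers than one window yields no calls, and markers near chromosome
ends are covered by fewer windows. Each SNP receives the proportion of
homozygous windows among the complete windows covering it; SNPs with
proportion ≥ `hit_threshold` (default 0.05) are run-eligible. Maximal
eligible stretches are split wherever two adjacent markers lie more than
`max_gap_kb` (default 500) apart, then trimmed so both ends sit on
homozygous, non-missing markers — a run must begin and end on direct
evidence of homozygosity. Surviving runs are kept when they span at least
`min_snp` markers (default 100), at least `min_length_kb` (default 1,000),
and are no sparser than `max_density_kb_per_snp` (default 50). Segment
length is `end − start + 1` bp with 1-based inclusive coordinates. There
is no per-segment heterozygote cap beyond the window rule (the tool
default leaves it unset; `n_het` is still reported per segment), and no
MAF or LD pruning anywhere.

Two deliberate consequences of the window semantics are worth knowing:

* **Edge overshoot.** A window containing 49 tract markers and one
  background marker is always flagged (the background marker can
  contribute at most one heterozygote), so markers slightly outside a true
  autozygous tract inherit nonzero hit proportions. On isolated planted
  tracts at 10 kb spacing the detected endpoints overshoot the planted
  ones by a median of ~2 markers (95th percentile ~8). Tests therefore
  score endpoint recovery with a slack of a few markers rather than
  exactly one.
* **Threshold non-monotonicity.** Raising `hit_threshold` shrinks the set
  of run-eligible markers (that set is monotone and is tested as such),
  but pruning can split one long stretch into two pieces that both pass
  the final filters, so the *count* of emitted segments is not monotone in
  the threshold. The count is monotone in `min_snp` and `min_length_kb`,
  which are pure filters.

`detect_roh_oracle` re-implements the identical contract with explicit
loops and no incremental bookkeeping; the two callers are compared segment
for segment on randomized instances, and the oracle is the arbiter of any
semantic question the description above leaves open.

## Homozygosity characterization

F_ROH is total ROH length divided by the SNP-covered autosomal span (first
to last marker, summed over chromosomes) unless assembly chromosome
lengths are supplied — ROH cannot be observed outside marker coverage, so
the covered span is the defensible default denominator. Per-chromosome
homozygosity uses the chromosome length (supplied, or the last marker
position) as denominator and averages over animals.

Pedigree inbreeding is Wright's F computed by the tabular
additive-relationship method in topological order
(`a(i,j) = ½(a(s_i,j) + a(d_i,j))`, `a(i,i) = 1 + ½ a(s_i,d_i)`, unknown
parents contribute zero); the implementation is checked against exhaustive
common-ancestor path counting on small pedigrees. The correlation between
genomic and pedigree inbreeding is Pearson's r on (F_ROH, F_PED) pairs by
default; because the choice of the genomic variable is not canonical, raw
total ROH kb is available as an alternative (`use="total_kb"`).

The SCR association is an unweighted ordinary least-squares regression of
SCR on total ROH length in Mb (or on segment count): the phenotype is
already a population-scale deviation, and breeding counts are kept only as
record-selection metadata, not as regression weights.

## Extreme-group enrichment

The population is split into the n lowest- and n highest-SCR animals
(default n = 100); boundary ties go to the record with more breedings,
then to the lexicographically smaller id, and the low group is assigned
first so the groups are always disjoint.

Overlap regions are built as a **constant-carrier-set partition**: on each
chromosome the line is cut at every segment start and end+1, each
elementary interval carries exactly the set of animals whose ROH fully
cover it, adjacent intervals with identical carrier sets are merged, and
regions carried by fewer than `pool_min` (default 2) animals are dropped.
This deliberately replaces PLINK's `--homozyg-group` pooling: the
partition is deterministic, unambiguous and testable, and carrier status
(full coverage) is guaranteed by construction. The price is that region
counts and lengths are not comparable with the pooling heuristic — the
partition produces more, shorter regions with exact carrier sets.

Each region's 2×2 table (low/high × carrier/non-carrier) is tested with a
one-tailed Fisher exact test for carrier over-representation in the
low-fertility row, i.e. the hypergeometric upper tail P(X ≥ a) with
margins fixed, evaluated through the log-space hypergeometric survival
function and verified against exact-rational full-table enumeration to
1e−12. Significance defaults to p ≤ 0.001 (inclusive); no multiple-testing
correction is applied by default, matching the extreme-group screening
design in which the mixed model, not the Fisher p-value, is the
confirmatory step. Gene annotation is a local interval intersection
against a BED (0-based half-open, converted on read) or GFF3 (1-based
inclusive) file; a gene is reported on ≥1 bp overlap.

## Mixed-model validation

Candidate regions are validated one at a time on all phenotyped genotyped
animals with the animal model y = Xb + u + e, u ~ N(0, G σ²_g),
e ~ N(0, I σ²_e), where X holds an intercept and the region-carrier
indicator (an animal is a carrier when one of its ROH fully covers the
region). No further covariates are added: SCR is already pre-adjusted for
service-sire age and AI company upstream. G is the VanRaden method-1 GRM
(codes centered by 2p̂_j, missing imputed to the mean, denominator
2Σp̂_j(1−p̂_j), monomorphic markers excluded); the construction method is a
package choice since none is canonical here.

REML profiles the variance ratio γ = σ²_g/σ²_e: G + 0.01·I is
eigendecomposed once, the model is rotated to the eigenbasis where the
covariance is diagonal, σ²_e is profiled analytically, and the restricted
log-likelihood is maximized over γ on a 65-point log grid (10⁻⁴…10⁴, plus
the γ = 0 boundary) refined by golden-section search on log γ. Fixed-effect
standard errors come from the inverse weighted normal equations times
σ̂²_e, which equals the fixed-effect block of the inverse mixed-model-
equation coefficient matrix. `var_ratio=0` forces σ²_g = 0 and reduces the
fit to ordinary least squares exactly. A region whose indicator is
constant is reported as untestable rather than raising. The validation
rule is |t| ≥ 2 (overridable).

Under a pure-noise phenotype the REML heritability estimate behaves as
boundary theory predicts: roughly half the replicates land exactly at
σ²_g = 0 and the rest form a positive tail whose spread reflects how
little variance-ratio information one GRM realization carries (eigenvalue
spread ≈ 0.26 for the reference study). Point estimates of h² from a
single replicate are therefore noisy even though the estimator is
calibrated in the mean (h² = 0.4 is recovered within ±0.1 averaged over 50
replicates at n = 800).

## Synthetic studies

The generator emulates the *shape* of a dense-chip bull-fertility study,
not its population genetics. Defaults define the package's reference
study, chosen so the full pipeline runs in well under a minute on one CPU:

* **Scale:** 800 bulls × 5 chromosomes × 4,000 markers at ~25 kb mean
  exponential spacing (~100 Mb per chromosome). Two inter-marker gaps per
  chromosome are drawn uniformly from 100–800 kb so that the gap-splitting
  rule is exercised on both sides of the 500 kb ceiling.
* **Pedigree:** 4 generations of 800, each generation sired by a pool of
  25 males (paternal half-sib structure, as in AI cattle breeding); with
  probability 0.15 a dam is mated to her own sire. The resulting final
  generation — the study cohort — spans F_PED ≈ 0 to ≈ 0.3.
* **Genotypes:** HWE background with allele frequencies uniform on
  0.05–0.5; per animal, Poisson(2 × (1 + 4·F_PED)) tracts per chromosome
  with gamma(2, 4 Mb) lengths are planted by forcing homozygous codes,
  with heterozygous genotyping errors at 0.001 inside tracts and missing
  calls at 0.002 everywhere. This yields ~16% of the covered genome in
  ROH and a realized F_ROH–F_PED correlation of ~0.65 (the multiplier 4
  was calibrated once to that target). Tract lengths straddle the segment
  filters, so some planted tracts are deliberately undetectable.
* **Fertility:** SCR_i = μ + β·(true total ROH Mb)_i + Σ_r effect_r·carrier_ri
  + u_i + e_i with β = −0.01 %/Mb, one planted 3 Mb risk region
  (chromosome 2, 40–43 Mb, −4 SCR% penalty, 12% carriers whose planted
  tract covers the whole region), u ~ N(0, G σ²_g) with polygenic
  heritability 0.3 of the residual variance and σ_e = 2 SCR%. Breeding
  counts are uniform on 50–8,110 and carry no signal.
* **Determinism:** every stage draws from a seed sequence derived from
  `config.seed`; a bundle regenerates byte-for-byte. Marker columns are
  canonicalized (first non-missing genotype never homozygous-alternate) so
  the PED round trip reproduces codes exactly.

What the generator does **not** model: linkage disequilibrium, coalescent
haplotype structure, allele-frequency spectra shaped by selection,
chromosome-specific homozygosity hotspots, and genotyping artifacts beyond
uniform error/missingness. Passing tests therefore demonstrate that the
pipeline recovers *planted* signal under its own stated noise model — they
say nothing about calling accuracy in the presence of real LD (where
short IBS-not-IBD runs are the main confounder), and region counts on real
data will differ substantially from the partition counts here.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive bp throughout; BED input is converted on
read. Genotypes are biallelic by contract; a third allele in a PED file is
a hard error. Multiple SCR records per animal are collapsed at read time
(most breedings, then larger SCR). Chromosomes shorter than one window,
animals with zero segments, regions with no carriers, and constant
indicators all take defined non-exceptional paths. The Fisher tail is
clipped to [0, 1]; the regression p-value uses the t distribution with
n − 2 df; the GRM ridge (0.01) bounds the smallest eigenvalue away from
zero before factorization. Problem sizes in the test suite (study scale,
replicate and seed counts) are the package's reference study conditions
stated above.
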