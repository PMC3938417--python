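# Methods

## Data model

An **alignment** is a fixed-length matrix over `{A, C, G, T, -, N, ?}` with
one population label per sample. `N` and `?` are missing data; `-` is kept
as a fifth character state for haplotype identity but never counted as a
pairwise difference, so all difference-based statistics are statistics of
substitutions. Published partial sequences (e.g. 278 bp of a 664 bp D-loop
alignment) are padded with `?` at a user-declared offset; nothing in the
package guesses the anchoring of a partial record, because coordinates of
previously published fragments are metadata, not inferable from sequence.

**Haplotype collapsing** partitions full-length sequences by exact identity
and then assigns each partial sequence, in input order, to the existing
haplotype with minimal Hamming distance over its observed sites (a new
haplotype is created when the minimum is positive). The distance rule
leaves ties unspecified, so the package resolves them deterministically —
highest current count, then earliest creation — and reports how many tie
decisions were taken. Sites are 0-based internally and 1-based in error
messages.

The packaged cyt-b (C1–C39 × 20 populations, 161 samples) and D-loop
(D1–D25 × 18 populations, 239 samples) occurrence tables carry country
rows, continent rows (the sums of their countries), an inbred-strains row
and a grand total; all row and column sums are enforced by tests.

### Private haplotypes

A haplotype is *private* to a population when no other population **at the
same grouping level** (country vs. country, continent vs. continent)
carries it; the inbred-strains column never participates in comparisons
among wild populations. Under this rule every printed private-haplotype
count reproduces except one: the Asian cyt-b sample shares only C2 and C3
with other wild continents, giving 30 private haplotypes where the source
table prints 28. The discrepancy is documented rather than matched, since
no comparison set we could construct yields 28 while preserving the other
rows.

## Diversity statistics

* Haplotype diversity uses Nei's unbiased estimator
  H = n/(n−1)·(1 − Σ pᵢ²), identical to the probability that two samples
  drawn without replacement differ; a property test checks the identity by
  exhaustive pair enumeration.
* Nucleotide diversity π averages per-pair differences divided by the
  per-pair comparable length (*pairwise deletion*, default), because data
  sets pooling partial published sequences have heterogeneous coverage;
  complete deletion is available by flag.
* F_ST is computed on haplotype frequencies, (H_T − H_S)/H_T with unbiased
  gene diversities and sample-size-weighted H_S, with a permutation test
  over individuals. Distance-based Φ_ST (Arlequin-style) is deliberately
  out of scope, so published Φ-type values are context, not oracles.

## Neutrality tests and their nulls

Tajima's D follows the 1989 variance constants; Fu's Fs computes
S′ = P(K ≥ k_obs) under the Ewens sampling formula with unsigned Stirling
numbers of the first kind built exactly in integer arithmetic and combined
in log space (log-sum-exp), then Fs = ln(S′/(1−S′)); R₂ uses the folded
singleton definition (a site where exactly one sequence differs from all
others), which needs no outgroup.

Null distributions come from a hand-coded Kingman coalescent with
**fixed-S conditioning**: a genealogy is drawn, then exactly S mutations
are placed uniformly on total branch length. This matches the convention
of DnaSP, the tool whose outputs the statistics mirror. D is two-tailed;
Fs and R₂ are one-tailed on the low side, where their expansion signal
lies. Time is scaled so a pair of lineages has expected TMRCA 1; the
engine is cross-checked in tests against msprime under identical
conditioning and against closed-form expectations (pair TMRCA, total
branch length).

## Mismatch distributions and the sudden-expansion model

The expected mismatch under a jump from θ₀ to θ₁ at mutational time τ is

F_j = F̂_j(θ₁) + e^(−τ/θ₁) Σ_m Pois(m; τ) [F̂_{j−m}(θ₀) − F̂_{j−m}(θ₁)],

with F̂_j(θ) = θ^j/(θ+1)^{j+1}. The Poisson form keeps the evaluation
stable for large τ. Classes beyond the largest observed difference are
aggregated into an explicit tail bucket before comparison, so SSD is
always computed between vectors of equal length. Raggedness uses classes
0..d with one appended zero class.

Parameters are fitted by bounded nonlinear least squares on the class
frequencies from five fixed starting points (bounds τ ∈ [0, 200],
θ₀ ∈ [0, 500], θ₁ ∈ [10⁻⁶, 10⁵]); the SSD objective makes the fit the
exact minimiser of the statistic later tested. Goodness-of-fit p-values
are parametric bootstraps: samples of the observed size are simulated
under the fitted history (stepwise-size coalescent, Poisson mutations at
θ₁/2 per unit branch), refitted, and compared on SSD (raggedness is
compared without refitting, as it does not depend on the fit). A
simulation-recovery test requires the median fitted τ over 20 data sets at
n = 50 to fall within 50% of the generating value.

## Forward simulation of rodent control

Scenarios share a founding population of 25 mtDNA haplotypes — one focal
haplotype at frequency i₀, the rest sharing 1 − i₀ equally (realised by
largest-remainder rounding) — evolving for 500 generations (250 years at 2
generations/year, colonisation ~1750, control introduced at generation 400
~1950). No mutation is simulated: on this timescale drift and selection
dominate and the founding spectrum is the object of interest.

* **Transmitting copy number.** A census of Ne diploids contains ≈ Ne/2
  females, so the mtDNA pool resampled each generation holds Ne/2 copies
  (`mt_copy_rule="half"`, default; `"full"` is a sensitivity switch). The
  drift law was validated against the diffusion variance
  p(1−p)(1−e^{−t/N}).
* **Scenario L**: Ne constant at 10,000.
* **Scenario M**: crash to Nei ∈ {100, 500, 3000, 7000} at generation 400,
  held to the end (control stays effective).
* **Scenario R**: control holds the census at Nei while resistance evolves
  (generations 400–420, the observed ~10 years between introduction and
  first resistance reports); once resistance is established the census
  recovers to Ne0 by constant (linear) growth over the following 20
  generations (`recovery_gens`, configurable; exponential growth
  available). Reading the bottleneck as persisting until resistance has
  evolved is the only interpretation under which a freely recombining
  autosomal locus can reproduce the reported threshold behaviour: with an
  instant recovery the haplotype–allele association halves every
  generation and the selective boost to the focal haplotype is bounded
  near 2×.
* **Resistance genetics.** One autosomal locus, genotypes SS/RS/RR with
  symmetric overdominance w = (0.7, 1, 0.7) (balancing coefficient
  s = 0.3, the classic heterozygote advantage of warfarin resistance;
  asymmetric weights configurable). At the crash the R allele enters at
  frequency p_R0 = 0.05 with `assoc0 = 1`: all R copies sit in
  focal-haplotype heterozygotes, reflecting resistance arising on the
  lineage of one haplotype. Both knobs are exposed because neither is
  observable from the data.
* **State representation.** Aggregated counts over haplotype ×  genotype
  classes with multinomial resampling — the same stochastic law as an
  agent-based model at this resolution, vectorised across replicates.
  Selection is viability selection on mothers; the paternal allele is an
  independent draw from the post-selection allele pool. Because the whole
  state lives in the female pool of size Ne/2, the autosomal locus drifts
  like a population of Ne/2 rather than Ne diploids; at the bottleneck
  (where it matters) selection at s = 0.3 dominates that factor-two
  difference in drift, and mtDNA drift — the quantity under study — is
  exact under the copy rule.
* **Threshold sweep.** P(final ≥ 0.72) is estimated per grid point of i₀
  (step 0.01, 1,000 replicates), monotonicity in i₀ is enforced by PAVA
  isotonic regression, and the 5% crossing is linearly interpolated. A
  cheap coarse sweep brackets the crossing first so the fine grid is only
  evaluated where it matters; the window extends automatically if the
  crossing falls at its edge. Every grid point draws from its own
  deterministic substream of the master seed, so results are reproducible
  and independent of the bracketing path.

## Synthetic data

The generator emulates the *structure* of the real data — haplotype
frequency spectra, a requested number of segregating sites placed on a
coalescent or star genealogy, terminal truncation of a fraction of
records — not its substitution process: sites are infinite-sites unique,
ancestral bases uniform, and no rate heterogeneity, indels or sequencing
error are modelled. Tests passing on synthetic data therefore validate
the statistical machinery, not robustness to alignment artefacts. Since a
coalescent draw need not distinguish all requested haplotypes, placement
is redrawn (bounded retries) until all reference sequences differ; this
requires S ≥ number of haplotypes − 1.

## Numerical choices and problem sizes

* Stirling rows are cached per n; Ewens probabilities are renormalised by
  log-sum-exp to absorb float error (normalisation asserted to 1e−9).
* Empirical p-values use ≥/≤ comparisons with a 1e−12 slack so exact ties
  count as extreme.
* Fst of two populations fixed for the same haplotype is defined as 0 with
  p = 1; estimates are clipped to [0, 1].
* Degenerate statistics (S = 0, single haplotype, n < 2) return None
  throughout and print as "-" in summaries.
* Default problem sizes — 1,000 replicates per grid point, 1,000-replicate
  coalescent nulls, 2,000-replicate calibration checks, 5,000-replicate
  variance checks — keep the full test suite and the acceptance script in
  the minutes range on one CPU while holding Monte-Carlo error well inside
  the tolerances asserted.

## Known limitations

* No recombination, structure or migration in the coalescent; only the
  sudden (demographic) expansion model is fitted, not spatial expansion.
* Printed neutrality-test values for the original sequence data (e.g. the
  German D-loop D = −1.83) require the deposited GenBank sequences and the
  original sample partitions; they are reproducible by users who supply
  those alignments but are not asserted anywhere — property-based checks
  (brute-force agreement, type-I error calibration, directional power)
  stand in for them.
* The scenario-R threshold is sensitive to the unobservable p_R0 and
  assoc0; its defaults are stated above and the acceptance tolerance for
  that quantity is the loosest.
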