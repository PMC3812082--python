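# Methods

## The Luria–Delbrück model and its two estimators

Mutant counts per culture are modelled by the Lea–Coulson form of the
Luria–Delbrück distribution: mutation events per culture are Poisson(m),
and each event founds a clone whose size follows the law
P(size = j) = 1/(j(j+1)), the limit of clonal expansion at the culture's
own growth rate.  The pmf is evaluated by the Ma–Sandri–Sarkar recursion
(p₀ = e^(−m); p_r = (m/r)·Σ_{i<r} p_i/(r−i+1)) with no renormalisation —
the raw recursion values are the likelihood factors, and the missing
partial-sum mass is exactly the truncated tail.  For likelihood
evaluation the pmf is computed to the largest observed count plus a
20-entry tail guard.

**MSS maximum likelihood.**  m̂ maximises the count log-likelihood over
a 61-point log-spaced grid on [10⁻³, 10³], refined by bounded scalar
optimisation inside the winning bracket (ties resolved toward smaller
m by taking the first grid maximiser).  The rate is m̂ / median(N_t).
The 95% CI uses the Stewart large-sample standard error of ln m̂,
σ = 1.225·m̂^(−0.315)/√C, as a normal interval on the log scale,
back-transformed and divided by the median cell count.  Simulation at
the assay scale used throughout (C = 15 cultures, m = 2) gives 95–96%
empirical coverage over 500 replicates, within the nominal band.
When every culture has zero mutants no point estimate exists; the
reported value is the upper bound at which all-zero data retain 5%
probability, m = ln 20 / C, flagged `is_upper_bound`.

**Drake median.**  Per culture, the implicit equation μ·ln(N_t·μ) = f
(f = r/N_t) is solved by Brent root-finding on the monotone branch
μ > 1/N_t, with the upper bracket doubled until it straddles the root
(for r < e the root exceeds f, so the bracket cannot simply be (0, f]).
The assay summary is the median of per-culture rates with the exact
binomial order-statistic CI: ranks (k, n−k+1), k the largest rank with
P(X ≤ k−1) ≤ 0.025 for X ~ Binomial(n, ½).  Fewer than six cultures
admit no two-sided 95% interval; the CI is then reported unavailable.
The choice *per-culture rates, then median* (rather than one Drake
solve on the median frequency) matches the reporting convention of
median rates with order-statistic CIs; the pooled variant is available
behind the `pooled=True` flag.  The Drake formula is deliberately
rough: in the m ≈ 30–100 regime its absolute rates run some tens of
percent above the generative truth, with a similar factor across
genotypes, so relative rates are recovered much more accurately than
absolute ones (the package's recovery tests use a factor-two band for
absolute rates).

**Plating fractions.**  Cultures partially plated on selective medium
have their counts rescaled to whole-culture equivalents
(r → r/fraction) before estimation; the finer FALCOR-style plating-
efficiency correction to the likelihood itself is not implemented.
The synthetic samplers apply the complementary operation — binomial
thinning — when a plating fraction below one is configured.

**Zero medians.**  An assay whose median mutant count is zero only
bounds the rate; it is reported as the rate implied by a single mutant
colony at the median cell count, flagged as a "<" upper bound, matching
the convention of printed "<0.6"-style table entries.

## Relative rates and the printing convention

Relative rates are computed on unrounded estimates and rounded half
away from zero to two significant figures.  Published tables print one
further convention on top of this, inferred from the printed values:
relatives at or above one appear as whole numbers (1.74 → 2,
25.26 → 25, 233.3 → 230) and sub-unity values at one significant
figure (0.579 → 0.6).  `printed_relative` implements that rendering and
the reconciliation stage reproduces 82 of 99 comparable table cells
exactly.  The 17 remaining cells (frozen in
`data/rounding_exceptions.tsv` with their computed values) cannot be
recovered from the printed absolute rates under any fixed rounding rule
— e.g. one cell computes to exactly 850 while 840 is printed — which
indicates they were derived from unrounded rates that were never
published.  They are reported as documented mismatches, not failures,
and excluding them the reconciliation is exact.

## Interaction classification

With S and P the sum and product of single-mutant relatives, the rule
set is, in order: combined > S ⇒ synergistic, refined to multiplicative
when |ln(R_ab/P)| ≤ ln 1.5; else additive when |ln(R_ab/S)| ≤ ln 1.5;
else suppressive when R_ab < min(Rᵢ)/1.5; else epistatic when
R_ab ≤ max(Rᵢ)·1.5; anything between those bands is labelled
additive-to-synergistic.  Two orderings here are deliberate design
choices: the multiplicative test is gated on exceeding the sum (for
weak singles the product can fall below the sum, where matching the
product is not evidence of synergy), and suppression is tested before
epistasis (otherwise the epistasis band, which extends down to zero,
would absorb it).  No numeric tolerance for "equal to the sum/product"
is standard in the field; ×1.5 on the log scale is configurable and
every call carries the raw S and P so users can re-threshold.
Rank-based two-sample comparisons use the Mann–Whitney U test: exact by
enumeration when the pooled size is ≤ 20 without ties, otherwise the
tie- and continuity-corrected normal approximation (at balanced n = 10
the two agree within 0.01 in p).

## Mutation calling and spectrum classes

Mutant ORF sequences are aligned to the reference globally with
gap-affine scoring (match 0, mismatch −1, gap open −2.5, extend −0.01).
Affine gaps matter: under unit-cost edit distance a kilobase deletion
has many cost-equivalent representations that interleave mismatches and
short gaps, whereas the affine scores make the single contiguous gap
strictly optimal while leaving clustered substitutions aligned
base-per-base.  Indels are left-normalised within homopolymer runs
(leftmost placement, the standard variant-normalisation convention) and
touching same-type indels are merged; substitutions are kept as
single-base events so that clustered changes classify as complex
mutations rather than multi-base substitutions.  A difference budget —
substituted bases, plus inserted bases, plus one per deletion gap —
above 50 marks a pair as mispaired input; deletions count once so that
legitimate whole-gene-scale losses stay callable.

Classes: events within 10 bp of each other merge transitively; clusters
of ≥2 events are complex; lone substitutions and 1-bp indels keep their
elementary classes; a lone deletion of 11–10,000 bp is a medium-size
deletion (the observed range in hyperacetylated strains is 40–1,036 bp);
anything else — e.g. a lone 2-bp insertion — is "other".  Isolates whose
reporter fails PCR while the unlinked control amplifies are GCR
deletions; control-amplicon failure invalidates the DNA.  Class rates
are isolate fractions times the genotype's total rate and sum to it
exactly; invalid-DNA isolates are excluded from the denominator.

Reversion of the his7-2 frameshift requires a net +1 frame change
inside its 51-bp window with frame-neutral events elsewhere; the window
start is a parameter because the package works in reporter-local
coordinates rather than chromosomal ones.

**Junction repeats.**  For a deletion of length L at 0-based start d, a
flanking direct repeat is a pair of windows [i, i+k) and [i+L, i+L+k)
with i ∈ [d−k, d], so one copy overlaps or abuts each breakpoint and
exactly one copy plus the spacer was removed.  The maximal-length hit
with ≤1 Hamming mismatch is reported (ties: fewer mismatches, then
5′-most); hits shorter than 4 bp are discarded and k is capped at L.
"Nearly perfect" has no standard quantitative definition; ≤1 mismatch
with no internal indels is this package's choice, and both thresholds
are parameters.  The scanner is validated against an exhaustive search
over all lengths and placements.

## The synthetic-data generator

The generator emulates the study conditions of yeast reporter-gene
fluctuation assays: 15 cultures per assay (the typical number; at least
9), grown from a 100-cell inoculum to 2×10⁸ cells, rates spanning
10⁻⁹–10⁻⁵ per cell per generation, and a default mutation spectrum
patterned on a strongly mutating, GCR-prone (H3 K56 hyperacetylated)
strain: 40% whole-reporter losses, 33% base substitutions, 16% 1-bp
indels biased into homopolymer runs, and ~5.5% each complex mutations
and medium-size deletions.  The default reporter length, 1,771 bp,
matches the *CAN1* ORF.  Strong mutators are best simulated with
smaller cultures or partial plating, as in real assays, so colony
counts stay countable.

Two independent count samplers exist by design.  The exact sampler
inverts the CDF of the MSS pmf; because the Luria–Delbrück tail decays
only like m/r, evaluating the recursion until the tail is negligible is
not feasible (the 10⁻¹² point lies near r ≈ m·10¹²), so the pmf is
computed to a cap (default 4,096) and the residual tail mass — about
m/4096 — is lumped into the top bin.  The cap is configurable; it is
also not wholly artificial, since physical clone sizes are bounded by
the culture size.  The growth-process oracle never touches the
recursion: it draws Binomial(divisions, μ) mutation events per culture,
places each uniformly among the N_t − N₀ divisions, and expands the
clone deterministically to ⌊N_t/n⌋ cells.  The uniform-in-divisions
placement reproduces the 1/(j(j+1)) clone-size law, so the two routes
agree distributionally (chi-square p ≫ 0.01 on binned counts at 10⁴
draws) while sharing no code.  A strictly synchronous binary-fission
model was considered and rejected for the oracle: its generation-
quantised clone sizes (powers of two) give a measurably different pmf
(e.g. P(r = 2) = e^(−m)(m/4 + m²/8) versus the Lea–Coulson
e^(−m)(m/6 + m²/8)), which no amount of growth makes converge.

Mutant sequences carry exactly one classified mutation, planted in
left-normalised form so the calling round trip is exact; truth tables
accompany every FASTA.  Medium deletions are carved between direct-
repeat copies planted at registered loci in 80% of cases (configurable)
so junction-repeat detection has positives and negatives.  GCR isolates
are emitted as PCR-table rows without sequences, mirroring the
experimental workflow in which such DNA yields no reporter amplicon.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: phenotypic lag, post-plating
mutation, differential mutant fitness, cell death, variation of N_t
between cultures, sequencing errors in mutant ORFs, and multiple
mutations per isolate.  These are the standard idealisations of the
Lea–Coulson model and of finished Sanger-sequenced ORFs.

## Problem sizes and numerical choices

Validation workloads are sized to be decisive yet quick: maximum-
likelihood recovery uses 5,000 cultures per m ∈ {0.5, 2, 8} (observed
error ≤ ~3%), CI coverage uses 500 replicate assays, sampler
concordance 10⁴ draws per route, the spectrum round trip 1,000
isolates, and the junction-repeat oracle 100 references of ≤ 300 bp.
Drake roots are verified against 200-step bisection (agreement to
10⁻¹² relative); the pmf is verified against a scalar transcription of
the recursion (agreement to 10⁻¹²).  All stochastic components consume
explicit integer seeds, and identical configuration plus seed yields
byte-identical outputs.

## Known limitations

* The MSS likelihood treats counts at the sampler cap as exact counts;
  for very large m (≳ a few hundred) the cap truncates the body of the
  distribution and median-based estimation should be used with smaller
  cultures or partial plating instead.
* The Stewart CI is a large-sample approximation; with few cultures and
  very small m it can under-cover.
* The Drake estimator's absolute-rate bias is not corrected; the
  package reports what the formula yields, as published analyses do.
* Mutation calling assumes finished, high-quality ORF sequences over
  {A,C,G,T}; ambiguity codes are rejected rather than interpreted.
* Published-table reconciliation can only be as exact as the printed
  values allow; cells derived from unpublished unrounded rates are
  documented, not reproduced.
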