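# Methods

This note documents the models, numerical choices and known
limitations of the package, in the order the pipeline runs them.

## Coordinates and junction identity

A back-splice junction (BSJ) is identified by `chrom:start:end`,
1-based and inclusive at both ends: `start` is the leftmost base inside
the circle (acceptor side), `end` the rightmost (donor side). BED-style
caller dialects (0-based, half-open) are converted on read; nothing
else is. Junctions are matched exactly — no ±1 coordinate slop — on the
grounds that harmonization has already removed the systematic
convention offsets between dialects, and residual off-by-one
disagreements between callers are a property of the callers, not of
the coordinates. Strand is carried through but ignored for identity:
callers disagree on strand far more often than on position, and the
pseudo-reference quantification is strand-symmetric anyway.

## Consensus filtering

Two-stage: (1) per caller, keep junctions that caller reported with
≥ `min_bsj_reads` (default 2) supporting reads in at least one sample;
(2) keep junctions retained by ≥ `consensus_k` callers (default 3, the
strictest setting). Stage 1 is applied per caller *before* counting
support, so one caller's deep coverage never rescues another caller's
marginal call. The read-support filter is interpreted per
sample-and-method (a junction needs ≥ 2 reads in *some single sample*
for that method), not pooled across the cohort; with typical
per-sample counts the two readings rarely differ, but the per-sample
reading is the stricter and simpler one.

## Pseudo-reference quantification

For a circle `[start, end]` of length L, the pseudo reference is
`genome[end − a + 1 .. end] ++ genome[start .. start + a − 1]` with arm
length `a = min(149, L)`. The junction sits between positions `a` and
`a + 1`. For L ≥ 149 this gives the canonical 298-nt sequence; shorter
circles get truncated arms with no wrap-around (rolling-circle
modelling is out of scope), which means a read longer than a short
circle's arm can never be counted — a documented divergence risk for
very short circles.

Read placement is a deterministic seed-and-extend contract rather than
a reproduction of any particular quasi-mapping engine: exact 21-mer
seeds at disjoint read offsets, ungapped full-length (end-to-end, no
clipping) comparison, at most 2 mismatches, both strands. Three
disjoint 21-mer seeds fit in a 75-nt read, so by pigeonhole every
alignment with ≤ 2 substitutions is guaranteed to be found; the
guarantee degrades for reads shorter than `(max_mismatches + 1) · k`.
Restricting to end-to-end placements makes the contract exactly
checkable against brute force and costs nothing scientifically: a
clipped placement could never satisfy the junction-overhang rule that
drives counting. Indels are not modelled (extension is ungapped), which
the simulator matches by emitting substitution errors only.

Counting applies two rules:

- **Linear filter.** A fragment is discarded iff both mates map
  end-to-end to the *same* linear transcript on opposite strands with
  ≤ 2 mismatches each. Junction-spanning reads cannot do this (the
  junction context exists in no linear transcript), so true BSJ
  evidence always survives.
- **Overhang rule.** A surviving fragment is counted for a circRNA iff
  at least one mate's pseudo-reference alignment covers the junction
  with `min(left, right) ≥ 7` bases. A fragment counts at most once,
  even when both mates span the junction. A fragment eligible for
  several circRNAs (shared arms) is assigned to the one with the
  fewest total mismatches across its aligned mates, ties broken
  lexicographically by key — the multi-mapping policy is a determinism
  choice, flagged as such rather than a claim about any upstream
  tool's behaviour.

## Phenotype preparation

Fixed order, logged per run: population filter → z-score → inverse
normal transform → hidden factors. The population filter keeps
circRNAs with counts ≥ 2 in ≥ 20% of samples; these thresholds are
configurable defaults chosen as ordinary expression-QTL practice, not
claimed to reproduce any specific study's unstated values. The INT
maps rank r (average ranks on ties) to Φ⁻¹((r − ½)/n), so every
tie-free phenotype row carries the identical multiset of normal
quantiles; the preceding z-score step therefore only matters for rows
with ties and for the transformation log's readability.

Hidden expression covariates are the top-k sample-space principal
components of the row-centred phenotype matrix. This is a deliberate,
clearly-labelled PCA stand-in for Bayesian factor models (PEER-style):
it is testable by planted-factor recovery and has no inference
machinery to go wrong. The default is k = 2 at the simulator's scale.
The reason is statistical, not computational: PCs are estimated from
the phenotype matrix itself, and when k is an appreciable fraction of
the number of phenotype rows (the simulator produces ~15–20), the
factors absorb the planted genotype effects and re-inject them into
other phenotypes' residuals, simultaneously deflating power and
inflating false associations. With thousands of phenotype rows — the
regime real cohorts occupy — k of 10 or more is appropriate and the
config exposes it. Genotype PCs (population structure) are available
but default to 0 because the simulator's cohorts are unstructured.

## cis-QTL mapping

Variants within ± 1 Mb of the circle boundaries (window configurable;
at the simulator's chromosome sizes every same-chromosome variant is
cis) are tested by OLS of the covariate-residualized phenotype on the
covariate-residualized dosage; two-sided t test with
n − n_covariates − 2 degrees of freedom. Monomorphic variants are
skipped and logged.

The locus-level empirical p-value permutes the residualized phenotype
across samples (covariates stay fixed), recording each permutation's
best association. Permutations are compared on r² (monotone in the
t statistic), so only one p-value per permutation is ever computed.
The adaptive rule runs at least 100 permutations and stops once 15
permutation optima beat the observed optimum, or at 10,000;
`empirical_p = (1 + hits)/(1 + perms)`. The permutation minima are
then fitted with a Beta(α, β) by Newton iteration on the exact
log-likelihood gradient (digamma/trigamma), method-of-moments start,
tolerance 1e-8, falling back to the method-of-moments estimate after
100 iterations; `beta_p = BetaCDF(p_top; α̂, β̂)` interpolates below the
1/(B+1) floor of the raw empirical p. Each phenotype draws its
permutations from an independent stream seeded by (seed, row index),
so results are independent of execution order and trivially
parallelizable.

Feature-level FDR: Storey q-values with the single-λ estimator
π̂₀ = min(1, #{p > 0.5} / (0.5 m)) applied to step-up-adjusted beta_p.
The single-λ form is simpler than the smoother, conservative (clamped
at 1), and exactly testable by hand. eCircRNAs are phenotypes with
q < 0.05.

## Colocalization

Single-causal-variant approximate-Bayes-factor colocalization from
(beta, se) pairs. QTL-side effects come from the nominal scan on INT
phenotypes (quantitative prior, W = 0.15²); GWAS traits use W = 0.2²
when case-control. Hypothesis sums are evaluated in log space with
log-sum-exp; the H3 inner term `S1·S2 − S12` is computed as a log
difference and clamped to zero mass when non-positive (single-variant
loci). Variants are intersected by id with allele harmonization — a
ref/alt swap flips the effect sign, strand-ambiguous A/T and C/G pairs
are dropped — and pairs with fewer than 25 shared variants are
skipped. Priors default to the cited convention (p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵); the shared-variant threshold, priors and the PP.H4 ≥ 0.5
call are all configurable.

## Simulator: what it emulates, and what it does not

The generator reproduces the *structure* of a circQTL study — a
40-sample cohort, ~20 circRNAs inside 10 linear transcripts on 2
chromosomes of 120 kb, three callers with sensitivities 0.9/0.85/0.75
and Poisson(3) method-specific false junctions, paired 75-nt reads
(fragment length 250 ± 30), 40 biallelic HWE variants per chromosome
(MAF 0.1–0.5, optional copying-LD), 5 planted circQTLs with per-allele
log-abundance effect 0.35, and two GWAS traits (n = 20,000, causal
variant explaining 1% of liability) of which one shares its causal
variant with a planted circQTL. Abundances are Poisson around a
lognormal baseline (mean 30 countable junction fragments; a
negative-binomial dispersion knob exists but defaults to the Poisson
limit for oracle simplicity). The expected *countable* fragment count
is held at the nominal abundance regardless of circle length by
drawing total circle fragments as Poisson(abundance / p_capture),
where p_capture is the exact probability that a uniformly-placed
fragment yields a mate spanning the junction with ≥ 7-base overhang.
Caller detection of a true junction is drawn once per (method,
junction) cohort-wide — emulating a method's systematic blind spots —
with per-sample read counts Poisson around truth. GWAS statistics are
marginal regressions of a latent liability on an independently
simulated panel at the cohort's allele frequencies; this is exact at
the level of (beta, se) inputs to colocalization and far cheaper than
case-control sampling.

It does *not* emulate: real LD panels, sequencing quality-score decay,
indels, rolling-circle multi-lap fragments, isoform structure within a
shared BSJ, library-size variation between samples, or
ascertainment-biased GWAS effect sizes. Passing tests therefore
demonstrate the correctness and calibration of the pipeline's
decisions under its stated contracts, not robustness to every artefact
of real libraries.

Every generator is a pure function of (seed, parameters); FASTQ, VCF
and TSV outputs are byte-stable across runs, which the test suite
checks at the level of whole output trees.

## Problem sizes used by the test suite

The suite exercises the quantifier at 3 samples × ~50,000 fragments
(exact agreement with a brute-force recount from ground-truth fragment
origins), calibration at 10,000 null tests, Beta-approximation
fidelity on 50 loci × 10,000 permutations, planted-QTL recovery (40%
variance explained, n = 40) over 50 replicates, colocalization over 20
shared- and 20 distinct-causal replicates, and full-pipeline
determinism at the default scenario size. These sizes were chosen so
the whole suite completes in a few minutes on one CPU while keeping
the Monte-Carlo error of each checked statistic small relative to its
acceptance band.

## Known limitations

- Short circles (L < 149) use truncated arms; reads longer than the
  arm are uncountable, biasing short-circle quantification downward.
- A fragment is counted once even when both mates span the junction
  (the alternative — counting mates separately — would double-count
  fragments, but the choice is not validated against any upstream
  tool).
- The π₀ estimator at a single λ = 0.5 is noisy for small phenotype
  sets (its variance scales as 1/m); with tens of phenotypes the
  q-values are correct in expectation but the eCircRNA count is
  variable.
- Colocalization assumes a single causal variant per trait per locus;
  multi-signal loci dilute PP.H4.
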