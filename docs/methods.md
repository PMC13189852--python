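# Methods

This note documents the statistical model behind `rarehap`, the default
parameters and why they were chosen, what the synthetic generator does and
does not emulate, the numerical conventions, and known limitations.

## Pipeline model

The engine operates on a *pool*: a binary variants × haplotypes matrix paired
with a per-variant legend (position, alleles, annotation class, protected
flag, prune weight, causal label, pruned flag).  Positions are 1-based and the
alternate allele is always the counted (minor) allele, so a variant's minor
allele count (MAC) is its row sum.  The pool must be *over-abundant*: it
carries more rare variants than expected, and the engine only ever removes
variants — a deficit is reported as a warning, never corrected by adding
variants, because an under-simulated pool signals a problem upstream.

### MAC bins

"Rare" means MAC ≤ round(0.01·M), inclusive of the boundary (a variant at
exactly 1% MAF is binned, filtered, and counted as rare).  The default schema
for M haplotypes is [1,1], [2,2], [3,5], [6,10], [11,20], [21, round(0.005·M)],
[round(0.005·M)+1, round(0.01·M)]; at M = 20,000 this is the familiar
seven-bin layout ending at MAC 100 and MAC 200.  Percent boundaries use
round-half-up.  For small M, bins whose nominal bounds collapse are dropped
and the survivors stay contiguous up to the cap (at M = 2,000 five bins
remain), which keeps the engine usable on toy inputs instead of erroring.

### Expected counts

Two parametric curves:

* `Nvar(n) = φ·n^ω` — rare variants per kilobase at diploid sample size n,
  with φ > 0 and 0 < ω ≤ 1 (densities grow sublinearly with sample size).
  `fit_nvar` estimates (φ, ω) by ordinary least squares on the log-log scale
  from calibration points.
* `f(z) = α·(z+β)^(−γ)` — the MAC decay, normalized over z ∈ [1, cap].  α
  cancels under normalization; β flattens the head; γ sets how
  singleton-heavy the spectrum is.  `fit_afs` estimates (β, γ) by nonlinear
  least squares against target bin proportions, multi-started from a fixed
  grid; a fit at the γ floor (an essentially flat spectrum) is flagged.

The per-bin, per-class expectation splits the total `Nvar(n)·L_kb` by the
model bin proportions and a scalar functional share, applies the class
weights, then floors at the per-bin minimum.  Ordering matters and is
deliberate: weighting before thresholding guarantees the floor regardless of
weights.  Expectations are computed for the haplotype count of the matrix
being pruned (M = 2·(N_case + N_ctrl) in the case-control flow), which is what
makes the bin cap and the sample's rare-variant definition agree.

### Pruning

For each class being pruned and each bin (largest MAC first — this fixes the
random stream layout; whole-variant removal makes bins independent, so order
does not affect the outcome distribution): the real-valued target is resolved
by *stochastic rounding* (floor with probability 1−frac, ceil otherwise),
which preserves the expectation exactly across replicates, unlike truncation.
Excess variants are selected without replacement with probability
proportional to their prune weights via exponential keys
(Efraimidis–Spirakis), which realizes the successive weighted-draw
distribution exactly; protected and zero-weight variants are never selected.
If too few variants are eligible, everything eligible is pruned and a
shortfall warning is recorded (non-fatal by design — a simulation run should
complete and report, not die mid-pipeline).

Pruned rows are kept as all-zero rows and flagged in the legend so that
haplotype column indices remain valid across nested prunes; the writer drops
them on request.

### Scenarios

Three paired arms from one pool, with case/control column index sets drawn
disjointly up front and reused everywhere:

* same direction: cases from the w_fun,a-pruned matrix, controls after a
  further prune of the functional class down to w_fun,b1;
* null: cases and controls are disjoint column sets of the *same* matrix;
* opposite direction: two branches pruned from the w_fun,a matrix at
  w_fun,b2 (pruned variants labeled protective) and w_fun,b3 (protective
  variants shielded from selection, pruned variants labeled risk).

Shielding (rather than deleting) the protective set in the second branch
makes its prunable pool exactly the survivors of the first branch, so risk
and protective label sets are disjoint and each is present in exactly one
arm.  The arm weights follow `w_b2 = p·w_a + (1−p)·w_b1`,
`w_b3 = (1−p)·w_a + p·w_b1`, which conserves the total causal excess across
scenarios.  Each step consumes an independent child seed derived from the
master seed and a fixed stream id, so one integer reproduces the whole
bundle.

### Association tests

Intercept-only score tests for a binary phenotype, in closed form (the
benchmark phenotype is group membership by construction, so no covariate
machinery is needed):

* Burden: `U = Σᵢ(yᵢ−ȳ)bᵢ` with `bᵢ = Σᵥ wᵥgᵢᵥ`, variance
  `ȳ(1−ȳ)Σᵢ(bᵢ−b̄)²`, referred to a 1-df chi-square.
* SKAT: `Q = Σᵥ wᵥ²sᵥ²` with `sᵥ = Σᵢ(yᵢ−ȳ)gᵢᵥ`; the null is the weighted
  chi-square mixture with weights the eigenvalues of
  `ȳ(1−ȳ)·W·Gcᵀ Gc·W` (Gc column-centered).  Tail probabilities use
  three-moment matching to a scaled noncentral chi-square (Liu–Tang–Zhang);
  this is accurate at conventional levels but only approximate in the far
  tail.  For a single variant SKAT reduces to Burden exactly.
* SKAT-O: `Q_ρ = (1−ρ)·Q_SKAT + ρ·(Σᵥwᵥsᵥ)²` over a grid containing ρ = 0
  and 1; the statistic is the minimum per-ρ moment-matched p, and the final
  p-value is its permutation tail probability under phenotype relabeling with
  an add-one correction.  Permutation calibration is exactly valid at any
  grid size and sidesteps the one-dimensional integration of the analytic
  approach (a possible future extension); its cost is Monte-Carlo resolution
  1/(n_perm+1).

Variant weights are flat by default, with Beta(1,25) MAF weighting available.

## Synthetic pools: what they are and are not

The generator draws `stochastic_round(inflation · Nvar(M/2) · L_kb)` variants,
samples each variant's MAC independently from the normalized decay, assigns
carriers uniformly at random across columns, labels each variant functional
with probability `prop_fun`, and places variants at strictly increasing
positions.  This is a *statistical stand-in* for a population-genetic
simulator: there is **no linkage disequilibrium, no recombination, no
demography**, and carriers are exchangeable.  The pruning/extraction/scenario
engine never looks at LD, so synthetic pools exercise it fully — but passing
benchmarks on them says nothing about LD-dependent behavior of downstream
analyses, and synthetic pools should not be mistaken for realistic haplotypes.

## Default study conditions

Chosen once as a desk-scale small-gene setting and used by the benchmark
harness, the examples, and the acceptance script:

| parameter | default | meaning / rationale |
|---|---|---|
| φ, ω | 1.0, 0.45 | ≈31 rare variants/kb at n = 2,000 — exome-like density |
| β, γ | 0.0, 1.5 | singleton-heavy decay (~39% singletons at cap 40) |
| region | 2.0 kb | a small gene's coding footprint; keeps replicates cheap |
| inflation | 1.6 | must exceed the largest pruning weight (1.4) with headroom |
| prop_fun | 0.6 | functional share of rare coding variants |
| w_fun,a / w_fun,b1 | 1.4 / 1.0 | benchmark pruning weights; p = 0.5 in the opposite arm |
| pool size | 2(N_case+N_ctrl) | the arms consume the whole pool, avoiding batch effects |
| test weights | flat | Beta(1,25) available |
| SKAT-O | ρ ∈ {0, .01, .04, .09, .16, .25, .5, 1}, 500 permutations | standard grid; p resolution 1/501 |

The benchmark experiments are scaled down relative to a production power
study (2,000 null replicates and 500 power replicates at N = 1,000 + 1,000);
all three methods are run on the same replicate datasets, so method
comparisons are paired.

## Numerical conventions and degenerate inputs

* round-half-up for all percent-of-M boundaries;
* stochastic rounding always consumes one uniform, keeping random streams
  aligned whether or not the target is integral;
* child seeds are 31-bit values derived from (master, stream-id) seed
  sequences;
* a constant phenotype raises; zero burden variance or an all-zero SKAT
  kernel returns p = 1 with a flag rather than dividing by zero;
* empty AFS classes return a zero vector with an `empty` flag;
* extraction returns columns sorted ascending so outputs are canonical.

## Known limitations

* No LD in synthetic pools (above).  Spectrum realism is as good as the
  supplied (or fitted) decay parameters.
* The functional share is a single scalar across bins; no per-bin class
  model is provided.
* SKAT's moment-matched tail is approximate; far-tail p-values (≪ 1e-4)
  should not be over-interpreted.  SKAT-O p-values are bounded below by
  1/(n_perm+1).
* The relative power of Burden versus SKAT in the same-direction scenario is
  regime-dependent: it hinges on how singleton-heavy the spectrum is and on
  the rare-MAC cap of the sample.  At the desk-scale defaults (cap 40,
  γ = 1.5) the two tests sit near parity at w_fun,a = 1.4, with SKAT slightly
  ahead — proportional per-bin pruning occasionally creates case-only
  variants of 20–40 alleles that SKAT detects individually.  Steeper,
  more singleton-heavy spectra and larger samples shift the balance toward
  Burden.  The opposite-direction contrast (SKAT ≫ Burden) and null
  calibration are robust across these regimes.
* Multi-allelic variants, VCF/PLINK I/O, covariates, related samples and
  quantitative traits are out of scope.
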