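# Methods

## Score residuals

The null generalized linear model regresses the trait on an intercept
and the covariates only; genotype terms are fixed at zero, so the
residuals carry whatever trait variation the covariates do not explain
and no information about any particular SNP combination leaks into
them.  Gaussian traits are fit by ordinary least squares with identity
link; binary traits by logistic regression.  Scores are internally
studentized residuals — residual divided by `σ̂ √(1 − hᵢ)` with `hᵢ`
the hat-matrix leverage — in the gaussian case, and leverage-adjusted
Pearson residuals `(yᵢ − μ̂ᵢ)/√(μ̂ᵢ(1 − μ̂ᵢ)(1 − hᵢ))` in the binomial
case.  The studentization variant is switchable (`internal`, `pearson`,
`none`); the internal variant is the default because it is the common
reading of "studentized by a sample-based estimate of a population
standard deviation" and the direct analogue across both families.
Degenerate inputs (constant trait, perfect covariate fit, fitted
probabilities of 0 or 1) raise rather than silently emitting zero
scores, which would tie every cell.

With no covariates and a binary trait, the intercept-only fit makes
every score's sign equal its case/control label, which is why MDR and
FMDR are realized as the covariate-free special cases of GMDR and FGMDR
rather than as separate count-based implementations.  This unification
is also what lets the covariate-blind methods run on continuous traits
(scenario 1 of the simulation study), which classic count-based MDR
cannot do.

## Cells and the fuzzy balanced accuracy

Cell j of a k-SNP model is the mixed-radix base-3 encoding of the
genotype tuple (first SNP most significant), matching the AABB…aabb
enumeration of the cell reports.  Samples missing any genotype of the
combination are dropped from that combination's table only.  Each
nonempty cell carries its nonnegative score mass, the magnitude of its
negative score mass, and its mean score.

The negative-score sum enters the confusion measures as a magnitude.  A
signed convention would produce negative FP/TN and balanced accuracies
outside [0, 1]; the magnitude convention preserves the
sensitivity/specificity analogy (positive score mass plays the role of
cases, negative mass the role of controls) and makes the indicator
reduction to the crisp method exact.  Empty cells contribute nothing to
any confusion term: no defensible membership degree exists for an
unobserved genotype combination.  Cells whose mean equals the threshold
are classified high-risk (the "nonnegative" rule).

## Membership thresholds

The sigmoid membership needs a band (t_l, t_h), which the original
method leaves to be "determined a priori" and never publishes.  Two
default rules are provided:

- **Single-table reports** (`default_thresholds`): a symmetric band
  `±spread·σ` where σ is the population standard deviation of the
  table's nonempty-cell means (default spread 1).  Natural when only
  one table is inspected.
- **Searches and power studies** (`null_noise_thresholds`): a fixed
  dataset-level band `±2·soft_se·σ(S)·√(3^k/n)`, i.e. scaled to the
  standard error of a null cell's mean score (cells hold ≈ n/3^k
  samples).  Cells within a few SEs of zero — the "tied" cells whose
  crisp assignment is unstable — receive partial membership, while
  clearly signed cells stay effectively crisp (the sigmoid passes 0.9
  at half the band).  The half-transition width `soft_se = 4` was fixed
  once by a sensitivity scan of detection power on simulated data.

The search deliberately does **not** re-estimate the band per
combination: a per-table band makes the fuzzy balanced accuracy nearly
scale-free across combinations (every table is normalised by its own
spread), which erases the between-model contrasts the search ranks on —
we measured fuzzy power dropping below crisp power under that rule.
Explicit `--tl/--th` override both defaults.  A zero-width band
degenerates to the indicator; at `s = t_l` the singular middle branch is
replaced by its continuous limit 0.

## Cross-validated search

Scores are computed once on the full data and reused across folds (the
null model has no genotype terms, so there is no leakage of the tested
signal); per-fold refitting of the null model is available as
`refit_scores_per_fold`.  Folds are a seeded round-robin deal, optionally
stratified by a binary trait.  For each fold, all C(p, k) combinations
are ranked by training BA; testing BA drops held-out samples into cells
with membership degrees learned on the training fold, and test samples
landing in training-empty cells are left out (no membership is defined
for them; a fold whose remaining test mass is one-sided contributes NaN
and is excluded from the mean).  The best model maximizes CVC with mean
testing BA as tie-break, then lexicographic order — the reference
analyses state "minimum prediction error and maximum cross-validation
consistency" without a precedence, and CVC-first matches how their
result tables are narrated.

## Simulation design

Penetrance models are 3×3 tables `f = b + d·(u vᵀ)` with per-locus
contrast vectors u, v centred to HWE-weighted zero mean, so all
HWE-weighted marginals equal the baseline b = 0.5 identically — neither
causal locus is detectable alone.  Five built-in contrast shapes
(additive×additive "xor", heterozygote checkerboard, dominant,
recessive, mixed) stand in for externally published table collections,
which can be loaded verbatim via `load_penetrance_table`.  Heritability
is defined as `Var_w(f) / (K(1−K))` with K the HWE-weighted mean — the
standard normalisation for disease penetrance tables, chosen because it
is scenario-independent; d is solved from the target h².  The outer
product construction bounds the attainable h² per (pattern, MAF) — the
generator reports the attainable maximum when asked for more — so the
study grid (`study_models`) takes the reference levels
h² ∈ {0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4} × MAF ∈ {0.2, 0.4} and
filters by attainability (40 of 70 cells).

Three scenarios share the genetic effect `X ~ Normal(f(g₁,g₂), 0.1)` and
covariate `Z ~ Normal(0, 0.7)`, with β = γ = 1 and α = 0 unless
overridden:

1. continuous: `Y = α + βX + γZ + ε`, ε sd 1;
2. median split: latent value as scenario 1 with ε sd 0.5, case = above
   the replicate median (exactly 1000/1000 at n = 2000);
3. logit: `logit P(Y=1) = α + 0.5·X + γZ + ε` with ε sd 2 inside the
   linear predictor (an over-dispersion device), cases and controls
   accumulated by rejection to exact quotas.

Defaults are n = 2000 samples and p = 100 SNPs; background SNPs are
independent HWE draws with MAF uniform in [0.05, 0.5].  Everything is
bit-reproducible from a seed.

What the generator does **not** emulate: linkage disequilibrium,
population structure, genotyping error/missingness patterns, >2-locus
causal models, and the per-scenario coefficient calibration the
reference study applied (its coefficients were tuned to a 50–60%
average success rate; here they stay at the stated values and are
exposed as configuration).  Passing tests therefore demonstrate
correctness of the machinery and the *relative* behaviour of the four
methods under clean epistasis, not absolute power on real cohorts.  In
particular, scenario 3's logit-scale signal at these penetrance scales
is weak, and its absolute powers at desk scale sit far below the
reference study's; the method ordering, estimated on shared replicates,
is the meaningful comparison.

## Power estimation

Power is the fraction of replicates in which the causal pair attains
the strictly highest BA among all C(p, 2) pairs — ties count as misses
(conservative; ties have measure zero for continuous scores).  Ranking
uses full-data training BA by default, with cross-validated ranking
behind `with_cv`.  Replicate r uses seed base+r, and all methods are
evaluated on identical replicates, so per-model power differences are
exactly paired for the Wilcoxon signed-rank test (zero differences
dropped, per the conventional treatment).  The test-suite and
acceptance-script studies run 25 replicates with p = 20 SNPs (p = 100
for null calibration), sizes chosen to keep the full three-scenario
grid a few minutes of compute while leaving Monte-Carlo error on a mean
power near ±0.01.

## Numerical notes

- Cell aggregation is by `bincount` over base-3 cell indices; the
  brute-force oracle in `fgmdr.fixtures` recomputes BA with per-sample
  Python loops and shares no code with the production path.  Agreement
  is bit-exact for dyadic-rational scores and ≤ 1e-12 otherwise
  (summation order differs).
- `default_thresholds` uses the population (divide-by-n) standard
  deviation for determinism.
- Exhaustive searches beyond a combination budget (default 200 000)
  raise with advice to pre-filter to a candidate panel, mirroring how
  the reference analyses restricted to 30 and 10 candidate SNPs.
- Stratified folds that would leave a fold without both classes raise.

## Known limitations

- Interaction order is capped at k = 5 (the range analysed in the
  reference study); no heuristic search is provided beyond exhaustive
  enumeration.
- GLM families beyond gaussian/binomial are out of scope.
- No permutation-based significance testing of the selected model.
- The membership band default is a package choice; absolute fuzzy-BA
  values (and to a lesser degree power) are sensitive to it.
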