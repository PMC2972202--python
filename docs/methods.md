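# Methods

## Model and statistic

The trait model is the single-combined-effect first-stage model
g(E[Y_i]) = β₀ + Σ_j β_j G_ij with a logit link for dichotomous traits and
the identity link for continuous ones, where G_ij counts minor alleles
(additive coding; a dominant coding would be nearly identical for rare
variants). Rather than estimating p unstable per-variant effects, every
test evaluates a single aggregated predictor S_i = Σ_j w_j s_j γ_j G_ij and
forms the score statistic

T = U² / (σ̂²_Y · Σ_i (S_i − S̄)²),  U = Σ_i (Y_i − Ȳ) S_i,
σ̂²_Y = n⁻¹ Σ_i (Y_i − Ȳ)².

With maximum-likelihood (1/n) variance scaling this is algebraically the
score test of a logistic (binary Y) or linear (continuous Y) regression of
Y on S with the intercept profiled out, hence χ²₁ under the null for a
fixed model; the test suite verifies the identity against a
statsmodels-derived oracle to 1e-10 and the χ²₁ law by simulation
(10,000 null replicates: mean within [0.95, 1.05], KS distance < 0.02).
Degenerate models (constant S, or constant Y) are assigned T = 0 instead
of raising, so families containing empty groups remain well-defined under
maximization. T is invariant to affine rescaling of S and of continuous Y.

### Weight components

- **w (continuous weight).** Constant (all 1: the burden/dosage-sum test),
  or Madsen–Browning: w_j = 1/√(n q_j (1−q_j)) with
  q_j = (m_j + 1)/(2 n_ref + 2), where m_j is the minor-allele count among
  controls (dichotomous) or all subjects (continuous) and n is the total
  sample size. The pseudocount keeps weights finite for variants unseen in
  the reference group. The sample entering n is the total sample; the
  reference group enters only through q.
- **s (direction).** All +1 (all-deleterious assumption), or estimated:
  +1 when the minor allele is more frequent in cases than controls, −1
  when less frequent, +1 on an exact tie (so with no information the
  signed test reduces to the unsigned one); for continuous traits the sign
  of cov(Y, G_j), +1 at zero.
- **γ (inclusion).** A hard MAF threshold (inclusive boundary, so a
  threshold drawn from the observed MAFs includes its own variant);
  "all MAF" (one model per unique observed nonzero MAF — these γ vectors
  are nested); functional groups (all nonsynonymous, or the deleterious
  calls of any of the three annotation algorithms) crossed with MAF
  thresholds; or the step-up search below. Monomorphic variants are always
  excluded: they carry no information and would break MAF-indexed model
  families.

MAF thresholds use the full-sample (cases + controls) frequency, the
convention of the variable-threshold literature; control-only frequencies
appear only inside the Madsen–Browning weight, where the method prescribes
them.

### Maximization and step-up

For a model family M the reported statistic is max over M of T, first
label winning ties, so the procedure is deterministic given the family
order. The step-up search replaces explicit enumeration: compute the
univariate statistic of every polymorphic variant (with the chosen w and s
applied), keep the best, then repeatedly add the variant whose inclusion
yields the largest statistic, stopping as soon as the best addition fails
to *strictly* increase it (a plateau terminates; candidate ties break to
the lowest variant index). Weights and signs are computed once from the
full data and applied marginally, not re-estimated per subset. The
accepted-step statistics are strictly increasing, the result is never
below the best univariate statistic and never above the exhaustive
best-subset statistic (verified by enumeration for p ≤ 6, with equality
forced and checked at p ≤ 2); worst-case cost is O(p²) statistic
evaluations.

Internally, per-model statistics are evaluated as quadratic forms
U = cᵀu and V = cᵀQc, where u = G_cᵀ(Y − Ȳ) and Q = G_cᵀG_c is the
phenotype-independent centered Gram matrix cached on the genotype object;
step-up updates U, V and the cross-term vector incrementally, so one full
search costs O(np) for the mat-vec plus O(steps·p) array work. The
definitional route (explicit S, then T) is public API and the suite
asserts the two routes agree to 1e-9.

### Permutation inference

Data-estimated quantities (signs, control-frequency weights, the selection
path) make the naive χ²₁ reference invalid, so p-values come from
permuting phenotype labels (preserving genotype LD) and re-running the
*entire* procedure per permutation; p = (1 + #{T_b ≥ T_obs})/(B + 1). The
add-one estimator is never zero and yields a valid (super-uniform) test at
any B; validity is verified by null simulation and against exhaustive
enumeration of all 4! label permutations on a toy dataset. A regression
test demonstrates why full re-computation matters: freezing the signs at
their observed values inflates the null rejection rate at α = 0.05 to
≈0.5 in our null simulations, while the correctly re-computed test stays
at the nominal level. An optional adaptive rule (stop after a configurable
number of exceedances, default 10, reporting p from the permutations seen)
serves screening workloads; the study-scale default is B = 500.

### CMC comparator

The combined multivariate and collapsing comparator regresses disease on
an any-rare-variant indicator (rare: 0 < maf ≤ cutoff) plus one dosage
term per common variant, and reports the likelihood-ratio χ² against the
intercept-only model with df = 1 + #common (constant/collinear columns
dropped with a warning). It is evaluated with its asymptotic p-value
only, never permuted (multivariate logistic fits inside a permutation
loop would dominate the runtime for no inferential gain); non-convergent
(separated) fits return NA and are excluded from power tallies. The fit is
delegated to statsmodels and checked against direct likelihood
maximization to 1e-6.

## Synthetic haplotype pool

The generator emulates a deeply sequenced candidate-gene panel of the kind
these tests target — on the order of 750 coding-region SNPs across 16
genes in a few hundred individuals, ~85% of variants below MAF 0.01, with
three partially agreeing deleteriousness algorithms — rather than
reproducing any particular dataset:

- Defaults p = 48 variants and H = 256 haplotypes per pool — the order of
  one deeply sequenced gene; haplotype frequencies are a symmetric
  Dirichlet(1) simplex draw.
- Target MAFs are log-uniform, 85% on [2·10⁻⁴, 0.01] and 15% on
  [0.01, 0.35]; each variant is assigned a random haplotype subset whose
  total frequency approaches but never exceeds its target, so the realized
  spectrum stays rare-heavy (verified ±7 percentage points at p = 400).
- 30% of variants are nonsynonymous (higher than the ~16% typical of such
  panels, so a 48-variant pool reliably contains functional rare
  variants); a latent 40% of those are truly deleterious, the order of the
  fraction SIFT-style algorithms call intolerant among nonsynonymous
  coding variants. The continuous score is uniform on [0, 0.05) for deleterious
  and [0.05, 1] for tolerated variants, with 0.05 the conventional
  intolerance cutoff; the three algorithms are conditionally independent
  noisy observers of the score-derived truth with accuracy chosen so each
  pair agrees with probability `concordance` (default 0.6; values below
  0.5 are unreachable under this construction and are rejected).
- Individuals are two independent haplotype draws (Hardy–Weinberg random
  mating); no LD beyond what the finite haplotype set induces, no
  sequencing error, no missingness, no population structure. Passing tests
  therefore speak to the statistical procedure under a clean, idealized
  population — not to robustness against data artifacts.

## Disease scenarios

All effects are capped at |β_j| ≤ log(OR) so no allele contributes more
than the nominal odds ratio (mean difference, for continuous traits).
"Functional" defaults to the deleterious calls of algorithm A (the
generating algorithm, playing SIFT's role), except scenario 3 (all scored,
i.e. nonsynonymous, variants) and scenario 4 (algorithm B, playing PMUT's
role, which enlarges the common-variant causal set).

1. β_j = log(OR) for functional variants with pop MAF ≤ c (default 0.01).
2. As 1, with c redrawn each replicate uniformly from the pool's distinct
   MAFs below 0.05 — the causal frequency is unknown.
3. β_j = log(OR)·(1 − score_j): predicted-more-deleterious variants get
   proportionally larger effects.
4. β_j = log(OR)·(λ + maf_min)/(λ + maf_j) over functional variants: at
   small λ (default 0.01) only the rarest variants matter; larger λ gives
   common variants increasing effect. The specific decay is this package's
   choice among curves with those limiting properties.
5. Rare functional variants are greedily assigned (in random order) to a
   deleterious set until it holds ≈`deleterious_fraction` of their total
   allele frequency (defaults 0.5 and 0.8 as the two study arms);
   deleterious variants get +log(OR), the rest −log(OR). At fraction 1
   this reduces exactly to scenario 1.

The intercept β₀ solves E_G[expit(β₀ + Gβ)] = K (default prevalence
K = 0.01) exactly over the H² Hardy–Weinberg haplotype pairs when
H² ≤ 10⁶ (brentq to 1e-12; the expectation is monotone in β₀ so the root
is unique), else over a fixed Monte-Carlo genotype sample. Case-control
datasets are rejection-sampled from the calibrated model; when β ≡ 0 the
genotype distribution is independent of disease status, so genotypes are
drawn unconditionally — an exact shortcut, not an approximation.
Quantitative traits are Y ~ Normal(Gβ, 1) on unascertained individuals.

## Power study scales

The full-scale profile is 13 pools × 500 simulations × 500 permutations
per test at α = 0.05. The package's default desk profile is 3 pools ×
200–300 simulations × B = 199 permutations ((B+1)·α integer, so p = α is
exactly attainable under the add-one estimator), with 250–1000 cases and
as many controls; these sizes give binomial standard errors of ~1–3
percentage points on power estimates, which is what the qualitative
orderings reported here need. Per-replicate seeds are spawned from the
master seed by counters, so any replicate is re-runnable in isolation.
Power is the fraction of replicates with p ≤ α, counts pooled across
pools (the analogue of averaging over genes); 95% CIs are Clopper–Pearson.

The signed-vs-unsigned power ordering under mixed-direction effects
(scenario 5, 50/50 split) is asserted on the continuous-trait arm (mean
difference 0.6, n = 2000), where signing shows its clearest benefit; in
the dichotomous arm the same ordering holds at the point estimates
(e.g. 0.56 vs 0.47 at OR = 4, 1000/1000) but the gap is within CI overlap
at desk scale, so it is not asserted as a separated comparison.

## Known limitations

- No covariate adjustment, no stratified permutation, no missing-genotype
  handling (missing genotypes are rejected, never imputed), biallelic
  unphased sites only.
- Asymptotic p-values are provided for the CMC comparator only; everything
  data-adaptive is permutation-only by design.
- The hierarchical second-stage extension (random variant-effect
  distributions) and step-down selection are out of scope.
- The simulator's idealizations listed above mean power numbers should be
  read as comparisons between methods under identical conditions, not as
  absolute predictions for any real study.
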