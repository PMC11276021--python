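# Methods note

This note defines every model, parameter and rule the package implements,
states defaults and units, delimits what the synthetic-data generator does
and does not emulate, and records numerical choices and limitations.

## 1. Traits, exposures and analysis combinations

Traits: systolic (SBP), diastolic (DBP) and pulse pressure (PP), all in
mmHg, with PP = SBP − DBP derived after medication adjustment. Exposures:
short and long total sleep time (STST, LTST), each a 0/1 indicator.
Analyses run per cohort for every trait × exposure × sex group
(combined/female/male): 3 × 2 × 3 = 18 combinations.

## 2. Harmonization protocol (per cohort, in order)

1. **Reading averaging.** When per-visit BP readings (`sbp_1`, `sbp_2`, …)
   are supplied instead of a single value, the within-visit mean is taken
   (missing readings ignored; all-missing ⇒ NaN).
2. **Sample filters.** Keep samples with age ≥ 18 years, TST in [3, 14] h
   (both bounds inclusive) and complete data in all analysis columns.
   Counts of each drop reason are recorded. This is a pure subset; no
   values are modified.
3. **Medication adjustment.** Treated samples get +15 mmHg added to SBP
   and +10 mmHg to DBP, the standard additive correction for
   antihypertensive treatment. It precedes winsorization and PP
   derivation, so PP of treated samples is exactly +5 mmHg relative to
   their observed value.
4. **Pulse pressure.** PP = SBP − DBP on adjusted values.
5. **Winsorization.** Each trait is clamped to mean ± 6 SD in a single
   pass, with mean and SD taken from the pre-clamping vector (sample SD,
   ddof = 1). A constant vector is returned unchanged with a warning.
6. **Exposure derivation.** TST is regressed (OLS) on intercept, age, sex
   and age × sex (sex terms dropped if sex is constant); STST = 1 for
   residuals ≤ their 20th percentile, LTST = 1 for residuals ≥ the 80th
   (linear-interpolation quantiles; boundary ties are included). The
   percentiles are derived once on the pooled filtered sample and reused
   unchanged in sex-stratified analyses.

Sex is coded 0 = male, 1 = female throughout.

## 3. Regression models and tests

Per variant with dosage G ∈ [0, 2] and exposure E ∈ {0, 1}:

- **M1 (interaction):** Y = b0 + bE·E + bG·G + bGxE·G·E + C1, with
  C1 = {age, age², sex, age·E, age²·E, sex·E, PCs, center dummies}.
- **M2 (marginal):** Y = b0 + bG·G + C2, with C2 = {age, age², sex, PCs,
  center dummies}.

Age is centred at 50 years before squaring to tame the age/age²
conditioning; center enters as treatment-coded dummies (first level
dropped); sex and sex-by-exposure columns are omitted in sex strata. A
rank check names collinear columns and aborts the fit.

Coefficient covariance is the heteroskedasticity-consistent sandwich
(X'X)⁻¹ X' diag(w) X (X'X)⁻¹ with w = r² (HC0, default), w = r²·n/(n−p)
(HC1) or w = (r/(1−h))² (HC3, leverage-adjusted). Reported tests:

- 1df Wald z = b/se against the two-sided normal tail for the marginal
  (M2), main and interaction (M1) effects;
- 2df joint Wald χ² = (bG, bGxE)' V⁻¹ (bG, bGxE) from M1's robust 2×2
  block, against χ²₂ (whose tail is exactly exp(−χ²/2)).

P-values are computed in log space (`LNP_*` columns carry ln p) and
clipped below at 5e-324 so extreme signals never round to zero.

## 4. Variant filters

Before fitting, drop: non-autosomal variants; duplicated
chrom:pos:allele-pair records (first kept); monomorphic variants;
MAF < 0.001; imputation R² < 0.3; and MAC × R² < 20 in any of the exposed,
unexposed or total samples, where MAC = min(Σg, 2n − Σg) on dosages as
observed. The MAC × R² floor is the effective-df guard that removes the
rare-variant, small-stratum fits whose robust SEs are unstable. Per-variant
diagnostics (EAF, the three MAC × R² values, drop reason) are retained.

## 5. Meta-analysis

**Allele alignment.** The first cohort reporting a variant fixes the
reference effect/other allele. Swapped-allele cohorts get betas negated
and EAF complemented (a whole-genotype flip leaves the covariance
unchanged); irreconcilable allele pairs are dropped with a log entry;
strand-ambiguous pairs (A/T, C/G) are flagged `AMBIGUOUS`, not dropped —
the synthetic panel emits only non-palindromic pairs, so the flag is
opt-in for external data.

**1df effects** pool by fixed-effects inverse variance:
b = Σwᵢbᵢ/Σwᵢ, se = (Σwᵢ)^−1/2, wᵢ = seᵢ⁻².

**2df effects** pool by GLS over the per-cohort vector βᵢ = (bG, bGxE) and
2×2 robust covariance Vᵢ: V = (ΣVᵢ⁻¹)⁻¹, β = V ΣVᵢ⁻¹βᵢ, χ² = β'V⁻¹β.
Cohorts with singular Vᵢ are dropped from the joint pooling only. The
pooled (β, V) are carried forward in `B2_*`/`V2_*` columns (and V's
off-diagonal also fills `COV_MAIN_INT`) so the second level pools exact
covariances rather than reconstructed ones.

**Two levels.** Cohorts pool within population groups; the
cross-population meta-analysis (CPMA) then pools the group tables, each
group treated as one unit. Pooled N is the sum, EAF is N-weighted,
`DIRECTIONS` records per-unit interaction-effect signs in sorted unit
order, `K_COHORTS` counts contributing units.

**Genomic control.** λ = median(observed χ²)/median(null χ²) per test
family (marginal, main, interaction at 1df; joint at 2df), computed only
when ≥ 100 variants contribute (else λ = 1 with a warning), and clamped at
1 so deflation is never applied. Correction: 1df SEs are multiplied by √λ
and p recomputed; the 2df χ² is divided by λ with `V2_*` scaled by λ to
stay consistent. GC applies after each level's pooling.

**QC.** Pooled allele frequencies can be screened against a reference
(|EAF − ref| > 0.2 flags; missing reference entries never flag).

## 6. Discovery

A meta table enters discovery only if pooled N > 20,000 (strict) or at
least 3 cohorts contributed. Variants within the MHC
(chr6:28,510,120–33,480,577, GRCh38) ± 1 Mb are masked first.

Selection routes:

- **1df:** interaction p < 5e-9 and BH-FDR q < 0.05 (FDR over the table);
- **2df:** joint p < 5e-9 and q < 0.05;
- **two-step:** marginal screen p < 1e-5 (z variants), then interaction
  p < 0.05/N_G and within-screen FDR q < 0.05. N_G is the simpleM
  effective test count: the smallest k whose top-k eigenvalues of the z×z
  screened-dosage correlation matrix reach 99.5% of the trace. Screened
  variants missing from the LD source count as independent tests.

A variant reached by several routes is labelled by priority 1df >
two-step > 2df. Selected variants are clumped greedily: the smallest
selection p (ties: larger |bGxE|, then lower position) becomes a lead and
absorbs unassigned selected variants within ±500 kb on its chromosome;
leads in LD (dosage r² ≥ 0.1) merge into the stronger locus.

Classification: 1df/two-step loci are class X when > 1 Mb from known
gene-sleep interaction loci. 2df loci are prioritized only when the lead's
marginal effect is insignificant (p > 5e-9 and marginal q > 0.05) and the
locus is > 1 Mb from known BP loci; they are class Y when
interaction-driven (interaction p < main-effect p) and class Z otherwise.
Without known-locus tables, novelty is left undetermined — never assumed.
Lead interaction effects are compared between sexes with
Z = (bF − bM)/√(seF² + seM²) at the Bonferroni level 0.05/Q, Q = number of
loci tested.

## 7. Synthetic-data generator

Scope: the generator produces data shaped like consortium inputs so the
pipeline's statistics can be validated; it does not emulate LD (variants
are drawn independently unless dosage columns are duplicated by the user),
imputation error (R² is a filter attribute only, dosages are exact
Hardy–Weinberg draws), relatedness, or longitudinal structure.

- **Genotypes.** Ancestral MAFs are log-uniform over `maf_range`
  (default (0.001, 0.5)), covering the rare tail evenly. Population-group
  frequencies follow the Balding–Nichols model: Beta(p(1−F)/F,
  (1−p)(1−F)/F) around ancestral p with divergence F (default 0.01).
  Dosages are Binomial(2, p) per sample. Variants cycle across the 22
  autosomes at 1 Mb spacing with non-palindromic allele pairs.
- **Sleep.** TST ~ Normal(7.5 − 0.005·(age − 50) + 0.10·female, 1.2) h,
  truncated to [2, 15] h — deliberately wider than the analysis window so
  the TST filter is exercised. The interaction exposure entering the
  phenotype model is derived from generated TST with the same
  residual-percentile rule harmonization applies, making planted
  interactions recoverable without attenuation.
- **Blood pressure.** SBP/DBP = base (120/75) + age effect (0.45/0.18 per
  year) + female offset (−2.5/−1.5) + 0.5 per PC unit + 1.0 per center
  index + planted genetic terms + Normal(0, 15) noise. Planted PP effects
  are injected through SBP so the derived PP = SBP − DBP inherits them.
- **Medication.** Bernoulli(0.25) treatment; treated samples' *observed*
  BP is lowered by 15/10 mmHg, so the harmonization adjustment recovers
  the underlying values by construction.
- **Ages** U(20, 80); sex Bernoulli(0.5); PCs standard normal.
- Every planted effect is emitted as a truth record (variant, trait,
  exposure, beta_main, beta_gxe in mmHg per allele).

Cohort I/O uses VCF 4.2 with `FORMAT/DS` dosages and `INFO/AF`, `INFO/R2`,
plus a phenotype TSV. In multi-cohort pipeline runs all cohorts share one
variant panel; each cohort redraws genotypes from its population group's
frequencies using per-cohort seeds spawned from the run seed
(`numpy.random.SeedSequence`), so runs are reproducible byte for byte.

## 8. Numerical choices

- OLS via LAPACK `gelsd` with an explicit rank check (rank-deficient
  designs error, naming collinear columns via QR).
- Sandwich bread from an explicit (X'X)⁻¹; HC3 leverages via an einsum of
  the hat diagonal rather than forming the hat matrix.
- Log-space tails everywhere (`norm.logsf`, `chi2.logsf`); p clipped to
  [5e-324, 1].
- 2df solves via Cholesky (single variant) and closed-form 2×2 inverses
  (vectorized meta pooling); determinant ≤ 0 marks a covariance unusable.
- Quantiles are numpy's linear-interpolation default; BH-FDR is
  `scipy.stats.false_discovery_control`.
- TSVs are written with `%.8g`; equality of repeated runs is enforced at
  the byte level through the manifest checksums.

## 9. Limitations

- No LD model in the generator: clumping/simpleM behavior under realistic
  LD is exercised only through constructed block structures in tests.
- Fixed-effects meta only; no heterogeneity statistics (Cochran's Q, I²)
  beyond the per-unit direction string.
- Dichotomous exposures only; continuous-TST interactions are out of
  scope.
- The robust 1df/2df Wald tests are asymptotic; in tiny strata the
  MAC × R² ≥ 20 floor is the only small-sample guard.
- Sex-heterogeneity testing covers female vs male lead effects only; no
  other subgroup contrasts.
- Known-locus tables for novelty classification must be supplied by the
  user; none ship with the package.
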