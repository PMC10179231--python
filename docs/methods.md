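# Methods

This note documents the models behind `mecgwas`, the defaults and why they
were chosen, what the synthetic cohort generator does and does not emulate,
and the numerical choices that matter when reproducing results.

## Disposition model and its solution

Drug amounts in the three compartments follow the linear system
A′ = K·A with

```
K = [ −(k10+k12+k13)   k21    k31 ]
    [      k12        −k21     0  ]
    [      k13          0    −k31 ]
```

and plasma concentration Cp = A₁/V1.  The effect site is a
negligible-volume compartment relaxing toward plasma at rate ke0.  A unit
bolus therefore produces Cp(t) = Σᵢ cᵢ·e^(−λᵢt) with Σcᵢ = 1/V1, where λᵢ
are the negated eigenvalues of K (all real and positive for a mammillary
model), and the effect-site response is the convolution with ke0·e^(−ke0·t),
again a four-exponential closed form that starts at zero.

The engine evaluates this closed form directly instead of integrating the
ODE, for one load-bearing reason: the MEC is defined at the *left limit*
immediately before a demand, and an exact expression evaluates that limit
(and the post-bolus jump of dose/V1) without grid blur.  Two invariants are
enforced by tests against independent oracles: the exponents satisfy the
trace identity Σλᵢ = k10+k12+k21+k13+k31 and the determinant identity
λ₁λ₂λ₃ = k10·k21·k31, and full profiles agree with a stiff LSODA
integration of the four-state system to better than 10⁻⁶ relative error
over random parameter and dosing draws.

Repeated eigenvalues (or a collision of ke0 with a disposition exponent)
make the partial-fraction form singular.  This is a measure-zero
configuration; it is detected at relative spacing < 10⁻⁹ and resolved by
perturbing the micro-constants by ~10⁻⁹ relative with a warning, keeping
the closed form usable (a one-compartment configuration with k12 = k13 = 0
remains exactly representable — the undosed modes simply carry zero
coefficients).

Units are fixed: minutes, micrograms, litres; 1 µg/L ≡ 1 ng/mL.

### Parameter defaults

The shipped `shafer_fentanyl` block (V1 = 6.09 L, k10 = 0.0827,
k12 = 0.4714, k21 = 0.2250, k13 = 0.1538, k31 = 0.0166, ke0 = 0.147 min⁻¹)
is the commonly cited adult fentanyl parameterization of the Shafer
three-compartment model with a first-order effect-site constant.  These
numbers are deliberately *configuration*, not ground truth: clinical
simulation programs differ in how (or whether) age, sex, height and weight
adjust them, and those internal rules are generally unpublished.  The
engine accepts any positive parameter set, and named blocks live in a YAML
file so alternative parameterizations can be added without touching code.

## MEC phenotypes

One (plasma, effect-site) pre-demand pair is recorded per PCA demand;
initial boluses shape the concentration field but yield no MEC point.
Window means are arithmetic means over demands in (0, h·60] minutes for
h ∈ {6, 12, 24} (the bound is inclusive), and the analysis value is
ln(1 + MEC).  A window containing no demand is *missing*, never zero, and
missing subjects are dropped from regressions on that phenotype
(complete-case; no imputation rule is defined).  If the pump reservoir is
exhausted before a window closes, the demands observed up to exhaustion
still enter the mean with no censoring adjustment — reservoir exhaustion is
the reason 0–24 h endpoints are less reliable than 0–6 h and 0–12 h ones,
and the recommended primary endpoints are the latter.

Note a consequence of the transform: a per-copy genetic effect β on
ln(MEC) appears in the ln(1 + MEC) regression shrunk by the factor
MEC/(1 + MEC) (≈ 0.45 at 0.8 ng/mL).  Recovery tests therefore assert rank
and significance of planted effects, not equality of coefficients.

## Staged association scan

Per SNP and genetic model (additive / dominant / recessive codings of the
minor-allele count), the fit is OLS of the log phenotype on
[intercept, coding, covariates].  The bulk path residualizes the phenotype
and all complete-genotype columns on the covariates once per subject set
(Frisch–Waugh) and reproduces the full-design coefficient, standard error
and two-sided t-test exactly — verified to 10⁻⁸ against statsmodels — while
scanning thousands of SNPs in milliseconds; SNPs with missing calls fall
back to per-SNP complete-case fits.  Monomorphic or covariate-collinear
codings are skipped with a log entry.  Chromosome-X markers are fitted in
females only (no hemizygous male coding).

The staged design: stage 1 keeps SNPs with p < α (default 0.05); each later
stage k keeps SNPs with stage-k p < α *and* pooled stages-1..k p < α.  The
combined analysis is a single pooled OLS over the concatenated stage
subjects with the same covariates and no stage indicator — matching a
single "combined β, combined p" per SNP; an inverse-variance meta-analysis
was the open alternative, but nothing in the procedure description suggests
one, and a stage fixed-effect covariate is available behind the API if
wanted.  Stage assignment defaults to contiguous blocks in input order
(117/117/117 at n = 351); a seeded random split is provided because the
original allocation rule is unknown.

Multiple-testing correction follows the design rather than the marker
count: q-values are Benjamini–Hochberg computed over the candidates
*selected after the penultimate stage* once that set has been greedily
LD-pruned (visit by combined p ascending, ties broken by position then id;
keep a SNP iff r² < 0.8 with every kept SNP).  Genome-wide significance
requires surviving every stage, escaping pruning and q < 0.05.  This
stratum choice is forced by arithmetic: a final combined p of ~10⁻⁷ can
reach q < 0.05 only if the BH set is the handful of staged candidates, not
the full panel.  Stratified BH (q within user-defined strata) is available
behind a keyword; the default is a single stratum since no stratification
variable is documented.

A consequence worth knowing: the staged procedure has an irreducible
false-discovery behaviour under the global null.  With 5000 null SNPs and
351 subjects, about 0.14 scans per seed (measured over 100 seeds) end with
one significant SNP — a null SNP lucky enough to pass three independent
0.05 filters nearly always carries a small pooled p, and BH over the small
candidate stratum then confirms it.  Calibration tests should therefore
expect "no significant SNP" in roughly 85–90% of null scans, not more.

## Supporting statistics

* **HWE.**  Pearson 1-df χ² against p², 2pq, q² expected counts, and the
  exact conditional test summing P(heterozygote count | allele counts) over
  outcomes no more probable than observed.  The exact test runs in rational
  arithmetic (`fractions.Fraction`), so ties need no epsilon and the
  enumeration oracle match is exact.
* **LD.**  Two-locus haplotype frequencies by EM over unphased diplotypes —
  only the double heterozygote is phase-ambiguous and is split by the
  current phase odds — then D = p_AB − p_A·p_B, D′ = |D|/D_max,
  r² = D²/(p_A p_a p_B p_b).  The observed-data log-likelihood is
  non-decreasing across iterations (tested), and with no double
  heterozygotes the EM equals direct counting.
* **Power.**  The per-stage regression F-test with df1 tested predictors at
  sample size n has noncentrality λ = f²·n and denominator df n − df1 − 1.
  df1 defaults to 1, the convention under which the three standard
  worked values at n = 117 (98.6% at f² = 0.15, 32.9% at f² = 0.02,
  f² = 0.0682 for 80% power) all reproduce.  `required_f2` inverts the
  monotone power curve by bracketed root finding to 10⁻¹² tolerance.
* **Screening.**  Spearman ρ with average ranks (exact permutation p for
  n ≤ 9), Mann–Whitney U (exact enumeration for n_A + n_B ≤ 12, otherwise
  tie-corrected normal approximation), and one joint OLS of the log
  phenotype on all clinical variables with p < 0.05 flagging them as GWAS
  covariates.

## Synthetic cohort generator

The generator defines the study conditions for every simulation-based test.

* **Genotypes** — per SNP, counts ~ Binomial(2, MAF) with MAF uniform on
  (0.05, 0.5); inside an LD block one MAF is shared and each haplotype is a
  correlated latent Gaussian thresholded at the MAF quantile, with the
  latent correlation calibrated (bivariate-normal inversion) so the block
  parameter is the *allele-level* correlation after attenuation.
* **Covariates** — age uniform 20–85 y; remifentanil rate normal around
  the 0.25 µg/kg/min protocol rate (sd 0.05, clipped at 0.05); end-of-surgery
  fentanyl 100 µg + 50 µg × Poisson(1), mimicking titration in 50 µg
  increments on top of a 100 µg bolus; 2-h pain score Binomial(10, 0.3).
* **Latent phenotype** — ln(latent MEC) = intercept (−0.75) + Σβ_snp·count
  + Σβ_cov·covariate + N(0, 0.2).  The default covariate coefficients
  (age 0.004, remifentanil rate 0.409, end-surgery fentanyl 0.001, pain
  score 0.019 — all positive) reproduce the screened association pattern,
  and the intercept and noise put latent MECs near 0.6–1.2 ng/mL with
  ln-scale spread ≈ 0.2, inside the clinically reported fentanyl MEC range.
* **Dosing** — initial 100 µg bolus at t = 0; the subject demands 20 µg at
  the first instant the *effect-site* concentration falls back to their
  latent MEC (opioids act at the effect site, not in plasma; a
  plasma-triggered mode exists for sensitivity analyses), subject to the
  pump program: 5-min lockout, ≤ 12 demands in any sliding 60-min window,
  1000 µg reservoir, 24-h horizon.  Crossings are found by coarse scan plus
  Brent root-polish on the analytic curve, so with zero behavioral noise an
  unconstrained demand sits at the latent MEC to ~10⁻¹⁰ — the basis of the
  2% round-trip acceptance check.  Optional behavioral noise multiplies the
  per-demand threshold by a lognormal factor (default off, keeping
  round-trips deterministic).  Demands forced later than their crossing by
  the lockout/cap are flagged "constrained" in the truth record, since their
  pre-dose concentration undershoots the threshold.

What the generator does **not** emulate: rescue analgesia and dropout,
pharmacodynamic pain trajectories (the latent MEC is constant within
subject over the observation window), genotyping error and missingness
patterns of real arrays, population structure and relatedness, and any
within-subject drift of opioid sensitivity.  Passing recovery tests
therefore demonstrates correctness of the estimation chain under its own
assumptions, not robustness to these real-data complications.

## Problem sizes used in validation

The calibration suites use 5000 SNPs × 351 subjects × 20 seeds for the
null scan, 1000 SNPs × 351 subjects × 20 seeds for full-pipeline planted
recovery (panel size chosen to keep a complete dosing→extraction→GWAS
round per seed while leaving the planted signal realistically embedded in
noise), 100 random parameter/dosing draws for the ODE-equivalence check,
and a 50-subject cohort for the MEC round trip.  All simulation seeds are
fixed in the tests.

## Numerical notes and edge cases

* Left/right limits at dose instants are explicit everywhere (`side="pre"`
  vs `"post"`); profile output duplicates event times to represent the jump.
* CSV writers emit 17 significant digits and readers parse with
  `float_precision="round_trip"`, so file round trips are bit-exact.
* Genotype loaders re-orient every SNP to the in-sample minor allele (swap
  logged), skip multiallelic/non-SNP VCF records with counts, treat
  half-calls as missing, and reject duplicate SNP ids.
* BH q-values are monotone-enforced and permutation-invariant; empty
  inputs yield empty outputs rather than errors.
* QQ data clips zero p-values at a configurable floor with a warning.
* The degenerate single-stage plan reduces the staged scan to simple
  p < α thresholding with BH over all SNPs, which is the expected limit.

## Known limitations

* The combined-stage estimator is pooled OLS; if stages differed
  systematically (era effects, site effects) a stage fixed effect should be
  enabled.
* The effect-site trigger model is an idealization of demand behaviour; real
  patients exhibit hysteresis, sleep, and nonstationary thresholds, so
  absolute MEC recovery tolerances are defined against the generator, not
  against clinical truth.
* Power calculations cover a single-stage regression; no closed form is
  claimed for the power of the full three-stage selection procedure.
* X-chromosome handling (female-only fits) discards male information by
  design; a hemizygous 0/2 male coding is deliberately not offered.
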