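# Methods

## The models

Allele-specific expression (ASE) at a heterozygous transcribed SNP
(tSNP) is measured per cell as `y` alternative-haplotype reads out of
`n` total allele-specific reads. Differential ASE asks whether the
allelic imbalance changes with a covariate `x` — a continuous cell
state such as pseudotime, or a donor-level condition such as disease
status. Two features of multi-donor single-cell data drive the design:
cells from the same donor are correlated, and the regulatory variant
behind the imbalance is unobserved, so its expression-increasing allele
may sit on either tSNP haplotype in different donors ("haplotype
switching"), cancelling naively pooled signal.

**Baseline model (DAESC-BB).** A beta-binomial regression with a donor
random intercept:

    y_ij | n_ij ~ BB(n_ij, mu_ij, phi)
    logit(mu_ij) = b0 + b1 x_ij + a_i,    a_i ~ N(0, sigma2_a)

`BB(n, mu, phi)` has shape parameters `mu/phi` and `(1-mu)/phi`; as
`phi -> 0` it approaches Binomial(n, mu). `phi` absorbs extra-binomial
noise within cells; `sigma2_a` the donor repeat structure.

**Mixture model (DAESC-Mix).** A per-donor orientation indicator
`z_i = 2*delta_i - 1 in {-1, +1}`, `delta_i ~ Bernoulli(pi0)`,
multiplies the fixed effects:

    logit(mu_ij) = z_i (b0 + b1 x_ij) + a_i

Donors whose regulatory allele sits on the opposite haplotype enter
with flipped sign instead of cancelling; inferring `z_i` amounts to
implicit phasing from expression alone. The pair `(b, pi0)` and
`(-b, 1 - pi0)` give identical likelihoods; the reported fit flips
post-hoc so `pi0 >= 0.5`.

Differential ASE is tested by a likelihood-ratio test of `b1 = 0`
against chi-square(1), with the null mixture model retaining the
mixture structure (`logit(mu) = z_i b0 + a_i`). Benjamini–Hochberg
adjustment is applied across genes.

## Variational EM

`a_i` (and `delta_i`) are treated as missing data. The variational
family is mean-field, `q(a_i) = N(a_hat_i, s2_i)`,
`q(delta_i) = Bernoulli(resp_i)`. Expectations of the beta-binomial
log-likelihood under `q(a_i)` use a second-order Taylor expansion
around `a_hat_i` (delta-method form), making every step cheap:

- **q(a_i):** damped Newton ascent of the responsibility-weighted
  expected complete-data log-likelihood in `a_i` (analytic
  digamma/trigamma derivatives), then `s2_i = -1/f''(a_hat_i)`. The
  curvature is floored at `-1/(2 sigma2_a)` — a posterior can never be
  much flatter than its prior — which keeps the closed-form `sigma2_a`
  update from being poisoned by near-flat donors.
- **q(delta_i):** Bernoulli with log-odds
  `logit(pi0) + E[loglik | z=+1] - E[loglik | z=-1]`.
- **M-step:** `pi0 = mean(resp)`; `sigma2_a = mean(a_hat^2 + s2)`
  iterated to its joint fixed point with the `s2_i` (plain EM creeps
  toward a zero-variance boundary too slowly); `(b0, b1, log phi)` by
  L-BFGS-B on the Taylor-corrected expected log-likelihood with fully
  analytic gradients (third-order polygamma terms included).

Every step carries an accept-only-if-better guard, so the reported
objective (ELBO: Taylor-expected log-likelihood + Gaussian prior terms
+ entropies, binomial coefficients dropped) is non-decreasing by
construction; the test suite asserts monotonicity to 1e-8 over random
fits. Convergence: relative ELBO change < `tol` (default 1e-6, the
benchmark runs use 1e-5), `max_iter` 200 default.

The LRT statistic uses the converged variational objective of full and
null fits — an approximation, since the ELBO is a lower bound, not the
marginal likelihood. Both fits share a deterministic initialization
policy (see below), and `lr_test` cross-warm-starts them: the null
fit's state seeds an extra candidate start of the full fit, and the
full fit's state then seeds a re-polish of the null (kept only if it
raises the null objective). This keeps the statistic non-negative and
prevents the more flexible full model from banking pure optimization
gains the null could reach too; without the re-polish the mixture's
null rejection rate roughly doubles.

**Initialization** is deterministic — no random restarts. The BB model
starts from the fixed-effects beta-binomial MLE, `sigma2_a = 0.5`, and a
method-of-moments `phi` from per-donor pseudobulk fractions. The mixture
splits donors by the sign of their pseudobulk log-odds deviation from
0.5 (`resp` 0.75/0.25), flips the counts of negative-side donors, and
refits the fixed-effects model on the aligned counts for `(b0, b1)`;
`pi0` starts at 0.5. A second start that split donors by empirical
slope sign was evaluated and rejected: it systematically found
noise-phasing optima under the null and tripled the type-I error.

**Special cases.** Fits with a single donor or `sigma2_a` pinned (e.g.
0) are supported for diagnostics; with the variance pinned at zero the
fit reduces to the fixed-effects MLE (asserted to 1e-3 against an
independent grid search). All-zero or all-`n` genes return with a
boundary flag rather than failing. Cells with `n = 0` are dropped at
construction with a logged count.

**Numerical notes.** `mu` is clipped to `[1e-9, 1-1e-9]`; `phi` lives
on the log scale in `[-12, 5]`. Trigamma and tetragamma are computed by
a shift-by-6 recurrence plus asymptotic series (validated to ~1e-8
against scipy; scipy's polygamma routes through the Hurwitz zeta
function and is orders of magnitude slower). The allele-swap symmetry
`y -> n - y` holds exactly at the optima; because EM float trajectories
of the mirrored problems separate at the ~1e-5 level, the mixture swap
test asserts it at 1e-3 while the BB p-value invariance is asserted at
1e-6.

## Binomial GLMM reference

The comparison method is the classical binomial mixed model
`logit(p_ij) = b0 + b1 x_ij + a_i + eps_ij` with `a_i ~ N(0, sigma2_a)`
and an observation-level `eps_ij ~ N(0, sigma2_eps)` for
overdispersion, tested by the Wald z statistic for `b1`. The cell-level
effect is integrated by 15-point Gauss–Hermite quadrature; the donor
effect by a Gaussian (Laplace) approximation. Fitting alternates an
EM-style loop with (i) a joint Newton polish of `(b, a)` using the
Schur complement over the diagonal donor block and (ii) a Nelder–Mead
refinement of `(sigma2_a, sigma2_eps)` on the Laplace marginal
likelihood. The Wald SE inverts the fixed-effect block of the joint
penalized-likelihood information over the fixed effects *and both
random-effect vectors* (the per-cell eps block is diagonal, so its
elimination just discounts each cell's binomial curvature; the donor
block is a second diagonal Schur complement), conditional on the
variance estimates — the same construction as lme4's fixed-effect
vcov. Using instead the sharper information of the GH-integrated
marginal halves the SEs on strongly overdispersed genes and roughly
doubles the type-I error on beta-binomial data: more accurate
integration of a misspecified model makes it more confidently wrong,
and the reference method is meant to reproduce the mixed-model
software behaviour practitioners actually see. On a frozen simulated dataset the fit matches
`lme4::glmer(cbind(y, n-y) ~ x + (1|donor) + (1|obs))` to ~0.03 in
log-likelihood and ~0.1 in coefficients/SE (the integration schemes
differ); exact equality with lme4 is not a goal, only distributional
behaviour. Variance estimates may sit at the zero boundary, where the
fit reproduces a plain binomial GLM to 0.02.

## Simulation engine

**Mixture proportions from LD.** For a donor heterozygous at the tSNP,
the eQTL configuration probabilities `(pi1, pi2, pi3)` for
`z = -1, +1, 0` follow from the four two-locus haplotype frequencies
`h_11 = pA pB + D` etc., with `D = +sqrt(r2 pA(1-pA) pB(1-pB))`
(positive LD sign by convention; the sign is not identified by r^2
alone) conditioned on the donor carrying one alternative- and one
reference-tSNP haplotype. Inadmissible `(maf, r2)` pairs raise an error
naming the violated frequency bound. Note `pi3 >= 1/2` whenever
`r2 = 0`: with independent loci most donors carry a homozygous eQTL.

**One-eQTL generator.**
`logit(mu_ij) = z_i (b0 + b1 x_ij + b1 eta_i) + a_i` with
`z_i ~ categorical([-1, +1, 0], [pi1, pi2, pi3])`, beta-binomial
counts. `x_ij ~ U(0, 1)` per cell (matching effect sizes quoted per
unit of cell state); `eta_i` assigns exactly N/2 cases and N/2
controls (odd N is rejected). The scenario chooses which covariate the
analysis sees. An `eta_effect=False` switch removes the donor-level
shift for focused recovery experiments, and an explicit `z` vector can
pin the orientations (e.g. half +1 / half -1).

**GLMM generator** replaces the beta overdispersion by
`eps_ij ~ N(0, 1)` with binomial counts (model-misspecification check
for the beta-binomial fitters).

**Multi-eQTL generator** draws `m` independent eQTLs:
`MAF_k ~ U[0.1, 0.5]`; haplotype alleles `g_ik0, g_ik1 ~ Bern(MAF_k)`;
`m` coefficient pairs; donor-specific effective coefficients
`bASE_i0 = sum_k b_k0 (g_ik1 - g_ik0)` and likewise `bASE_i1`; then
`logit(mu) = bASE_i0 + bASE_i1 x + bASE_i1 eta + a_i`. Donors whose two
haplotypes match at every eQTL have exactly zero allelic effect. No LD
among the eQTLs or with the tSNP (the deliberate simplification).

**Totals.** Real per-cell total ASE counts are study-specific; the
generator substitutes a zero-truncated negative binomial for both
cells-per-donor and per-cell depth, with the truncated mean calibrated
to the requested value. Defaults emulate a large multi-donor
Smart-seq2-scale experiment: ~290 cells/donor, depth mean 15,
dispersion 0.8. What the generator does *not* emulate: empirical
heavy-tailed depth profiles tied to expression level, pseudotime
distributions concentrated at differentiation endpoints, mappability
artifacts, or genotyping error — so passing benchmarks demonstrate
statistical behaviour under the stated generative model, not robustness
to those data pathologies.

**Parameter draws.** In place of an empirical strong-effect parameter
table, defaults draw `b0 ~ U[-1.5, 1.5]`, `|b1| ~ U[0.5, 2.5]` with
random sign, `sigma2_a ~ U[0.1, 1]`, `phi ~ U[0.02, 0.5]`; null genes
reset `b1 = 0`. A user table with columns `beta0, beta1, sigma2_a, phi`
is drawn from uniformly when supplied.

## Benchmarks and evaluation

Type-I error and power are rejection fractions at nominal p < 0.05
among null and non-null genes (NA p-values count as non-rejections and
are tallied). Precision–recall sweeps every distinct p-value.
Implicit-phasing effectiveness hard-assigns donors by responsibility
> 0.5 and tests the 2x3 table of assignment vs true `z` with an exact
Fisher test (probability-ordering two-sided rule; exhaustive
enumeration up to total 500, seeded margin-preserving Monte Carlo
beyond, flagged). The effectiveness fraction is reported among genes
with suggestive differential ASE (mixture p < 0.05), mirroring the
validation protocol used with real phased genotypes; over all genes
regardless of significance it runs about ten points lower at the
benchmark's reduced cell counts.

Problem sizes used by the shipped benchmark (tests and
`scripts/acceptance.py`): the full r^2 in {0, 0.1, 0.9} x N in
{10, 50, 100} grid at 30 null + 6 alternative genes per scenario,
~15 cells/donor, depth mean 15, tol 1e-5, max_iter 100 — the package's
chosen desk-scale replication of the full design (which used 400-500
genes per scenario at real-data cell counts). At this replication the
Monte-Carlo SE of a grid-mean type-I estimate is about 1.5 points.

**Known behaviour worth stating.** (1) Under `r2 = 0` at least half
the donors are homozygous (z = 0); the two-component mixture absorbs
them into both components and the fitted `|b1|` attenuates by roughly
40-50% relative to the generating value. Recovery experiments therefore
pin explicit half/half orientations; the attenuation is a property of
the model class, not a fitting failure. (2) The GLMM's Wald test is
anti-conservative on beta-binomial data, increasingly so at large `phi`
and depth (the logit-normal cannot match a U-shaped beta); the same
behaviour is reported for lme4 fits in this setting. (3) The mixture
LRT is mildly anti-conservative (~8-11% at nominal 5%) because the
null and full variational optima are found with finite, shared-policy
searches; a permutation recipe (refit on covariate-permuted data per
gene, compare LRT statistics) is the documented remedy when exact
calibration matters.

## Downstream utilities

- **Phased SNP-to-gene aggregation:** per cell, allele counts route to
  their haplotypes via `hap_of_alt` and sum; the gene's alternative
  haplotype is anchored at the tSNP with the highest total count across
  donors; donors homozygous at that tSNP get a seeded random anchor
  (seed recorded by the CLI provenance file). Reads are conserved
  exactly.
- **Unphased (pseudo-phasing):** per tSNP and donor, counts pool across
  cells; the lower-count allele is the expression minor allele; gene
  alternative count = sum of minor-allele counts. Ties go to the
  alternative allele, logged.
- **QC filters:** monoallelic-expression filter on per-donor pseudobulk
  fractions (strict < low / > high; defaults 0.02/0.98, sparse-data
  preset 0.05/0.95); coverage presets — "endoderm" removes genes with
  non-zero counts in <= 20% of cells; "pancreatic" prunes donors with
  < 3 cells or < 5 reads, then drops genes with < 50 cells, < 2 cases
  or < 2 controls. Filters are idempotent.
- **Trajectory classification:** endpoint allelic ratios
  `p = 1/(1+exp(-(b0 + b1 t)))` at the start/end cell-state averages;
  five mutually exclusive categories (increasing / decreasing / late /
  early / switching; thresholds 0.47/0.53, dead zone 0.03) with
  everything else unspecified. Here increasing/decreasing refer to the
  magnitude of imbalance along the trajectory.
- **Chromatin:** ChromHMM-style state codes 1..15 recode to active
  (<= 7) vs inactive; the start condition averages its epigenomes; the
  change score is the absolute activity difference. Association with
  D-ASE status is an OLS of change on the D-ASE indicator adjusting for
  total read depth.

## Limitations

- The LRT on a variational lower bound has no exact chi-square
  guarantee; calibration is empirical (and tested).
- The mixture has exactly two components; multiple eQTLs imply more,
  and the model is used as a working approximation (its power advantage
  under allelic heterogeneity is part of the benchmark).
- Effect sizes under haplotype switching are attenuated toward zero by
  homozygous-eQTL donors (above); reported `b1` should be read as a
  consensus-orientation effect, not an unbiased estimate of the
  generating coefficient.
- The GLMM SE conditions on estimated variance components; with few
  donors this understates uncertainty, as for any Wald test of this
  type.
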