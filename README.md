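# daesc

Differential allele-specific expression (ASE) analysis for single-cell
RNA-seq collected across many donors.

ASE compares the read counts of a gene's two alleles at heterozygous
transcribed SNPs; changes in allelic imbalance along a covariate —
pseudotime, cell type, disease status — expose context-specific
cis-regulation. Two features of multi-donor single-cell ASE defeat
naive per-cell tests: cells from the same donor are correlated, and the
unobserved regulatory allele can sit on either tSNP haplotype in
different donors ("haplotype switching"), so effects cancel when donors
are pooled. This package is for statistical geneticists and
single-cell analysts who have per-cell allele-specific counts and want
calibrated differential-ASE tests at the gene level.

## Models

For donor *i*, cell *j*: alternative-haplotype count `y_ij` out of
`n_ij` allele-specific reads, covariate `x_ij`.

**DAESC-BB** — beta-binomial regression with a donor random intercept:

    y_ij | n_ij ~ BB(n_ij, mu_ij, phi)
    logit(mu_ij) = beta0 + beta1 * x_ij + a_i,   a_i ~ N(0, sigma2_a)

**DAESC-Mix** — adds implicit haplotype phasing via a donor-level
latent orientation z_i = 2*delta_i − 1 ∈ {−1, +1},
delta_i ~ Bernoulli(pi0):

    logit(mu_ij) = z_i * (beta0 + beta1 * x_ij) + a_i

Both are fitted by a deterministic variational EM; H0: beta1 = 0 is
tested by a likelihood-ratio test on the converged variational
objective (chi-square, 1 df), with Benjamini–Hochberg FDR across genes.
A binomial GLMM reference method
(`logit p = beta0 + beta1 x + a_i + eps_ij`, Wald z-test) is included
for comparison, plus a full simulation engine and downstream utilities
(SNP-to-gene aggregation, QC filters, dynamic-ASE classification, exact
2x3 Fisher test, chromatin-state association). See `docs/methods.md`.

## Worked example

```python
import numpy as np
from daesc import DAESCBB, DAESCMix, lrt_pvalue
from daesc.simulate import SimScenario, simulate_one_eqtl, ParamDraw

# 24 donors, ~40 cells each, eQTL in linkage equilibrium with the tSNP
# (r2 = 0), so donor haplotype orientations are mixed
scenario = SimScenario(n_donors=24, cells_per_donor=(40, 2.0),
                       depth=(15, 0.8), r2=0.0, maf_eqtl=0.5,
                       maf_tsnp=0.5, seed=3)
gene = simulate_one_eqtl(scenario,
                         ParamDraw(beta0=1.0, beta1=-1.5,
                                   sigma2_a=0.3, phi=0.1),
                         np.random.default_rng(3), gene_id="GENE1")

model = DAESCMix(gene.data)
null_fit = model.fit_null()                  # beta1 constrained to 0
fit = model.fit(warm_from=null_fit)          # full model, nested start
print(fit.summary())
result = lrt_pvalue(fit, null_fit)
print(f"LRT stat={result.lrt_stat:.2f}  p={result.pvalue:.3g}")
print(f"baseline (no phasing) p={DAESCBB(gene.data).lr_test().pvalue:.3g}")
```

Output:

```
DAESC-MIX fit: gene GENE1
==========================================================
n donors                        24
beta0 (log-odds)            0.3453
beta1 (log-odds)           -0.7622
sigma2_a (donor var)        0.5357
phi (overdispersion)        0.1270
pi0 (mixture weight)        0.6833
ELBO                    -9904.6735
EM iterations                    9
converged                     True
==========================================================
LRT stat=31.77  p=1.74e-08
baseline (no phasing) p=0.0693
```

The mixture assigns every heterozygous-eQTL donor to its true haplotype
orientation (`fit.label`; posteriors in `fit.resp`) and detects the
dynamic allelic effect (p = 1.7e-8) that the baseline model, which
pools orientations, only hints at (p = 0.07).
`DAESCMix(gene.data).lr_test()` runs the same null-then-full sequence
in one call. The fitted `beta1` (-0.76) is attenuated relative to the
generating value (-1.5) because donors with a homozygous eQTL (z = 0,
the majority at r2 = 0) carry no allelic signal.

## Command line

```sh
daesc simulate --scenario scenario.cfg --out sim/ --seed 1
daesc fit      --input sim/counts.tsv --method mix --out fits/
daesc benchmark --grid scenario.cfg --methods bb,mix,glmm --out bench/
daesc classify --results fits/results.tsv --t-start 0.07 --t-end 0.86 \
               --out classes/
```

All tables are plain TSV; every run writes a `provenance.json` (config
echo + seed + version) and reruns are byte-identical.

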