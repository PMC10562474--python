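"""Generative models for benchmarking differential-ASE methods.

The central generator draws allele-specific counts for one gene under a
beta-binomial mixture in which a per-donor latent variable z_i in
{-1, +1, 0} encodes the phase relation between an unobserved regulatory
variant (eQTL) and the transcribed SNP at which reads are counted:
z = +1 / -1 are the two heterozygous-eQTL orientations and z = 0 is a
homozygous eQTL (no allelic imbalance). The three probabilities follow
from two-locus haplotype frequencies at a given LD coefficient r^2.

Counts: y_ij | n_ij ~ BB(n_ij, mu_ij, phi) with
logit(mu_ij) = z_i (b0 + b1 x_ij + b1 eta_i) + a_i, a_i ~ N(0, sigma2_a),
where x is a continuous cell state in [0, 1] and eta a donor-level binary
condition (half cases, half controls). A binomial-GLMM variant replaces
the beta overdispersion by a cell-level Gaussian effect, and a
multi-eQTL variant builds donor-specific effective coefficients from
independently drawn eQTL haplotype alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import GeneASECounts

TRUTH_COLUMNS = ["gene", "donor", "z_true", "beta1_true", "is_null"]

# Default parameter ranges standing in for an empirical strong-effect
# parameter library (log-odds scale; phi is beta-binomial overdispersion).
DEFAULT_RANGES = {
    "beta0": (-1.5, 1.5),
    "abs_beta1": (0.5, 2.5),
    "sigma2_a": (0.1, 1.0),
    "phi": (0.02, 0.5),
}


# --------------------------------------------------------------------------
# LD-derived mixture proportions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeMixtureProbs:
    """P(z = -1), P(z = +1), P(z = 0) for a donor heterozygous at the tSNP."""
    pi1: float
    pi2: float
    pi3: float

    def __post_init__(self):
        total = self.pi1 + self.pi2 + self.pi3
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi1, self.pi2, self.pi3])


def haplotype_mixture_probs(maf_eqtl: float, maf_tsnp: float,
                            r2: float) -> HaplotypeMixtureProbs:
    """Mixture proportions of the eQTL configurations given tSNP heterozygosity.

    Builds the four two-locus haplotype frequencies from the allele
    frequencies and D = +sqrt(r2 pA(1-pA) pB(1-pB)) (positive LD sign by
    convention), then conditions on the donor carrying one alternative-
    and one reference-tSNP haplotype:

    - pi2 (z = +1): alt-tSNP haplotype carries the eQTL alternative allele
      and the ref-tSNP haplotype carries the eQTL reference allele;
    - pi1 (z = -1): the reverse configuration;
    - pi3 (z = 0): the eQTL is homozygous.
    """
    pA, pB = float(maf_eqtl), float(maf_tsnp)
    for name, p in (("maf_eqtl", pA), ("maf_tsnp", pB)):
        if not (0.0 < p <= 0.5):
            raise ValueError(f"{name} must be in (0, 0.5], got {p}")
    if not (0.0 <= r2 <= 1.0):
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    D = np.sqrt(r2 * pA * (1 - pA) * pB * (1 - pB))
    h11 = pA * pB + D          # eQTL-alt, tSNP-alt
    h10 = pA * (1 - pB) - D    # eQTL-alt, tSNP-ref
    h01 = (1 - pA) * pB - D    # eQTL-ref, tSNP-alt
    h00 = (1 - pA) * (1 - pB) + D
    for name, h in (("h10 = pA(1-pB) - D", h10), ("h01 = (1-pA)pB - D", h01)):
        if h < -1e-12:
            raise ValueError(
                f"inadmissible (maf, r2): haplotype frequency {name} < 0")
    h10, h01 = max(h10, 0.0), max(h01, 0.0)
    # condition on one alt-tSNP haplotype (freq pB) and one ref (1 - pB)
    p_alt_on_alt = h11 / pB        # P(eQTL alt | tSNP-alt haplotype)
    p_alt_on_ref = h10 / (1 - pB)  # P(eQTL alt | tSNP-ref haplotype)
    pi2 = p_alt_on_alt * (1 - p_alt_on_ref)
    pi1 = (1 - p_alt_on_alt) * p_alt_on_ref
    pi3 = p_alt_on_alt * p_alt_on_ref \
        + (1 - p_alt_on_alt) * (1 - p_alt_on_ref)
    pis = np.clip([pi1, pi2, pi3], 0.0, 1.0)
    pis = pis / pis.sum()
    return HaplotypeMixtureProbs(pi1=float(pis[0]), pi2=float(pis[1]),
                                 pi3=float(pis[2]))


# --------------------------------------------------------------------------
# Scenario and parameter draws
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDraw:
    """One generative parameter set (log-odds coefficients + variances)."""
    beta0: float
    beta1: float
    sigma2_a: float
    phi: float

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.sigma2_a < 0:
            raise ValueError("sigma2_a must be >= 0")


@dataclass(frozen=True)
class SimScenario:
    """Study design for one simulation scenario.

    ``cells_per_donor`` and ``depth`` are (mean, dispersion) pairs of a
    zero-truncated negative binomial, or ``cells_per_donor`` may be an
    explicit per-donor tuple. Defaults mirror a large multi-donor
    single-cell experiment (about 290 cells per donor at mean
    allele-specific depth 15); benchmarks typically scale cells down.
    """
    n_donors: int = 50
    cells_per_donor: tuple = (290.0, 2.0)
    depth: tuple = (15.0, 0.8)
    covariate: str = "continuous"          # or "binary"
    r2: float = 0.0
    maf_eqtl: float = 0.2
    maf_tsnp: float = 0.2
    m_eqtls: int = 1
    eta_effect: bool = True
    n_null: int = 0
    n_alt: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.covariate not in ("continuous", "binary"):
            raise ValueError("covariate must be 'continuous' or 'binary'")
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if self.n_donors % 2:
            # half cases / half controls is part of the design
            raise ValueError("n_donors must be even (N/2 cases, N/2 controls)")
        if self.m_eqtls < 1:
            raise ValueError("m_eqtls must be >= 1")
        # validate LD admissibility eagerly for the one-eQTL design
        if self.m_eqtls == 1:
            haplotype_mixture_probs(self.maf_eqtl, self.maf_tsnp, self.r2)

    def mixture_probs(self) -> HaplotypeMixtureProbs:
        return haplotype_mixture_probs(self.maf_eqtl, self.maf_tsnp, self.r2)


@dataclass
class SimulatedGene:
    """Simulated counts plus the generating ground truth."""
    data: GeneASECounts
    z_true: np.ndarray
    beta1_true: float
    is_null: bool
    eta: np.ndarray | None = None
    params: ParamDraw | None = None
    g0: np.ndarray | None = None           # multi-eQTL ref-haplotype alleles
    g1: np.ndarray | None = None           # multi-eQTL alt-haplotype alleles
    beta_ase0: np.ndarray | None = None
    beta_ase1: np.ndarray | None = None
    beta_k0: np.ndarray | None = None      # per-eQTL coefficient draws
    beta_k1: np.ndarray | None = None

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.data.gene_id,
            "donor": self.data.donors,
            "z_true": self.z_true,
            "beta1_true": self.beta1_true,
            "is_null": self.is_null,
        })


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def draw_params(library: pd.DataFrame | None, rng, *,
                null: bool = False) -> ParamDraw:
    """Draw one generative parameter set.

    With a library table (columns ``beta0, beta1, sigma2_a, phi``) one row
    is chosen uniformly; otherwise parameters come from the documented
    default ranges (beta0 ~ U[-1.5, 1.5], |beta1| ~ U[0.5, 2.5] with
    random sign, sigma2_a ~ U[0.1, 1], phi ~ U[0.02, 0.5]). For null
    genes beta1 is reset to 0 after the draw.
    """
    rng = _as_rng(rng)
    if library is not None:
        need = ["beta0", "beta1", "sigma2_a", "phi"]
        missing = [c for c in need if c not in library.columns]
        if missing:
            raise ValueError(f"parameter library missing columns {missing}")
        if len(library) == 0:
            raise ValueError("parameter library is empty")
        row = library.iloc[int(rng.integers(len(library)))]
        draw = ParamDraw(beta0=float(row["beta0"]), beta1=float(row["beta1"]),
                         sigma2_a=float(row["sigma2_a"]),
                         phi=float(row["phi"]))
    else:
        lo, hi = DEFAULT_RANGES["beta0"]
        beta0 = rng.uniform(lo, hi)
        lo, hi = DEFAULT_RANGES["abs_beta1"]
        beta1 = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        lo, hi = DEFAULT_RANGES["sigma2_a"]
        s2 = rng.uniform(lo, hi)
        lo, hi = DEFAULT_RANGES["phi"]
        phi = rng.uniform(lo, hi)
        draw = ParamDraw(beta0=float(beta0), beta1=float(beta1),
                         sigma2_a=float(s2), phi=float(phi))
    if null:
        draw = replace(draw, beta1=0.0)
    return draw


# --------------------------------------------------------------------------
# Count scaffolding
# --------------------------------------------------------------------------

def _ztnb(mean: float, dispersion: float, size: int,
          rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated negative binomial draws with the *truncated* mean
    calibrated to ``mean`` (the underlying NB mean is solved by fixed
    point so that discarding zeros does not inflate the target)."""
    if mean <= 1 or dispersion <= 0:
        raise ValueError("mean must be > 1 and dispersion > 0")
    k = dispersion
    m_raw = mean
    for _ in range(60):  # m_trunc = m_raw / (1 - P0(m_raw))
        p0 = (k / (k + m_raw)) ** k
        new = mean * (1.0 - p0)
        if abs(new - m_raw) < 1e-10:
            break
        m_raw = new
    p = k / (k + m_raw)
    out = rng.negative_binomial(k, p, size=size)
    while np.any(out == 0):
        zero = out == 0
        out[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))
    return out.astype(np.int64)


def generate_totals(scenario: SimScenario, rng=None):
    """Per-cell total allele-specific counts and donor index.

    Returns (totals, donor_index) where cell counts per donor come from
    the scenario's cells-per-donor spec and totals from its depth spec;
    all totals are >= 1 and reproducible under a fixed seed.
    """
    rng = _as_rng(scenario.seed if rng is None else rng)
    cpd = scenario.cells_per_donor
    if np.isscalar(cpd[0]) and len(cpd) == 2 and not isinstance(cpd[0], (list, tuple)):
        counts = _ztnb(float(cpd[0]), float(cpd[1]), scenario.n_donors, rng)
    else:
        counts = np.asarray(cpd, dtype=np.int64)
        if len(counts) != scenario.n_donors:
            raise ValueError("explicit cell counts must have length n_donors")
    donor_index = np.repeat(np.arange(scenario.n_donors), counts)
    totals = _ztnb(float(scenario.depth[0]), float(scenario.depth[1]),
                   int(counts.sum()), rng)
    return totals, donor_index


def _covariates(scenario: SimScenario, donor_index, rng):
    """Continuous per-cell state x and binary donor condition eta."""
    n_cells = len(donor_index)
    x = rng.uniform(0.0, 1.0, size=n_cells)
    half = scenario.n_donors // 2
    eta = np.zeros(scenario.n_donors)
    cases = rng.choice(scenario.n_donors, size=half, replace=False)
    eta[cases] = 1.0
    return x, eta


def _finish_gene(gene_id, scenario, donor_index, totals, x, eta, mu, phi,
                 rng, z, beta1_true, is_null, params, **extra):
    if phi > 0:
        p = rng.beta(mu / phi, (1.0 - mu) / phi)
    else:
        p = mu
    y = rng.binomial(totals, p)
    analysis_x = x if scenario.covariate == "continuous" else eta[donor_index]
    donors = np.array([f"donor{i}" for i in range(scenario.n_donors)])
    data = GeneASECounts(gene_id=gene_id, donor_id=donors[donor_index],
                         y=y, n=totals, x=analysis_x)
    return SimulatedGene(data=data, z_true=z, beta1_true=beta1_true,
                         is_null=is_null, eta=eta, params=params, **extra)


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def simulate_one_eqtl(scenario: SimScenario, params: ParamDraw, rng=None,
                      gene_id: str = "gene", *,
                      z: np.ndarray | None = None) -> SimulatedGene:
    """One-eQTL beta-binomial mixture generator.

    z_i ~ categorical([-1, +1, 0], [pi1, pi2, pi3]) from the LD-derived
    proportions; logit(mu_ij) = z_i (b0 + b1 x_ij + b1 eta_i) + a_i, and
    donors with a homozygous eQTL (z = 0) show only their random
    intercept. Pass an explicit ``z`` vector to fix the haplotype
    configuration (e.g. half +1 / half -1 for recovery studies).
    """
    if scenario.m_eqtls != 1:
        raise ValueError("simulate_one_eqtl requires m_eqtls = 1")
    rng = _as_rng(scenario.seed if rng is None else rng)
    probs = scenario.mixture_probs().as_array()
    N = scenario.n_donors
    if z is None:
        z = rng.choice(np.array([-1, 1, 0]), size=N, p=probs)
    else:
        z = np.asarray(z, dtype=int)
        if len(z) != N or not np.isin(z, [-1, 0, 1]).all():
            raise ValueError("z must be length N with values in {-1, 0, 1}")
    a = rng.normal(0.0, np.sqrt(params.sigma2_a), size=N)
    totals, donor_index = generate_totals(scenario, rng)
    x, eta = _covariates(scenario, donor_index, rng)
    eta_term = eta[donor_index] if scenario.eta_effect else 0.0
    lin = (params.beta0 + params.beta1 * x + params.beta1 * eta_term)
    logit_mu = z[donor_index] * lin + a[donor_index]
    mu = np.clip(1.0 / (1.0 + np.exp(-logit_mu)), 1e-9, 1 - 1e-9)
    return _finish_gene(gene_id, scenario, donor_index, totals, x, eta, mu,
                        params.phi, rng, z, params.beta1,
                        params.beta1 == 0.0, params)


def simulate_glmm_gene(scenario: SimScenario, params: ParamDraw, rng=None,
                       gene_id: str = "gene") -> SimulatedGene:
    """Binomial-GLMM generator: overdispersion from a cell-level
    Gaussian effect eps_ij ~ N(0, 1) instead of the beta distribution."""
    if scenario.m_eqtls != 1:
        raise ValueError("simulate_glmm_gene requires m_eqtls = 1")
    rng = _as_rng(scenario.seed if rng is None else rng)
    probs = scenario.mixture_probs().as_array()
    N = scenario.n_donors
    z = rng.choice(np.array([-1, 1, 0]), size=N, p=probs)
    a = rng.normal(0.0, np.sqrt(params.sigma2_a), size=N)
    totals, donor_index = generate_totals(scenario, rng)
    x, eta = _covariates(scenario, donor_index, rng)
    eps = rng.normal(0.0, 1.0, size=len(totals))
    eta_term = eta[donor_index] if scenario.eta_effect else 0.0
    lin = (params.beta0 + params.beta1 * x + params.beta1 * eta_term)
    logit_mu = z[donor_index] * lin + a[donor_index] + eps
    mu = np.clip(1.0 / (1.0 + np.exp(-logit_mu)), 1e-9, 1 - 1e-9)
    return _finish_gene(gene_id, scenario, donor_index, totals, x, eta, mu,
                        0.0, rng, z, params.beta1, params.beta1 == 0.0,
                        params)


def simulate_multi_eqtl(scenario: SimScenario,
                        library: pd.DataFrame | None = None, rng=None,
                        gene_id: str = "gene", *,
                        null: bool = False) -> SimulatedGene:
    """Multi-eQTL generator with mutually independent eQTLs.

    Steps: draw (sigma2_a, phi) once; MAF_k ~ U[0.1, 0.5] for each of the
    m eQTLs; haplotype alleles g_ik0, g_ik1 ~ Bernoulli(MAF_k) for the
    reference- and alternative-tSNP haplotypes; m coefficient pairs
    (b_k0, b_k1); donor-specific effective coefficients
    bASE_i0 = sum_k b_k0 (g_ik1 - g_ik0) and likewise bASE_i1; then
    logit(mu_ij) = bASE_i0 + bASE_i1 x_ij + bASE_i1 eta_i + a_i with
    beta-binomial counts. Null genes have every b_k1 = 0.
    """
    if scenario.m_eqtls < 2:
        raise ValueError("simulate_multi_eqtl requires m_eqtls >= 2")
    rng = _as_rng(scenario.seed if rng is None else rng)
    m, N = scenario.m_eqtls, scenario.n_donors
    base = draw_params(library, rng)
    sigma2_a, phi = base.sigma2_a, base.phi
    mafs = rng.uniform(0.1, 0.5, size=m)
    g0 = rng.binomial(1, mafs[None, :], size=(N, m))
    g1 = rng.binomial(1, mafs[None, :], size=(N, m))
    pairs = [draw_params(library, rng, null=null) for _ in range(m)]
    bk0 = np.array([p.beta0 for p in pairs])
    bk1 = np.array([p.beta1 for p in pairs])
    diff = g1 - g0
    beta_ase0 = diff @ bk0
    beta_ase1 = diff @ bk1
    a = rng.normal(0.0, np.sqrt(sigma2_a), size=N)
    totals, donor_index = generate_totals(scenario, rng)
    x, eta = _covariates(scenario, donor_index, rng)
    logit_mu = (beta_ase0[donor_index] + beta_ase1[donor_index] * x
                + beta_ase1[donor_index] * eta[donor_index]
                + a[donor_index])
    mu = np.clip(1.0 / (1.0 + np.exp(-logit_mu)), 1e-9, 1 - 1e-9)
    # sign of the dominant orientation; donors with no net effect are z = 0
    z = np.sign(beta_ase1).astype(int) if not null \
        else np.sign(beta_ase0).astype(int)
    gene = _finish_gene(gene_id, scenario, donor_index, totals, x, eta, mu,
                        phi, rng, z, float(np.mean(np.abs(beta_ase1))),
                        bool(np.all(beta_ase1 == 0)), base,
                        g0=g0, g1=g1, beta_ase0=beta_ase0,
                        beta_ase1=beta_ase1, beta_k0=bk0, beta_k1=bk1)
    return gene


def simulate_dataset(scenario: SimScenario,
                     library: pd.DataFrame | None = None,
                     generator: str = "betabin"):
    """Generate ``n_null`` + ``n_alt`` genes under one scenario.

    Returns (counts frame, truth frame, genes list). The counts frame is
    the long-format analysis input; the truth frame records per-donor
    z_true, beta1_true and the null flag.
    """
    rng = np.random.default_rng(scenario.seed)
    gen = {"betabin": simulate_one_eqtl, "glmm": simulate_glmm_gene,
           "multi": simulate_multi_eqtl}.get(generator)
    if gen is None:
        raise ValueError(f"unknown generator {generator!r}")
    genes, counts, truths = [], [], []
    spec = ([(True, i) for i in range(scenario.n_null)]
            + [(False, i) for i in range(scenario.n_alt)])
    for is_null, i in spec:
        gid = f"{'null' if is_null else 'alt'}{i:04d}"
        if generator == "multi":
            g = simulate_multi_eqtl(scenario, library, rng, gene_id=gid,
                                    null=is_null)
        else:
            params = draw_params(library, rng, null=is_null)
            g = gen(scenario, params, rng, gene_id=gid)
        genes.append(g)
        counts.append(g.data.to_dataframe())
        truths.append(g.truth_frame())
    return (pd.concat(counts, ignore_index=True),
            pd.concat(truths, ignore_index=True), genes)


def load_scenario(path) -> SimScenario:
    """Parse a flat key=value scenario config (keys = SimScenario fields).

    Pair-valued fields (``cells_per_donor``, ``depth``) are written as
    comma-separated numbers; blank lines and ``#`` comments are ignored.
    """
    values: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed scenario line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
    known = set(SimScenario.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, val in values.items():
        if key in ("cells_per_donor", "depth"):
            kwargs[key] = tuple(float(v) for v in val.split(","))
        elif key == "covariate":
            kwargs[key] = val
        elif key in ("n_donors", "m_eqtls", "n_null", "n_alt", "seed"):
            kwargs[key] = int(val)
        else:
            kwargs[key] = float(val)
    return SimScenario(**kwargs)


def scenario_grid(r2_values=(0.0, 0.1, 0.9), n_values=(10, 50, 100),
                  **common) -> list[SimScenario]:
    """The benchmark grid: r^2 in {0, 0.1, 0.9} x N in {10, 50, 100}."""
    return [SimScenario(n_donors=n, r2=r2, **common)
            for r2 in r2_values for n in n_values]
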