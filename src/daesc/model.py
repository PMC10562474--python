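"""Beta-binomial mixed models for differential allele-specific expression.

Two statsmodels-style model classes are provided:

``DAESCBB``
    Beta-binomial regression with a donor-level random intercept:
    y_ij | n_ij ~ BB(n_ij, mu_ij, phi), logit(mu_ij) = b0 + b1 x_ij + a_i,
    a_i ~ N(0, sigma2_a). The random effect absorbs the non-independence of
    cells from the same donor.

``DAESCMix``
    The latent-haplotype mixture extension. A donor-level indicator
    z_i = 2*delta_i - 1 in {-1, +1}, delta_i ~ Bernoulli(pi0), multiplies
    the fixed-effect predictor: logit(mu_ij) = z_i (b0 + b1 x_ij) + a_i.
    This performs implicit phasing: donors whose expression-increasing
    regulatory allele sits on the opposite tSNP haplotype contribute with
    flipped sign instead of cancelling the pooled signal.

Both are fitted by a variational EM algorithm. The variational family is
mean-field: q(a_i) Gaussian, q(delta_i) Bernoulli. Expectations of the
beta-binomial log-likelihood under q(a_i) are approximated by a
second-order Taylor expansion around the posterior mean (delta-method
form), which makes every step closed-form or a smooth low-dimensional
optimization. Differential ASE (H0: b1 = 0) is tested by a likelihood
ratio test on the converged variational objective.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .betabin import (bb_loglik_eta, bb_taylor_obj_grad, fit_betabin_fixed,
                      phi_method_of_moments)
from .data import GeneASECounts

logger = logging.getLogger(__name__)

ELBO_SLACK = 1e-8  # permitted numerical backsliding of the objective
_PI0_EPS = 1e-6


# --------------------------------------------------------------------------
# Results containers
# --------------------------------------------------------------------------

@dataclass
class BBResults:
    """Converged DAESC-BB fit: parameters and per-donor posteriors."""
    gene_id: str
    beta0: float
    beta1: float
    sigma2_a: float
    phi: float
    a_hat: np.ndarray
    a_var: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int
    donors: np.ndarray
    null: bool = False
    boundary: bool = False
    data_fingerprint: str = ""
    method: str = "daesc-bb"

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])

    # alias used by the LRT machinery
    @property
    def objective(self) -> float:
        return self.elbo

    def summary(self) -> str:
        lines = [
            f"{self.method.upper()} fit: gene {self.gene_id}"
            + ("  [null model, b1 = 0]" if self.null else ""),
            "=" * 58,
            f"{'n donors':<22}{len(self.donors):>12}",
            f"{'beta0 (log-odds)':<22}{self.beta0:>12.4f}",
            f"{'beta1 (log-odds)':<22}{self.beta1:>12.4f}",
            f"{'sigma2_a (donor var)':<22}{self.sigma2_a:>12.4f}",
            f"{'phi (overdispersion)':<22}{self.phi:>12.4f}",
        ]
        lines += self._extra_summary_lines()
        lines += [
            f"{'ELBO':<22}{self.elbo:>12.4f}",
            f"{'EM iterations':<22}{self.n_iter:>12}",
            f"{'converged':<22}{str(self.converged):>12}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def _extra_summary_lines(self):
        return []

    def posterior_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene_id,
            "donor": self.donors,
            "a_hat": self.a_hat,
            "a_var": self.a_var,
        })


@dataclass
class MixResults(BBResults):
    """Converged DAESC-Mix fit; adds mixture weight and responsibilities."""
    pi0: float = 0.5
    resp: np.ndarray = field(default_factory=lambda: np.empty(0))
    method: str = "daesc-mix"

    @property
    def label(self) -> np.ndarray:
        """Hard haplotype-orientation assignment z_i in {-1, +1}."""
        return np.where(self.resp > 0.5, 1, -1)

    def _extra_summary_lines(self):
        return [f"{'pi0 (mixture weight)':<22}{self.pi0:>12.4f}"]

    def posterior_frame(self) -> pd.DataFrame:
        df = super().posterior_frame()
        df["resp"] = self.resp
        return df


@dataclass
class DASETestResult:
    """Per-gene differential-ASE test: LRT (or Wald) summary row."""
    gene_id: str
    method: str
    beta0: float = np.nan
    beta1: float = np.nan
    sigma2_a: float = np.nan
    phi: float = np.nan
    pi0: float = np.nan
    loglik_full: float = np.nan
    loglik_null: float = np.nan
    lrt_stat: float = np.nan
    df: int = 1
    pvalue: float = np.nan
    qvalue: float = np.nan
    converged: bool = False
    n_donors: int = 0
    n_cells: int = 0
    reason: str = ""

    def to_row(self) -> dict:
        return {
            "gene": self.gene_id, "method": self.method,
            "beta0": self.beta0, "beta1": self.beta1,
            "sigma2_a": self.sigma2_a, "phi": self.phi, "pi0": self.pi0,
            "lrt_stat": self.lrt_stat, "pvalue": self.pvalue,
            "qvalue": self.qvalue, "converged": self.converged,
            "n_donors": self.n_donors, "n_cells": self.n_cells,
            "reason": self.reason,
        }


# --------------------------------------------------------------------------
# Variational EM core (shared between BB and Mix)
# --------------------------------------------------------------------------

def _fingerprint(data: GeneASECounts) -> str:
    h = hashlib.sha1()
    h.update(str(data.gene_id).encode())
    h.update(np.ascontiguousarray(data.y).tobytes())
    h.update(np.ascontiguousarray(data.n).tobytes())
    h.update(np.ascontiguousarray(data.x).tobytes())
    return h.hexdigest()[:16]


class _VariationalEM:
    """Shared EM engine. ``mixture`` switches DAESC-Mix behaviour on;
    ``null`` constrains beta1 = 0."""

    def __init__(self, data: GeneASECounts, mixture: bool, null: bool,
                 allow_single_donor: bool = False):
        if data.n_donors < 2 and not allow_single_donor:
            raise ValueError("need >= 2 donors")
        if not null and len(np.unique(data.x)) < 2:
            raise ValueError("need >= 2 distinct covariate values")
        self.data = data
        self.mixture = mixture
        self.null = null
        self.y = data.y.astype(float)
        self.n = data.n.astype(float)
        self.x = data.x
        self.d = data.donor_index
        self.N = data.n_donors
        self.boundary = bool(np.all(data.y == 0) or np.all(data.y == data.n))
        if self.boundary:
            logger.warning("%s: all counts at one boundary; estimates may "
                           "sit at the parameter bound", data.gene_id)

    # ---- linear predictors -------------------------------------------------
    def _etas(self, beta0, beta1, a_cell):
        """Per-cell linear predictors for the (two) mixture components."""
        lin = beta0 + beta1 * self.x
        if self.mixture:
            return lin + a_cell, -lin + a_cell
        return (lin + a_cell,)

    # ---- E-step: q(a_i) ----------------------------------------------------
    def _update_a(self, a, s2, w1, beta0, beta1, phi, sigma2_a):
        """Vectorized damped Newton ascent of the responsibility-weighted
        expected complete-data log-likelihood in a_i, then Laplace variance.
        Candidates that would lower a donor's objective contribution are
        rejected (keeps the trace monotone)."""
        w1d = w1
        w2d = 1.0 - w1 if self.mixture else None
        floor = -0.5 / sigma2_a  # posterior never much flatter than prior
        a_new = a.copy()
        for _ in range(40):
            g, h = self._a_grad_hess(a_new, w1d, w2d, beta0, beta1, phi,
                                     sigma2_a)
            step = -g / np.minimum(h, floor)
            np.clip(step, -2.0, 2.0, out=step)
            a_new = np.clip(a_new + step, -30.0, 30.0)
            if np.max(np.abs(step)) < 1e-9:
                break
        _, h = self._a_grad_hess(a_new, w1d, w2d, beta0, beta1, phi, sigma2_a)
        s2_new = -1.0 / np.minimum(h, floor)

        e_old = self._per_donor_elbo(a, s2, w1d, w2d, beta0, beta1, phi,
                                     sigma2_a)
        e_new = self._per_donor_elbo(a_new, s2_new, w1d, w2d, beta0, beta1,
                                     phi, sigma2_a)
        keep = e_new >= e_old - ELBO_SLACK
        return np.where(keep, a_new, a), np.where(keep, s2_new, s2)

    def _a_grad_hess(self, a, w1, w2, beta0, beta1, phi, sigma2_a):
        a_cell = a[self.d]
        etas = self._etas(beta0, beta1, a_cell)
        if self.mixture:
            C = len(self.y)
            _, d1, d2 = bb_loglik_eta(np.concatenate([self.y, self.y]),
                                      np.concatenate([self.n, self.n]),
                                      np.concatenate(etas), phi)
            w1c, w2c = w1[self.d], w2[self.d]
            g_cell = w1c * d1[:C] + w2c * d1[C:]
            h_cell = w1c * d2[:C] + w2c * d2[C:]
        else:
            _, g_cell, h_cell = bb_loglik_eta(self.y, self.n, etas[0], phi)
        g = np.bincount(self.d, weights=g_cell, minlength=self.N)
        h = np.bincount(self.d, weights=h_cell, minlength=self.N)
        return g - a / sigma2_a, h - 1.0 / sigma2_a

    # ---- expected data log-likelihood per donor ---------------------------
    def _expected_ll(self, a, s2, beta0, beta1, phi):
        """E_q[log BB] per donor per component, Taylor order 2 around a_hat.
        Returns list of per-donor arrays (one per component)."""
        a_cell, s2_cell = a[self.d], s2[self.d]
        etas = self._etas(beta0, beta1, a_cell)
        if self.mixture:
            C = len(self.y)
            ll, _, d2 = bb_loglik_eta(np.concatenate([self.y, self.y]),
                                      np.concatenate([self.n, self.n]),
                                      np.concatenate(etas), phi)
            cells = [ll[:C] + 0.5 * s2_cell * d2[:C],
                     ll[C:] + 0.5 * s2_cell * d2[C:]]
        else:
            ll, _, d2 = bb_loglik_eta(self.y, self.n, etas[0], phi)
            cells = [ll + 0.5 * s2_cell * d2]
        return [np.bincount(self.d, weights=c, minlength=self.N)
                for c in cells]

    def _per_donor_elbo(self, a, s2, w1, w2, beta0, beta1, phi, sigma2_a):
        comp = self._expected_ll(a, s2, beta0, beta1, phi)
        if self.mixture:
            e = w1 * comp[0] + w2 * comp[1]
        else:
            e = comp[0]
        e = e - (a ** 2 + s2) / (2.0 * sigma2_a) + 0.5 * np.log(s2)
        return e

    # ---- M-step: sigma2_a with variance-only E-step sweeps -----------------
    def _update_sigma2_a(self, a, s2, w1, beta0, beta1, phi, sigma2_a):
        """Closed-form sigma2_a update, iterated jointly with the q(a)
        variance at fixed a_hat. Plain EM creeps toward a zero variance
        boundary extremely slowly; alternating the two exact coordinate
        updates (s2 given sigma2_a, sigma2_a given s2) to their fixed
        point is still coordinate ascent on the variational objective but
        converges in a handful of arithmetic-only iterations."""
        w2 = (1.0 - w1) if self.mixture else None
        _, h_tot = self._a_grad_hess(a, w1, w2, beta0, beta1, phi, sigma2_a)
        h_data = h_tot + 1.0 / sigma2_a  # data-only curvature at a_hat
        for _ in range(50):
            new = float(max(np.mean(a ** 2 + s2), 1e-8))
            s2 = -1.0 / np.minimum(h_data - 1.0 / new, -0.5 / new)
            if abs(new - sigma2_a) < 1e-10 * (sigma2_a + 1e-10):
                sigma2_a = new
                break
            sigma2_a = new
        return sigma2_a, s2

    # ---- E-step: q(delta_i) ------------------------------------------------
    def _update_resp(self, a, s2, beta0, beta1, phi, pi0):
        c1, c2 = self._expected_ll(a, s2, beta0, beta1, phi)
        logodds = special.logit(pi0) + c1 - c2
        return np.clip(special.expit(logodds), _PI0_EPS, 1.0 - _PI0_EPS)

    # ---- full variational objective ---------------------------------------
    def elbo(self, a, s2, w1, beta0, beta1, phi, sigma2_a, pi0):
        comp = self._expected_ll(a, s2, beta0, beta1, phi)
        val = 0.0
        if self.mixture:
            w2 = 1.0 - w1
            val += float(np.sum(w1 * (comp[0] + np.log(pi0))
                                + w2 * (comp[1] + np.log(1.0 - pi0))))
            val += float(-np.sum(special.xlogy(w1, w1)
                                 + special.xlogy(w2, w2)))
        else:
            val += float(np.sum(comp[0]))
        val += float(np.sum(-(a ** 2 + s2) / (2.0 * sigma2_a)))
        val += -0.5 * self.N * math.log(2.0 * math.pi * sigma2_a)
        val += float(0.5 * np.sum(np.log(2.0 * math.pi * math.e * s2)))
        return val

    # ---- M-step: (beta, phi) ----------------------------------------------
    def _update_beta_phi(self, a, s2, w1, beta0, beta1, phi):
        a_cell, s2_cell = a[self.d], s2[self.d]
        if self.mixture:
            w1c = w1[self.d]
            w2c = 1.0 - w1c

        free_beta1 = not self.null

        if self.mixture:  # evaluate both components in one stacked call
            y2 = np.concatenate([self.y, self.y])
            n2 = np.concatenate([self.n, self.n])
            a2 = np.concatenate([a_cell, a_cell])
            s2_2 = np.concatenate([s2_cell, s2_cell])
            C = len(self.y)

        def neg_obj_grad(theta):
            if free_beta1:
                b0, b1, lphi = theta
            else:
                (b0, lphi), b1 = theta, 0.0
            ph = np.exp(lphi)
            lin = b0 + b1 * self.x
            if self.mixture:
                eta2 = np.concatenate([lin, -lin]) + a2
                o, g, p = bb_taylor_obj_grad(y2, n2, eta2, ph, s2_2)
                val = w1c * o[:C] + w2c * o[C:]
                geta = w1c * g[:C] - w2c * g[C:]  # comp 2: d eta/d b = -1
                gph = w1c * p[:C] + w2c * p[C:]
            else:
                val, geta, gph = bb_taylor_obj_grad(
                    self.y, self.n, lin + a_cell, ph, s2_cell)
            if free_beta1:
                grad = np.array([geta.sum(), (geta * self.x).sum(),
                                 gph.sum()])
            else:
                grad = np.array([geta.sum(), gph.sum()])
            return -float(val.sum()), -grad

        if free_beta1:
            x0 = np.array([beta0, beta1, np.log(phi)])
            bounds = [(-25, 25), (-25, 25), (-12, 5)]
        else:
            x0 = np.array([beta0, np.log(phi)])
            bounds = [(-25, 25), (-12, 5)]
        f0, _ = neg_obj_grad(x0)
        res = optimize.minimize(neg_obj_grad, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": 8})
        if res.fun <= f0 + ELBO_SLACK:
            if free_beta1:
                b0, b1, lphi = res.x
            else:
                (b0, lphi), b1 = res.x, 0.0
            return float(b0), float(b1), float(np.exp(lphi))
        return beta0, beta1, phi  # reject a non-improving step

    # ---- driver ------------------------------------------------------------
    def fit(self, tol: float = 1e-6, max_iter: int = 200, start=None,
            fix_sigma2_a: float | None = None):
        if start is None:
            start = self._initial_values()
        beta0, beta1, phi, sigma2_a, pi0, w1 = start
        if fix_sigma2_a is not None:
            sigma2_a = max(float(fix_sigma2_a), 1e-6)
        a = np.zeros(self.N)
        s2 = np.full(self.N, max(sigma2_a, 1e-2))
        trace = []
        converged = False
        for it in range(1, max_iter + 1):
            # E-step: one q(a) sweep, then one q(delta) sweep
            a, s2 = self._update_a(a, s2, w1, beta0, beta1, phi, sigma2_a)
            if self.mixture:
                w1 = self._update_resp(a, s2, beta0, beta1, phi, pi0)
            # M-step: closed-form pieces, then (beta, phi)
            if self.mixture:
                pi0 = float(np.clip(np.mean(w1), _PI0_EPS, 1.0 - _PI0_EPS))
            if fix_sigma2_a is None:
                sigma2_a, s2 = self._update_sigma2_a(a, s2, w1, beta0,
                                                     beta1, phi, sigma2_a)
            beta0, beta1, phi = self._update_beta_phi(a, s2, w1, beta0,
                                                      beta1, phi)
            trace.append(self.elbo(a, s2, w1, beta0, beta1, phi, sigma2_a,
                                   pi0))
            if len(trace) > 1:
                rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0)
                if rel < tol:
                    converged = True
                    break
        return dict(beta0=beta0, beta1=beta1, phi=phi, sigma2_a=sigma2_a,
                    pi0=pi0, resp=w1, a_hat=a, a_var=s2,
                    elbo_trace=np.asarray(trace), converged=converged,
                    n_iter=len(trace))

    # ---- deterministic initialization --------------------------------------
    def _fit_fixed(self, y):
        from types import SimpleNamespace
        try:
            fixed = fit_betabin_fixed(SimpleNamespace(y=y, n=self.n,
                                                      x=self.x))
            return fixed.beta0, fixed.beta1
        except Exception:
            p = float(np.clip((y.sum() + 0.5) / (self.n.sum() + 1.0),
                              1e-4, 1 - 1e-4))
            return float(special.logit(p)), 0.0

    def _initial_values(self):
        phi0 = phi_method_of_moments(self.data)
        b0f, b1f = self._fit_fixed(self.y)
        beta1 = 0.0 if self.null else b1f
        return b0f, beta1, phi0, 0.5, 1.0, np.ones(self.N)

    def _mix_start(self, sign_per_donor):
        """Start with responsibilities set by a per-donor sign heuristic and
        (beta0, beta1) from a fixed-effects refit of the sign-flipped counts."""
        resp = np.where(np.asarray(sign_per_donor) >= 0, 0.75, 0.25)
        flip = (resp < 0.5)[self.d]
        y_aligned = np.where(flip, self.n - self.y, self.y)
        b0, b1 = self._fit_fixed(y_aligned)
        beta1 = 0.0 if self.null else b1
        phi0 = phi_method_of_moments(self.data)
        return b0, beta1, phi0, 0.5, 0.5, resp

    def initial_starts(self):
        """Deterministic candidate starts.

        The mixture start splits donors by the sign of their pseudobulk
        log-odds deviation from balance and aligns (beta0, beta1) by a
        fixed-effects refit of the accordingly sign-flipped counts. Full
        and null fits share the policy, so the likelihood-ratio statistic
        is not an artifact of asymmetric initialization.
        """
        if not self.mixture:
            return [self._initial_values()]
        dev = special.logit(self.data.pseudobulk_fraction())
        return [self._mix_start(dev)]


# --------------------------------------------------------------------------
# Public model classes
# --------------------------------------------------------------------------

class DAESCBB:
    """Beta-binomial donor-random-effect model for one gene's ASE counts."""

    method = "daesc-bb"
    _mixture = False
    _results_cls = BBResults

    def __init__(self, data: GeneASECounts):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene_id: str | None = None):
        return cls(GeneASECounts.from_dataframe(df, gene_id))

    def fit(self, tol: float = 1e-6, max_iter: int = 200, *,
            null: bool = False, fix_sigma2_a: float | None = None,
            warm_from=None):
        """Run the variational EM. ``null=True`` constrains beta1 = 0;
        ``fix_sigma2_a`` pins the donor variance (0 recovers the
        fixed-effects model up to the variational approximation);
        ``warm_from`` adds a candidate start inheriting another fit's
        converged state — typically the null fit's, a nested warm start.

        The fit with the highest converged objective over the candidate
        starts is kept.
        """
        engine = _VariationalEM(self.data, mixture=self._mixture, null=null,
                                allow_single_donor=fix_sigma2_a is not None)
        starts = engine.initial_starts()
        if warm_from is not None:
            starts.append((warm_from.beta0,
                           0.0 if null else warm_from.beta1,
                           warm_from.phi, warm_from.sigma2_a,
                           getattr(warm_from, "pi0", 1.0),
                           getattr(warm_from, "resp", np.ones(engine.N))))
        best = None
        for start in starts:
            est = engine.fit(tol=tol, max_iter=max_iter, start=start,
                             fix_sigma2_a=fix_sigma2_a)
            if best is None or est["elbo_trace"][-1] > best["elbo_trace"][-1]:
                best = est
        return self._wrap(best, engine, null)

    def fit_null(self, tol: float = 1e-6, max_iter: int = 200):
        return self.fit(tol=tol, max_iter=max_iter, null=True)

    def _wrap(self, est, engine, null):
        return BBResults(
            gene_id=self.data.gene_id, beta0=est["beta0"], beta1=est["beta1"],
            sigma2_a=est["sigma2_a"], phi=est["phi"], a_hat=est["a_hat"],
            a_var=est["a_var"], elbo_trace=est["elbo_trace"],
            converged=est["converged"], n_iter=est["n_iter"],
            donors=self.data.donors, null=null, boundary=engine.boundary,
            data_fingerprint=_fingerprint(self.data))

    def lr_test(self, tol: float = 1e-6, max_iter: int = 200, *,
                return_fits: bool = False):
        """Fit full and beta1 = 0 models; chi-square(1) likelihood ratio.

        Fits are cross-warm-started: the null fit's state seeds an extra
        candidate start of the full fit, and the full fit's state seeds a
        re-polish of the null fit. This keeps the statistic non-negative
        and stops a better-searched full model from inflating the ratio
        with optimization gains the null model could reach too.
        """
        nullf = self.fit_null(tol=tol, max_iter=max_iter)
        full = self.fit(tol=tol, max_iter=max_iter, warm_from=nullf)
        if full.objective > nullf.objective:
            null2 = self.fit(tol=tol, max_iter=max_iter, null=True,
                             warm_from=full)
            if null2.objective > nullf.objective:
                nullf = null2
        result = lrt_pvalue(full, nullf)
        return (result, full, nullf) if return_fits else result


class DAESCMix(DAESCBB):
    """Latent-haplotype beta-binomial mixture model (implicit phasing).

    Recommended for reasonably large donor numbers (N >= 20); with fewer
    donors the mixture weight is weakly identified and a warning is issued.
    """

    method = "daesc-mix"
    _mixture = True
    _results_cls = MixResults

    def __init__(self, data: GeneASECounts):
        super().__init__(data)
        if data.n_donors < 20:
            warnings.warn(
                f"{data.gene_id}: DAESC-Mix fitted with N={data.n_donors} "
                "donors; the mixture is recommended for N >= 20",
                UserWarning, stacklevel=2)

    def _wrap(self, est, engine, null):
        beta0, beta1 = est["beta0"], est["beta1"]
        pi0, resp = est["pi0"], est["resp"]
        if pi0 < 0.5:  # component-swap identifiability: resolve sign
            beta0, beta1 = -beta0, -beta1
            pi0, resp = 1.0 - pi0, 1.0 - resp
        return MixResults(
            gene_id=self.data.gene_id, beta0=beta0, beta1=beta1,
            sigma2_a=est["sigma2_a"], phi=est["phi"], a_hat=est["a_hat"],
            a_var=est["a_var"], elbo_trace=est["elbo_trace"],
            converged=est["converged"], n_iter=est["n_iter"],
            donors=self.data.donors, null=null, boundary=engine.boundary,
            data_fingerprint=_fingerprint(self.data), pi0=pi0, resp=resp)


# --------------------------------------------------------------------------
# Likelihood-ratio testing, gene drivers, FDR
# --------------------------------------------------------------------------

def lrt_pvalue(fit_full: BBResults, fit_null: BBResults) -> DASETestResult:
    """Chi-square(1) LRT of H0: beta1 = 0 from full and null fits.

    The "likelihood" is the converged variational objective of each fit
    (an approximation; both fits share the initialization policy). The
    statistic is clipped at zero.
    """
    if fit_full.data_fingerprint != fit_null.data_fingerprint:
        raise ValueError("full and null fits were made on different data")
    if not fit_null.null:
        raise ValueError("fit_null must be a beta1 = 0 fit")
    stat = max(0.0, 2.0 * (fit_full.objective - fit_null.objective))
    pval = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return DASETestResult(
        gene_id=fit_full.gene_id, method=fit_full.method,
        beta0=fit_full.beta0, beta1=fit_full.beta1,
        sigma2_a=fit_full.sigma2_a, phi=fit_full.phi,
        pi0=getattr(fit_full, "pi0", np.nan),
        loglik_full=fit_full.objective, loglik_null=fit_null.objective,
        lrt_stat=stat, df=1, pvalue=pval,
        converged=fit_full.converged and fit_null.converged,
        n_donors=len(fit_full.donors), n_cells=0)


_MODELS = {"daesc-bb": DAESCBB, "daesc-mix": DAESCMix}


def test_gene(data: GeneASECounts, method: str = "daesc-bb",
              tol: float = 1e-6, max_iter: int = 200) -> DASETestResult:
    """Fit full and null models for one gene and LRT-test differential ASE.

    Failures (too few donors, constant covariate, numerical errors) yield
    a row with NA p-value and a reason code instead of raising, so that
    multi-gene runs are never aborted by one gene.
    """
    if method not in _MODELS:
        raise ValueError(f"unknown method {method!r}; use daesc-bb/daesc-mix")
    result = DASETestResult(gene_id=data.gene_id, method=method,
                            n_donors=data.n_donors, n_cells=data.n_cells)
    if data.n_donors < 2:
        result.reason = "too-few-donors"
        return result
    if len(np.unique(data.x)) < 2:
        result.reason = "constant-covariate"
        return result
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = _MODELS[method](data)
            res = model.lr_test(tol=tol, max_iter=max_iter)
        res.n_cells = data.n_cells
        return res
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("%s: fit failed (%s)", data.gene_id, exc)
        result.reason = "fit-error"
        return result


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values; NA propagated."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    q[ok] = out
    return q


def fit_gene_table(df: pd.DataFrame, method: str = "daesc-bb",
                   tol: float = 1e-6, max_iter: int = 200,
                   collect_posteriors: bool = False):
    """Test every gene in a long-format counts frame.

    Returns a results DataFrame (one row per gene, BH q-values filled) and,
    if requested, a per-donor posterior DataFrame.
    """
    from .data import iter_genes
    from .glmm import glmm_test

    rows, posteriors = [], []
    for gene_data in iter_genes(df):
        if method == "glmm":
            res = glmm_test(gene_data)
        else:
            res = test_gene(gene_data, method=method, tol=tol,
                            max_iter=max_iter)
        rows.append(res.to_row())
        if collect_posteriors and method in _MODELS:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    fit = _MODELS[method](gene_data).fit(tol=tol,
                                                         max_iter=max_iter)
                posteriors.append(fit.posterior_frame())
            except Exception:
                pass
        logger.debug("tested %s (%s): p=%s", gene_data.gene_id, method,
                     rows[-1]["pvalue"])
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    post = (pd.concat(posteriors, ignore_index=True)
            if posteriors else pd.DataFrame())
    return (out, post) if collect_posteriors else out
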