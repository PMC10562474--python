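"""Binomial GLMM reference method for differential ASE.

Model: y_ij | n_ij ~ Binomial(n_ij, p_ij),
logit(p_ij) = b0 + b1 x_ij + a_i + eps_ij, with a donor random intercept
a_i ~ N(0, sigma2_a) and an observation-level random effect
eps_ij ~ N(0, sigma2_eps) absorbing overdispersion (the classical
``(1|subj) + (1|obs)`` binomial mixed model).

Estimation integrates the cell-level effect by 15-point Gauss-Hermite
quadrature and the donor effect by a Laplace/variational scheme: an
EM-style loop alternates a Gaussian approximation of each donor
posterior (Newton mode + curvature) with closed-form sigma2_a updates,
an analytic-gradient update of (b0, b1) and a bracketed 1-D update of
sigma2_eps. The Wald standard error of b1 conditions on the estimated
variance components (as lme4 does): it inverts the observed information
of the Laplace marginal likelihood in (b0, b1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data import GeneASECounts
from .model import DASETestResult

logger = logging.getLogger(__name__)

_GH_POINTS = 15


@dataclass
class GlmmFit:
    """Approximate-ML binomial GLMM fit with Wald test for beta1."""
    gene_id: str
    beta0: float
    beta1: float
    sigma2_a: float
    sigma2_eps: float
    se_beta1: float
    z_stat: float
    pvalue: float
    loglik: float
    converged: bool
    a_hat: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            f"GLMM fit: gene {self.gene_id}",
            "=" * 58,
            f"{'beta0':<22}{self.beta0:>12.4f}",
            f"{'beta1':<22}{self.beta1:>12.4f}",
            f"{'se(beta1)':<22}{self.se_beta1:>12.4f}",
            f"{'z':<22}{self.z_stat:>12.4f}",
            f"{'p (two-sided)':<22}{self.pvalue:>12.3e}",
            f"{'sigma2_a (donor)':<22}{self.sigma2_a:>12.4f}",
            f"{'sigma2_eps (cell)':<22}{self.sigma2_eps:>12.4f}",
            f"{'log-likelihood':<22}{self.loglik:>12.4f}",
            f"{'converged':<22}{str(self.converged):>12}",
            "=" * 58,
        ]
        return "\n".join(lines)


class _GlmmEngine:
    def __init__(self, data: GeneASECounts):
        self.y = data.y.astype(float)
        self.n = data.n.astype(float)
        self.x = data.x
        self.d = data.donor_index
        self.N = data.n_donors
        nodes, weights = np.polynomial.hermite.hermgauss(_GH_POINTS)
        self.nodes = nodes[None, :] * np.sqrt(2.0)       # (1, K)
        self.logw = np.log(weights / np.sqrt(np.pi))[None, :]
        self.const = float(np.sum(
            special.gammaln(self.n + 1) - special.gammaln(self.y + 1)
            - special.gammaln(self.n - self.y + 1)))

    # ---- per-cell GH-integrated log-likelihood and a-derivatives ----------
    def _cell_terms(self, a_cell, beta0, beta1, sig_eps, third=False):
        """log m_ij and d/da derivatives (up to 3rd) of the GH-integrated
        binomial likelihood; derivatives from posterior node moments."""
        eta = (beta0 + beta1 * self.x + a_cell)[:, None] \
            + sig_eps * self.nodes                        # (C, K)
        lp = special.log_expit(eta)
        lq = special.log_expit(-eta)
        L = self.logw + self.y[:, None] * lp + (self.n - self.y)[:, None] * lq
        M = L.max(axis=1)
        E = np.exp(L - M[:, None])
        S = E.sum(axis=1)
        m = M + np.log(S)
        om = E / S[:, None]
        p = np.exp(lp)
        r = self.y[:, None] - self.n[:, None] * p
        c = -self.n[:, None] * p * (1.0 - p)
        A1 = np.sum(om * r, axis=1)
        A2 = np.sum(om * (c + r * r), axis=1)
        d1 = A1
        d2 = A2 - A1 * A1
        if not third:
            return m, d1, d2
        l3 = c * (1.0 - 2.0 * p)
        A3 = np.sum(om * (l3 + 3.0 * c * r + r ** 3), axis=1)
        d3 = A3 - 3.0 * A1 * A2 + 2.0 * A1 ** 3
        return m, d1, d2, d3

    # ---- E-step: Gaussian approximation of donor posteriors ---------------
    def update_a(self, a, beta0, beta1, sig_eps, sigma2_a):
        # posterior curvature can never be flatter than ~the prior's
        floor = -0.5 / sigma2_a
        gv, g1, g2 = self._donor_terms(a, beta0, beta1, sig_eps, sigma2_a)
        for _ in range(50):
            step = -g1 / np.minimum(g2, floor)
            np.clip(step, -3.0, 3.0, out=step)
            for _ in range(4):
                a_new = np.clip(a + step, -30.0, 30.0)
                v_new, g1n, g2n = self._donor_terms(a_new, beta0, beta1,
                                                    sig_eps, sigma2_a)
                worse = v_new < gv - 1e-10
                if not worse.any():
                    break
                step = np.where(worse, 0.5 * step, step)
            accept = v_new >= gv - 1e-10
            moved = np.abs(np.where(accept, a_new - a, 0.0)).max()
            a = np.where(accept, a_new, a)
            gv = np.where(accept, v_new, gv)
            g1 = np.where(accept, g1n, g1)
            g2 = np.where(accept, g2n, g2)
            if moved < 1e-9:
                break
        s2 = -1.0 / np.minimum(g2, floor)
        return a, s2, gv, g2

    def _donor_terms(self, a, beta0, beta1, sig_eps, sigma2_a):
        m, d1, d2 = self._cell_terms(a[self.d], beta0, beta1, sig_eps)
        g = np.bincount(self.d, weights=m, minlength=self.N) \
            - a ** 2 / (2.0 * sigma2_a)
        g1 = np.bincount(self.d, weights=d1, minlength=self.N) \
            - a / sigma2_a
        g2 = np.bincount(self.d, weights=d2, minlength=self.N) \
            - 1.0 / sigma2_a
        return g, g1, g2

    # ---- M-step pieces -----------------------------------------------------
    def _beta_obj_grad(self, beta0, beta1, sig_eps, a, s2):
        a_cell, s2_cell = a[self.d], s2[self.d]
        m, d1, d2, d3 = self._cell_terms(a_cell, beta0, beta1, sig_eps,
                                         third=True)
        val = np.sum(m + 0.5 * s2_cell * d2)
        g = d1 + 0.5 * s2_cell * d3
        return -val, -np.array([g.sum(), (g * self.x).sum()])

    def update_beta(self, beta0, beta1, sig_eps, a, s2):
        res = optimize.minimize(
            lambda b: self._beta_obj_grad(b[0], b[1], sig_eps, a, s2),
            np.array([beta0, beta1]), jac=True, method="L-BFGS-B",
            bounds=[(-25, 25), (-25, 25)], options={"maxiter": 8})
        return float(res.x[0]), float(res.x[1])

    def update_sig_eps(self, beta0, beta1, sig_eps, a, s2):
        a_cell, s2_cell = a[self.d], s2[self.d]

        def neg(lse):
            m, _, d2 = self._cell_terms(a_cell, beta0, beta1,
                                        np.exp(lse))
            return -float(np.sum(m + 0.5 * s2_cell * d2))

        res = optimize.minimize_scalar(neg, bounds=(-6.0, 1.5),
                                       method="bounded",
                                       options={"xatol": 1e-3})
        cur = neg(np.log(max(sig_eps, 1e-6)))
        if res.fun <= cur:
            return float(np.exp(res.x))
        return sig_eps

    # ---- Laplace marginal log-likelihood (for LL reporting and Wald SE) ---
    def laplace_loglik(self, beta0, beta1, sig_eps, sigma2_a, a_start):
        a, s2, gv, g2 = self.update_a(a_start.copy(), beta0, beta1, sig_eps,
                                      sigma2_a)
        val = np.sum(gv - 0.5 * np.log(2.0 * np.pi * sigma2_a)
                     + 0.5 * np.log(2.0 * np.pi)
                     - 0.5 * np.log(-np.minimum(g2, -0.5 / sigma2_a)))
        return float(val) + self.const, a

    def fit(self, tol: float = 1e-6, max_iter: int = 25):
        # initialize at the pooled binomial GLM
        p0 = float(np.clip((self.y.sum() + 0.5) / (self.n.sum() + 1.0),
                           1e-4, 1 - 1e-4))
        beta0, beta1 = float(special.logit(p0)), 0.0
        sigma2_a, sig_eps = 0.5, np.sqrt(0.5)
        a = np.zeros(self.N)
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            a, s2, gv, _ = self.update_a(a, beta0, beta1, sig_eps, sigma2_a)
            sigma2_a = float(max(np.mean(a ** 2 + s2), 1e-8))
            beta0, beta1 = self.update_beta(beta0, beta1, sig_eps, a, s2)
            if it % 3 == 1:
                sig_eps = self.update_sig_eps(beta0, beta1, sig_eps, a, s2)
            cur = float(np.sum(gv))
            if abs(cur - prev) / (abs(prev) + 1.0) < tol and it >= 5:
                converged = True
                break
            prev = cur
        # polish: alternate a Nelder-Mead refinement of the variance
        # components on the Laplace marginal with a joint Newton step for
        # (beta, a); the EM loop above only has to land in the basin
        for _ in range(1):
            beta0, beta1, a = self._joint_newton(beta0, beta1, sig_eps,
                                                 sigma2_a, a)
            a_ref = a.copy()

            def negml(t, b0=beta0, b1=beta1, a0=a_ref):
                v, _ = self.laplace_loglik(b0, b1, np.exp(0.5 * t[1]),
                                           np.exp(t[0]), a0)
                return -v

            x0 = np.array([np.log(sigma2_a), np.log(sig_eps ** 2)])
            res = optimize.minimize(negml, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-3, "fatol": 1e-5,
                                             "maxfev": 50})
            if res.fun <= negml(x0):
                sigma2_a = float(np.exp(res.x[0]))
                sig_eps = float(np.exp(0.5 * res.x[1]))
        beta0, beta1, a = self._joint_newton(beta0, beta1, sig_eps,
                                             sigma2_a, a)
        ll, a = self.laplace_loglik(beta0, beta1, sig_eps, sigma2_a, a)
        return dict(beta0=beta0, beta1=beta1, sigma2_a=sigma2_a,
                    sigma2_eps=sig_eps ** 2, loglik=ll, a_hat=a,
                    sig_eps=sig_eps, converged=converged)

    def _joint_blocks(self, beta0, beta1, sig_eps, sigma2_a, a):
        """Gradient and Hessian blocks of the joint log-likelihood in
        (beta, a) at the given point; the a-block is diagonal."""
        m, d1, d2 = self._cell_terms(a[self.d], beta0, beta1, sig_eps)
        joint = float(m.sum() - np.sum(a ** 2) / (2.0 * sigma2_a))
        gb = np.array([d1.sum(), float(d1 @ self.x)])
        ga = np.bincount(self.d, weights=d1, minlength=self.N) \
            - a / sigma2_a
        s1 = np.bincount(self.d, weights=d2, minlength=self.N)
        s2x = np.bincount(self.d, weights=d2 * self.x, minlength=self.N)
        Haa = np.minimum(s1 - 1.0 / sigma2_a, -1e-8)
        Hbb = np.array([[d2.sum(), float(d2 @ self.x)],
                        [float(d2 @ self.x), float(d2 @ (self.x ** 2))]])
        U = np.column_stack([s1, s2x])            # (N, 2) cross blocks
        return joint, gb, ga, Hbb, Haa, U

    def _joint_newton(self, beta0, beta1, sig_eps, sigma2_a, a,
                      max_iter: int = 40):
        joint, gb, ga, Hbb, Haa, U = self._joint_blocks(
            beta0, beta1, sig_eps, sigma2_a, a)
        for _ in range(max_iter):
            S = Hbb - (U.T / Haa) @ U             # Schur complement
            rhs = gb - U.T @ (ga / Haa)
            try:
                step_b = -np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                break
            step_a = -(ga + U @ step_b) / Haa
            scale = 1.0
            for _ in range(8):                    # damped acceptance
                b0n = float(np.clip(beta0 + scale * step_b[0], -25, 25))
                b1n = float(np.clip(beta1 + scale * step_b[1], -25, 25))
                an = np.clip(a + scale * step_a, -30, 30)
                out = self._joint_blocks(b0n, b1n, sig_eps, sigma2_a, an)
                if out[0] >= joint - 1e-10:
                    break
                scale *= 0.5
            else:
                break
            moved = max(abs(b0n - beta0), abs(b1n - beta1),
                        float(np.max(np.abs(an - a))))
            beta0, beta1, a = b0n, b1n, an
            joint, gb, ga, Hbb, Haa, U = out
            if moved < 1e-10:
                break
        return beta0, beta1, a

    def wald_se(self, est):
        """SE of beta1 from the fixed-effect block of the joint
        penalized-likelihood information over (beta, a, eps), conditional
        on the estimated variance components — the same construction as
        lme4's fixed-effect vcov. The per-cell eps block is diagonal, so
        eliminating it discounts each cell's binomial curvature by
        c~ = c - c^2 / (c - 1/sigma2_eps); the donor block is then
        eliminated as a second (diagonal) Schur complement."""
        b0, b1 = est["beta0"], est["beta1"]
        s2a, s2e = est["sigma2_a"], est["sigma2_eps"]
        a = est["a_hat"]
        base = b0 + b1 * self.x + a[self.d]
        eps = np.zeros(len(self.y))
        inv_e = 1.0 / max(s2e, 1e-10)
        for _ in range(60):  # vectorized per-cell Newton for the eps mode
            p = special.expit(base + eps)
            g = self.y - self.n * p - eps * inv_e
            h = -self.n * p * (1.0 - p) - inv_e
            step = np.clip(-g / h, -3.0, 3.0)
            eps += step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = special.expit(base + eps)
        c = -self.n * p * (1.0 - p)
        ce = c - inv_e
        ct = c - c * c / ce                   # eps eliminated
        Hbb = np.array([[ct.sum(), float(ct @ self.x)],
                        [float(ct @ self.x), float(ct @ (self.x ** 2))]])
        s1 = np.bincount(self.d, weights=ct, minlength=self.N)
        s2x = np.bincount(self.d, weights=ct * self.x, minlength=self.N)
        Haa = np.minimum(s1 - 1.0 / max(s2a, 1e-10), -1e-10)
        U = np.column_stack([s1, s2x])
        S = Hbb - (U.T / Haa) @ U
        info = -S
        try:
            cov = np.linalg.inv(info)
            if cov[1, 1] > 0:
                return float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass
        return np.nan


def fit_glmm(data: GeneASECounts) -> GlmmFit:
    """Approximate-ML fit of the binomial GLMM for one gene."""
    if data.n_donors < 2:
        raise ValueError("need >= 2 donors")
    eng = _GlmmEngine(data)
    est = eng.fit()
    se = eng.wald_se(est)
    beta1 = est["beta1"]
    z = beta1 / se if (se and se > 0) else np.nan
    pval = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return GlmmFit(gene_id=data.gene_id, beta0=est["beta0"], beta1=beta1,
                   sigma2_a=est["sigma2_a"], sigma2_eps=est["sigma2_eps"],
                   se_beta1=float(se) if se else np.nan,
                   z_stat=float(z) if np.isfinite(z) else np.nan,
                   pvalue=pval, loglik=est["loglik"],
                   converged=bool(est["converged"]), a_hat=est["a_hat"])


def glmm_test(data: GeneASECounts) -> DASETestResult:
    """Wald z-test of H0: beta1 = 0 under the binomial GLMM."""
    result = DASETestResult(gene_id=data.gene_id, method="glmm",
                            n_donors=data.n_donors, n_cells=data.n_cells)
    if data.n_donors < 2:
        result.reason = "too-few-donors"
        return result
    try:
        fit = fit_glmm(data)
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("%s: GLMM fit failed (%s)", data.gene_id, exc)
        result.reason = "fit-error"
        return result
    result.beta0 = fit.beta0
    result.beta1 = fit.beta1
    result.sigma2_a = fit.sigma2_a
    result.loglik_full = fit.loglik
    result.lrt_stat = fit.z_stat ** 2 if np.isfinite(fit.z_stat) else np.nan
    result.pvalue = fit.pvalue
    result.converged = fit.converged
    if not np.isfinite(fit.pvalue):
        result.reason = "no-standard-error"
    return result
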