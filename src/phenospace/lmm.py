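"""REML machinery for the randomized-block form-contrast mixed model.

The model fitted per quantitative trait is

    y = X beta + b_accession + eps,

with fixed effects X = [intercept | replicate dummies | domestic indicator]
and a random intercept per accession. Because each accession belongs to one
form only, the accession variance sigma2_k and the form-specific
accession-by-form interaction variance sigma2_j enter only through their sum,
so the model is parameterized internally by the per-form *total* accession
variance tau2_f = sigma2_k + sigma2_j,f together with the residual variance.
The marginal covariance is block-diagonal (compound symmetry per accession),
which the likelihood exploits in closed form.

The form contrast is tested with a t statistic whose denominator degrees of
freedom use the Satterthwaite approximation, computed from the numeric
gradient of the contrast variance and the numeric Hessian of the REML
criterion (parameters estimated at the zero boundary are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class RemlResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    tau2_wild: float
    tau2_dom: float
    sigma2_e: float
    estimate: float        # form contrast (domestic - wild)
    std_error: float
    t_value: float
    df: float
    p_value: float
    converged: bool
    reml_criterion: float


class _Blocks:
    """Sufficient statistics per accession block, precomputed once."""

    def __init__(self, X: np.ndarray, y: np.ndarray, block_id: np.ndarray,
                 block_is_dom: np.ndarray):
        order = np.argsort(block_id, kind="stable")
        X, y, block_id = X[order], y[order], block_id[order]
        uniq, starts = np.unique(block_id, return_index=True)
        bounds = np.append(starts, len(y))
        self.n_blocks = len(uniq)
        self.n_k = np.diff(bounds).astype(float)
        self.is_dom = block_is_dom
        self.p = X.shape[1]
        self.N = len(y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.s = np.add.reduceat(X, bounds[:-1], axis=0)       # K x p block sums of X
        self.t = np.add.reduceat(y, bounds[:-1])               # K block sums of y

    def solve(self, theta: np.ndarray):
        """Return (XtVinvX, XtVinvy, ytVinvy, logdetV) at theta=(tau2_w,tau2_d,s2)."""
        tau2_w, tau2_d, s2 = theta
        tau2 = np.where(self.is_dom, tau2_d, tau2_w)
        denom = s2 + self.n_k * tau2
        c = tau2 / denom
        XtVinvX = (self.XtX - (self.s * c[:, None]).T @ self.s) / s2
        XtVinvy = (self.Xty - self.s.T @ (c * self.t)) / s2
        ytVinvy = (self.yty - float(c @ (self.t ** 2))) / s2
        logdetV = float(np.sum((self.n_k - 1.0) * np.log(s2) + np.log(denom)))
        return XtVinvX, XtVinvy, ytVinvy, logdetV

    def reml(self, theta: np.ndarray) -> float:
        XtVinvX, XtVinvy, ytVinvy, logdetV = self.solve(theta)
        sign, logdet_xvx = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVinvX, XtVinvy)
        ypy = ytVinvy - float(XtVinvy @ beta)
        if ypy <= 0:
            return np.inf
        return logdetV + logdet_xvx + ypy


def _contrast_var(blocks: _Blocks, theta: np.ndarray, c: np.ndarray) -> float:
    XtVinvX, _, _, _ = blocks.solve(theta)
    return float(c @ np.linalg.solve(XtVinvX, c))


def _num_grad(f, x, rel=1e-4, floor=1e-7):
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = max(floor, rel * abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0)
        g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
    return g


def _num_hess(f, x, rel=1e-3, floor=1e-6):
    n = len(x)
    H = np.zeros((n, n))
    h = np.array([max(floor, rel * abs(xi)) for xi in x])
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            if min(xpm[j], xmp[i] if i != j else 0, xmm[i], xmm[j]) < 0 and (xmm < 0).any():
                # one-sided fallback near the boundary
                H[i, j] = H[j, i] = (f(xpp) - f(_clip0(xpm)) - f(_clip0(xmp)) + f0) / (h[i] * h[j])
            else:
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _clip0(x):
    return np.maximum(x, 0.0)


def fit_reml(X: np.ndarray, y: np.ndarray, accession: np.ndarray,
             is_dom_obs: np.ndarray, form_col: int) -> RemlResult:
    """Fit the compound-symmetry mixed model by REML and test the form contrast."""
    codes, _ = _codes(accession)
    # per-block form flags (accessions nested within forms)
    order = np.argsort(codes, kind="stable")
    uniq, starts = np.unique(codes[order], return_index=True)
    block_is_dom = is_dom_obs[order][starts].astype(bool)
    blocks = _Blocks(X, y, codes, block_is_dom)
    N, p = blocks.N, blocks.p

    # method-of-moments start values
    var_y = max(float(np.var(y)), 1e-12)
    resid_guess = 0.5 * var_y
    tau_guess = max(0.25 * var_y, 1e-6)
    x0 = np.array([tau_guess, tau_guess, resid_guess])
    lb = 1e-10 * var_y
    res = optimize.minimize(blocks.reml, x0, method="L-BFGS-B",
                            bounds=[(0.0, None), (0.0, None), (lb, None)])
    theta = np.maximum(res.x, 0.0)
    converged = bool(res.success)
    best = blocks.reml(theta)

    # polish against the boundary: REML ridges often end with tiny positive
    # variance components whose true optimum sits exactly at zero
    def _try(fixed_zero: tuple[int, ...]):
        nonlocal theta, best
        free = [i for i in range(3) if i not in fixed_zero]
        if free == [2]:
            beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta_ols) ** 2))
            cand = np.array([0.0, 0.0, rss / (blocks.N - blocks.p)])
        else:
            def sub_obj(sub):
                full = np.zeros(3)
                full[free] = np.maximum(sub, 0.0)
                return blocks.reml(full)
            sub0 = np.maximum(theta[free], 1e-6 * var_y)
            r = optimize.minimize(sub_obj, sub0, method="L-BFGS-B",
                                  bounds=[(0.0, None) if i < 2 else (lb, None) for i in free])
            cand = np.zeros(3)
            cand[free] = np.maximum(r.x, 0.0)
        val = blocks.reml(cand)
        if val < best - 1e-10 or (val <= best + 1e-9 and (cand[:2] == 0).sum() > (theta[:2] == 0).sum()):
            theta, best = cand, val

    for zero in ((0,), (1,), (0, 1)):
        _try(zero)

    # snap near-boundary variance components to exactly zero
    tol0 = 1e-8 * var_y
    theta[:2] = np.where(theta[:2] < tol0, 0.0, theta[:2])
    if (theta[:2] == 0).all():
        # pure OLS limit: residual REML variance is RSS/(N-p)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta_ols) ** 2))
        theta[2] = rss / (N - p)

    XtVinvX, XtVinvy, _, _ = blocks.solve(theta)
    C = np.linalg.inv(XtVinvX)
    beta = C @ XtVinvy
    cvec = np.zeros(p)
    cvec[form_col] = 1.0
    v = float(cvec @ C @ cvec)
    se = np.sqrt(v)
    tval = float(beta[form_col] / se) if se > 0 else 0.0

    # Satterthwaite df over parameters away from the zero boundary
    active = [i for i in range(3) if i == 2 or theta[i] > tol0]
    def v_of(sub):
        full = theta.copy()
        full[active] = np.maximum(sub, 0.0)
        return _contrast_var(blocks, full, cvec)
    def f_of(sub):
        full = theta.copy()
        full[active] = np.maximum(sub, 0.0)
        return blocks.reml(full)
    df = float(N - p)
    try:
        sub = theta[active]
        g = _num_grad(v_of, sub)
        H = _num_hess(f_of, sub)
        A = 2.0 * np.linalg.pinv(H)  # asymptotic covariance of the variance parameters
        denom = float(g @ A @ g)
        if denom > 0:
            df = 2.0 * v ** 2 / denom
        df = float(np.clip(df, 1.0, N - p))
    except np.linalg.LinAlgError:
        pass

    pval = float(2.0 * stats.t.sf(abs(tval), df))
    return RemlResult(
        beta=beta, cov_beta=C,
        tau2_wild=float(theta[0]), tau2_dom=float(theta[1]), sigma2_e=float(theta[2]),
        estimate=float(beta[form_col]), std_error=float(se), t_value=tval,
        df=df, p_value=pval, converged=converged, reml_criterion=float(res.fun),
    )


def _codes(labels: np.ndarray):
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, uniq
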