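"""Linear mixed model for well-median length, fit by REML.

The model is

    median length ~ treatment + plate design + (1|strain) + (1|strain:treatment)

with two crossed random intercept terms: a strain effect (genetic variation
in length across both environments) and a strain-by-treatment effect
(genetic variation in the plastic response to cold).  Fitting maximises the
restricted likelihood over the three variance components with the residual
variance profiled out, so the free parameters are the two variance ratios
gamma_k = sigma_k^2 / sigma_e^2 on [0, inf).  The nonnegativity boundary is
handled explicitly: every subset of ratios pinned at zero is profiled and
the best restricted likelihood wins, from a fixed list of starting values,
so the fit is deterministic.

Random-term significance uses a likelihood-ratio test against the model
with that term removed, refit by full REML.  Because the null value
sigma^2 = 0 sits on the parameter boundary, the LRT null is a 50:50 mixture
of chi-square(0) and chi-square(1); halving the chi-square(1) upper-tail
p-value gives the boundary-corrected p.

Fixed effects are tested by type-III F statistics with Satterthwaite
denominator degrees of freedom: the variance of each contrast variance is
propagated through central finite differences of the fixed-effect
covariance with respect to the variance components, with the component
covariance taken from the inverse observed information of the restricted
likelihood.

Broad-sense heritabilities share one denominator:

    H2_strain          = Var_strain / (Var_strain + Var_strain:treatment + Var_residual)
    H2_strain:treatment = Var_strain:treatment / (same denominator)

the first measuring heritable variation in the trait across environments,
the second heritable variation in plasticity (G×E).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_GAMMA_STARTS = (1.0, 0.2, 5.0)  # per free ratio; combined as a product grid
_GAMMA_MAX = 1e8


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge; carries the best state found."""

    def __init__(self, message: str, best: "MixedFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class ModelSpec:
    """Model structure: response column, fixed factors, random intercept terms.

    Fixed factors are categorical with reference-level coding (for
    ``treatment`` the reference is "control"; otherwise the first level in
    sorted order).  A random term is a column name or a colon-joined
    interaction of columns ("strain:treatment").
    """

    response: str = "median_length_um"
    fixed: tuple[str, ...] = ("treatment", "design_id")
    random: tuple[str, ...] = ("strain", "strain:treatment")

    def drop_random(self, term: str) -> "ModelSpec":
        if term not in self.random:
            raise ValueError(f"term {term!r} not in random part {self.random}")
        return ModelSpec(
            response=self.response,
            fixed=self.fixed,
            random=tuple(t for t in self.random if t != term),
        )


@dataclass
class VarianceComponents:
    """The three variance components (µm²) plus fixed effects and REML loglik."""

    var_strain: float
    var_strain_treatment: float
    var_residual: float
    fixed_effects: dict[str, float] = field(default_factory=dict)
    reml_loglik: float = np.nan


@dataclass
class HeritabilityEstimate:
    h2_strain: float
    h2_strain_treatment: float


@dataclass
class LrtResult:
    term: str
    statistic: float
    df: int
    p_halved: float


@dataclass
class AnovaResult:
    term: str
    F: float
    ndf: int
    ddf: float
    p: float


# ---------------------------------------------------------------------------
# design construction


def _level_order(col: str, values: pd.Series) -> list[str]:
    levels = sorted(map(str, values.unique()))
    if col == "treatment" and "control" in levels:
        levels.remove("control")
        levels = ["control"] + levels
    return levels


def _codes(table: pd.DataFrame, term: str) -> tuple[np.ndarray, int, list[str]]:
    """Integer codes for a (possibly interaction) grouping term."""
    cols = term.split(":")
    if len(cols) == 1:
        labels = table[cols[0]].astype(str)
    else:
        labels = table[cols[0]].astype(str)
        for c in cols[1:]:
            labels = labels + ":" + table[c].astype(str)
    levels = sorted(labels.unique())
    lut = {lv: i for i, lv in enumerate(levels)}
    return labels.map(lut).to_numpy(), len(levels), levels


def _fixed_design(table: pd.DataFrame, spec: ModelSpec):
    """Reference-coded fixed design matrix with per-term column spans."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    spans: dict[str, list[int]] = {}
    for f in spec.fixed:
        levels = _level_order(f, table[f].astype(str))
        idx = []
        for lv in levels[1:]:
            idx.append(len(cols))
            cols.append((table[f].astype(str) == lv).to_numpy(float))
            names.append(f"{f}[{lv}]")
        spans[f] = idx
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("fixed-effect design matrix is rank deficient")
    return X, names, spans


class _CrossProducts:
    """Sufficient statistics for the profiled REML criterion.

    All likelihood evaluations reduce to q×q and p×p linear algebra on
    Z'Z, Z'[X y] and [X y]'[X y]; nothing of size n is touched again.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, terms: list[tuple[np.ndarray, int]]):
        self.n, self.p = X.shape
        self.k = len(terms)
        self.block_sizes = [q for _, q in terms]
        self.offsets = np.concatenate([[0], np.cumsum(self.block_sizes)]).astype(int)
        self.q = int(self.offsets[-1])

        U = np.column_stack([X, y])
        ZtZ = np.zeros((self.q, self.q))
        ZtU = np.zeros((self.q, self.p + 1))
        for j, (cj, qj) in enumerate(terms):
            oj = self.offsets[j]
            np.add.at(ZtU, oj + cj, U)
            for l in range(j, self.k):
                cl, ql = terms[l]
                ol = self.offsets[l]
                pair = np.bincount(cj * ql + cl, minlength=qj * ql).reshape(qj, ql)
                ZtZ[oj : oj + qj, ol : ol + ql] = pair
                if l != j:
                    ZtZ[ol : ol + ql, oj : oj + qj] = pair.T
        self.ZtZ = ZtZ
        self.ZtU = ZtU
        self.UtU = U.T @ U

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        return np.repeat(gamma, self.block_sizes)

    def _core(self, gamma: np.ndarray):
        """Shared factorisations at a ratio vector gamma."""
        lam = np.sqrt(self._expand(gamma))
        A = np.eye(self.q) + (lam[:, None] * lam[None, :]) * self.ZtZ
        cA = np.linalg.cholesky(A)
        logdet_A = 2.0 * np.sum(np.log(np.diag(cA)))
        B = lam[:, None] * self.ZtU  # q × (p+1)
        AiB = np.linalg.solve(cA.T, np.linalg.solve(cA, B))
        S = self.UtU - B.T @ AiB  # [X y]' W^-1 [X y]
        Sxx = S[: self.p, : self.p]
        Sxy = S[: self.p, self.p]
        Syy = S[self.p, self.p]
        cS = np.linalg.cholesky(Sxx)
        logdet_Sxx = 2.0 * np.sum(np.log(np.diag(cS)))
        beta = np.linalg.solve(cS.T, np.linalg.solve(cS, Sxy))
        rss = max(float(Syy - Sxy @ beta), 0.0)  # y' P_W y
        return lam, cA, logdet_A, logdet_Sxx, cS, beta, rss

    def neg2_restricted_loglik(self, gamma: np.ndarray) -> float:
        _, _, logdet_A, logdet_Sxx, _, _, rss = self._core(gamma)
        npp = self.n - self.p
        sigma2 = max(rss / npp, 1e-300)  # floor guards degenerate zero-variance data
        return npp * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_A + logdet_Sxx

    def neg2_and_grad(self, gamma: np.ndarray, free: np.ndarray):
        """Criterion and its analytic gradient over the free ratio entries."""
        lam, cA, logdet_A, logdet_Sxx, cS, beta, rss = self._core(gamma)
        npp = self.n - self.p
        sigma2 = max(rss / npp, 1e-300)
        val = npp * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_A + logdet_Sxx

        # Z'W^-1 Z, Z'W^-1 X, Z'W^-1 y from the same factorisations
        G = lam[:, None] * self.ZtZ  # Lambda Z'Z
        AiG = np.linalg.solve(cA.T, np.linalg.solve(cA, G))
        T = self.ZtZ - G.T @ AiG  # Z'W^-1 Z
        Bu = lam[:, None] * self.ZtU
        AiBu = np.linalg.solve(cA.T, np.linalg.solve(cA, Bu))
        ZtWiU = self.ZtU - G.T @ AiBu  # Z'W^-1 [X y]
        ZtWiX = ZtWiU[:, : self.p]
        ZtWiy = ZtWiU[:, self.p]
        u = ZtWiy - ZtWiX @ beta  # Z' P_W y
        SxxInv_M = np.linalg.solve(cS.T, np.linalg.solve(cS, ZtWiX.T))  # p × q

        grads = []
        for j in np.flatnonzero(free):
            sl = slice(self.offsets[j], self.offsets[j + 1])
            t1 = np.trace(T[sl, sl])
            t2 = -float(np.sum(ZtWiX[sl, :].T * SxxInv_M[:, sl]))
            t3 = -float(u[sl] @ u[sl]) / sigma2
            grads.append(t1 + t2 + t3)
        return val, np.array(grads)

    def fixed_solution(self, gamma: np.ndarray):
        """beta, (X'W^-1X)^-1, profiled sigma2 at a ratio vector."""
        _, _, _, _, cS, beta, rss = self._core(gamma)
        SxxInv = np.linalg.solve(cS.T, np.linalg.solve(cS, np.eye(self.p)))
        return beta, SxxInv, rss / (self.n - self.p)

    def neg2_restricted_theta(self, theta: np.ndarray) -> float:
        """Unprofiled criterion on the variance scale theta = (sigma2_terms..., sigma2_e)."""
        sigma2_e = theta[-1]
        gamma = np.asarray(theta[:-1]) / sigma2_e
        _, _, logdet_A, logdet_Sxx, _, _, rss = self._core(gamma)
        npp = self.n - self.p
        return (
            npp * np.log(2 * np.pi)
            + npp * np.log(sigma2_e)
            + logdet_A
            + logdet_Sxx
            + rss / sigma2_e
        )


@dataclass
class MixedFit:
    """A converged REML fit plus everything needed for downstream tests."""

    spec: ModelSpec
    variances: dict[str, float]  # per random term, µm²
    var_residual: float
    beta: np.ndarray
    beta_names: list[str]
    cov_beta: np.ndarray
    reml_loglik: float
    n: int
    p: int
    converged: bool
    term_spans: dict[str, list[int]]
    _xp: _CrossProducts = field(repr=False, default=None)

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.variances.values()) + [self.var_residual])

    @property
    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(
            var_strain=self.variances.get("strain", 0.0),
            var_strain_treatment=self.variances.get("strain:treatment", 0.0),
            var_residual=self.var_residual,
            fixed_effects=dict(zip(self.beta_names, self.beta)),
            reml_loglik=self.reml_loglik,
        )


def fit_reml(table: pd.DataFrame, spec: ModelSpec | None = None) -> MixedFit:
    """Fit the mixed model by REML with explicit boundary handling.

    The residual variance is profiled out and the remaining variance ratios
    are maximised over [0, inf) by bound-constrained quasi-Newton with
    analytic gradients, started from a fixed grid; every subset of ratios
    pinned at zero is profiled separately and the best restricted
    log-likelihood wins.  Deterministic given the data.

    Raises :class:`ConvergenceError` (carrying the best state found) if no
    start converges, and a rank error for singular fixed designs.
    """
    spec = spec or ModelSpec()
    y = table[spec.response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    # centre the response for conditioning; REML is shift invariant and the
    # offset is restored on the intercept below
    y_offset = float(np.mean(y))
    y = y - y_offset
    X, names, spans = _fixed_design(table, spec)

    terms = []
    for term in spec.random:
        codes, q, _ = _codes(table, term)
        terms.append((codes, q))
    xp = _CrossProducts(y, X, terms)
    k = xp.k

    best_val = np.inf
    best_gamma = np.zeros(k)
    any_converged = False

    if k == 0:
        best_val = xp.neg2_restricted_loglik(np.zeros(0))
        any_converged = True
    else:
        for zero_mask in itertools.product([False, True], repeat=k):
            free = ~np.array(zero_mask)
            if not free.any():
                g = np.zeros(k)
                val = xp.neg2_restricted_loglik(g)
                if val < best_val - 1e-12:
                    best_val, best_gamma = val, g
                any_converged = True
                continue
            nfree = int(free.sum())
            for start in itertools.product(_GAMMA_STARTS, repeat=nfree):
                g0 = np.zeros(k)
                g0[free] = start

                def obj(gfree, free=free):
                    g = np.zeros(k)
                    g[free] = gfree
                    return xp.neg2_and_grad(g, free)

                res = optimize.minimize(
                    obj,
                    g0[free],
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[(0.0, _GAMMA_MAX)] * nfree,
                    options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 500},
                )
                if res.success:
                    any_converged = True
                g = np.zeros(k)
                g[free] = res.x
                if res.fun < best_val - 1e-12:
                    best_val, best_gamma = float(res.fun), g

    beta, SxxInv, sigma2 = xp.fixed_solution(best_gamma)
    beta = beta.copy()
    beta[names.index("(Intercept)")] += y_offset
    variances = {t: float(best_gamma[i] * sigma2) for i, t in enumerate(spec.random)}
    fit = MixedFit(
        spec=spec,
        variances=variances,
        var_residual=float(sigma2),
        beta=beta,
        beta_names=names,
        cov_beta=sigma2 * SxxInv,
        reml_loglik=-0.5 * best_val,
        n=xp.n,
        p=xp.p,
        converged=any_converged,
        term_spans=spans,
        _xp=xp,
    )
    if not any_converged:
        raise ConvergenceError("REML optimisation did not converge", best=fit)
    return fit


# ---------------------------------------------------------------------------
# inference


def lrt_random_term(full: MixedFit, reduced: MixedFit) -> LrtResult:
    """Boundary-corrected likelihood-ratio test for one random term.

    ``reduced`` must nest ``full`` by removing exactly one random term.  The
    statistic is 2·(loglik_full − loglik_reduced), clamped at zero; the
    p-value is half the chi-square(1) upper tail, correcting for the null
    lying on the variance boundary.
    """
    removed = set(full.spec.random) - set(reduced.spec.random)
    if len(removed) != 1 or set(reduced.spec.random) - set(full.spec.random):
        raise ValueError("reduced model must remove exactly one random term")
    stat = 2.0 * (full.reml_loglik - reduced.reml_loglik)
    if stat < -1e-6:
        raise ValueError(
            f"reduced model has higher restricted likelihood (LRT = {stat:.3g}); "
            "models are not nested on the same data"
        )
    stat = max(0.0, stat)
    return LrtResult(
        term=removed.pop(),
        statistic=float(stat),
        df=1,
        p_halved=float(0.5 * stats.chi2.sf(stat, df=1)),
    )


def _theta_cov(fit: MixedFit) -> np.ndarray:
    """Asymptotic covariance of the variance components.

    Inverse observed information of the restricted log-likelihood, by
    central-difference Hessian on the variance scale with per-component
    steps max(1e-6, 1e-4·theta_i).  A pseudo-inverse covers boundary fits
    where the information matrix is singular.
    """
    xp = fit._xp
    theta = fit.theta
    m = len(theta)
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))

    def f(t):
        t = np.maximum(t, 1e-12)
        return -0.5 * xp.neg2_restricted_theta(t)

    H = np.zeros((m, m))
    f0 = f(theta)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return np.linalg.pinv(-H)


def _contrast_cov(fit: MixedFit, theta: np.ndarray) -> np.ndarray:
    """cov(beta_hat) at an arbitrary variance-component vector theta."""
    xp = fit._xp
    sigma2_e = max(theta[-1], 1e-12)
    gamma = np.maximum(np.asarray(theta[:-1], float), 0.0) / sigma2_e
    _, SxxInv, _ = xp.fixed_solution(gamma)
    return sigma2_e * SxxInv


def satterthwaite_anova(fit: MixedFit) -> list[AnovaResult]:
    """Type-III F tests for the fixed factors with Satterthwaite ddf.

    Each factor's contrast is the block of its reference-coded coefficients.
    For multi-df factors the contrast covariance is eigen-decomposed into
    independent 1-df contrasts; each 1-df denominator df comes from the
    Satterthwaite recipe 2·(l'Cl)² / Var(l'Cl), with Var propagated through
    central finite differences of C(theta) and the component covariance from
    the observed information; the per-contrast dfs are pooled into a single
    F denominator df.
    """
    results = []
    Vtheta = _theta_cov(fit)
    theta = fit.theta
    m = len(theta)
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))

    # finite-difference gradient of C(theta), reused across terms
    dC = []
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        Cp = _contrast_cov(fit, theta + ei)
        Cm = _contrast_cov(fit, np.maximum(theta - ei, 1e-12))
        dC.append((Cp - Cm) / (2 * h[i]))

    C = fit.cov_beta
    for term, cols in fit.term_spans.items():
        if not cols:
            continue
        L = np.zeros((len(cols), fit.p))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        q = len(cols)
        M = L @ C @ L.T
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue  # non-estimable contrast
        Lb = L @ fit.beta
        F = float(Lb @ Minv @ Lb) / q

        eigval, eigvec = np.linalg.eigh(M)
        nus = []
        for d, v in zip(eigval, eigvec.T):
            if d <= 0:
                continue
            ell = L.T @ v  # p-vector contrast
            grad = np.array([float(ell @ dCi @ ell) for dCi in dC])
            denom = float(grad @ Vtheta @ grad)
            nu = 2.0 * d**2 / denom if denom > 0 else np.inf
            nus.append(nu)
        if q == 1:
            ddf = nus[0]
        else:
            E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
            ddf = 2.0 * E / (E - q) if E > q else float(fit.n - fit.p)
        p = float(stats.f.sf(F, q, ddf)) if np.isfinite(ddf) else float(stats.chi2.sf(F * q, q))
        results.append(AnovaResult(term=term, F=F, ndf=q, ddf=float(ddf), p=p))
    return results


def heritability(vc: VarianceComponents) -> HeritabilityEstimate:
    """Broad-sense heritability of trait and of plasticity.

    Both ratios share the denominator Var_strain + Var_strain:treatment +
    Var_residual from a single full-model fit.  All-zero components leave
    the ratios undefined and raise a ValueError.
    """
    denom = vc.var_strain + vc.var_strain_treatment + vc.var_residual
    if denom <= 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return HeritabilityEstimate(
        h2_strain=vc.var_strain / denom,
        h2_strain_treatment=vc.var_strain_treatment / denom,
    )
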