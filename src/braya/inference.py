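"""Mixed-model comparison layer: ML fits, likelihood-ratio selection, post hoc tests.

Two families of random-intercept mixed models are supported, both with crossed
random intercepts for experimental run and for clone nested within a grouping
factor (genetic cluster or temporal subpopulation):

* Gaussian responses (T_imm, standardized respiration rate) are fitted by
  statsmodels ``MixedLM`` expressed as variance components over a single
  all-encompassing group, with ML (for likelihood-ratio model selection) or
  REML (for reporting the selected model).
* Binary responses (reached P_crit) are fitted by a Laplace-approximation
  maximum-likelihood binomial GLMM implemented here, since the installed
  Python stack has no ML GLMM.

Model selection follows the likelihood-ratio test between nested ML fits,
choosing the fuller model only when p < alpha.  Post hoc machinery (Holm
step-down adjustment, Welch's t, one-way ANOVA, log-log regression) rounds
out the comparison layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "MixedModel",
    "MixedModelResults",
    "LrtResult",
    "fit_mixed",
    "refit_reml",
    "lrt",
    "lrt_from_stats",
    "holm_adjust",
    "welch_t",
    "oneway_anova",
    "loglog_regression",
    "LogLogResult",
    "timm_model_sets",
    "resp_model_sets",
    "pcrit_model_sets",
    "compare_models",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed`` lists fixed-effect terms by column name (the intercept is always
    included); ``random`` lists random-intercept terms, either a plain column
    (e.g. ``"run"``) or a nested term ``"grouping:clone"`` whose levels are
    the combined labels.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    family: str = "gaussian"
    estimation: str = "ML"
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        for term in self.random:
            if ":" in term and len(term.split(":")) != 2:
                raise ValueError(f"nested random term {term!r} must be 'grouping:unit'")

    @property
    def fixed_formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"

    def formula(self) -> str:
        """lme4-style display formula."""
        parts = list(self.fixed) if self.fixed else ["1"]
        parts += [f"(1|{t})" for t in self.random]
        return f"{self.response} ~ " + " + ".join(parts)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.response == other.response
            and self.family == other.family
            and set(self.fixed) <= set(other.fixed)
            and set(self.random) <= set(other.random)
        )


@dataclass
class MixedModelResults:
    """Fitted mixed model: likelihood, information criteria, fixed effects."""

    spec: ModelSpec
    npar: int
    llf: float
    params: pd.Series
    bse: pd.Series
    vc: dict[str, float]  # variance components (variances)
    scale: float | None  # residual variance (gaussian only)
    n_obs: int
    converged: bool
    fallback_applied: bool = False
    method: str = ""

    @property
    def deviance(self) -> float:
        """-2 log-likelihood, as tabulated for ML fits."""
        return -2.0 * self.llf

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.npar

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.npar * np.log(self.n_obs)

    def summary(self) -> str:
        lines = [
            f"Mixed model [{self.spec.family}, {self.spec.estimation}]: {self.spec.formula()}",
            f"  n = {self.n_obs}, npar = {self.npar}, logLik = {self.llf:.2f}, "
            f"AIC = {self.aic:.2f}, BIC = {self.bic:.2f}, deviance = {self.deviance:.2f}",
            f"  converged = {self.converged}"
            + ("  [clone random effect dropped after non-convergence]" if self.fallback_applied else ""),
            "  Fixed effects (estimate +- SE):",
        ]
        for name in self.params.index:
            se = self.bse.get(name, np.nan)
            lines.append(f"    {name:<30s} {self.params[name]: .4f} +- {se:.4f}")
        if self.vc:
            lines.append("  Random-effect variances:")
            for name, v in self.vc.items():
                lines.append(f"    {name:<30s} {v:.5g}")
        if self.scale is not None:
            lines.append(f"  Residual variance: {self.scale:.5g}")
        return "\n".join(lines)


def _nested_column(data: pd.DataFrame, term: str) -> tuple[pd.DataFrame, str]:
    """Materialize a 'grouping:unit' term as a combined-label column."""
    if ":" not in term:
        return data, term
    a, b = term.split(":")
    col = f"_vc_{a}_{b}"
    if col not in data.columns:
        data = data.copy()
        data[col] = data[a].astype(str) + ":" + data[b].astype(str)
    return data, col


class MixedModel:
    """Mixed model built from a :class:`ModelSpec` and a records DataFrame."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        missing = [t for t in spec.fixed if t not in data.columns]
        missing += [c for t in spec.random for c in t.split(":") if c not in data.columns]
        if spec.response not in data.columns:
            missing.append(spec.response)
        if missing:
            raise ValueError(f"terms missing from data: {sorted(set(missing))}")
        self.spec = spec
        self.data = data.reset_index(drop=True)
        for term in spec.random:
            d, col = _nested_column(self.data, term)
            if d[col].nunique() < 2:
                raise ValueError(f"random term {term!r} has fewer than 2 levels")
            self.data = d

    @classmethod
    def from_formula(cls, spec: ModelSpec, data: pd.DataFrame) -> "MixedModel":
        return cls(spec, data)

    def fit(self, auto_simplify: bool = True) -> MixedModelResults:
        """Fit by ML or REML; on non-convergence of a clone random effect the
        model is refitted without it (flagged via ``fallback_applied``)."""
        if self.spec.family == "gaussian":
            res = self._fit_gaussian(self.spec)
        else:
            res = self._fit_binomial(self.spec)
        if not res.converged and auto_simplify:
            clone_terms = [t for t in self.spec.random if ":" in t or "clone" in t.lower()]
            if clone_terms:
                simpler = replace(
                    self.spec,
                    random=tuple(t for t in self.spec.random if t not in clone_terms),
                )
                res2 = MixedModel(simpler, self.data).fit(auto_simplify=False)
                if res2.converged:
                    res2.fallback_applied = True
                    return res2
        return res

    # -- gaussian backend (profiled ML/REML over variance ratios) -----------

    def _fit_gaussian(self, spec: ModelSpec) -> MixedModelResults:
        import statsmodels.formula.api as smf

        if not spec.random:
            # no random terms: ML and REML coincide in the coefficients; use OLS
            res = smf.ols(spec.fixed_formula, self.data).fit()
            return MixedModelResults(
                spec=spec,
                npar=len(res.params) + 1,
                llf=float(res.llf),
                params=res.params.copy(),
                bse=res.bse.copy(),
                vc={},
                scale=float(res.scale),
                n_obs=int(res.nobs),
                converged=True,
                method="OLS",
            )

        from patsy import dmatrices

        y_mat, X_mat = dmatrices(spec.fixed_formula, self.data, return_type="dataframe")
        y = y_mat.to_numpy().ravel()
        X = X_mat.to_numpy()
        fe_names = list(X_mat.columns)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effect design matrix")
        Zs, term_names = [], []
        for term in spec.random:
            data, col = _nested_column(self.data, term)
            codes, levels = pd.factorize(data[col])
            Z = np.zeros((len(y), len(levels)))
            Z[np.arange(len(y)), codes] = 1.0
            Zs.append(Z)
            term_names.append(term)
        reml = spec.estimation == "REML"
        fitter = _GaussianLMM(y, X, Zs)
        gammas, llf, beta, bse, sigma2, ok = fitter.fit(reml=reml)
        npar = X.shape[1] + len(Zs) + 1
        return MixedModelResults(
            spec=spec,
            npar=npar,
            llf=float(llf),
            params=pd.Series(beta, index=fe_names),
            bse=pd.Series(bse, index=fe_names),
            vc={name: float(gamma * sigma2) for name, gamma in zip(term_names, gammas)},
            scale=float(sigma2),
            n_obs=len(y),
            converged=bool(ok),
            method="ProfiledLMM/" + ("REML" if reml else "ML"),
        )

    # -- binomial backend (hand-rolled Laplace ML GLMM) ---------------------

    def _fit_binomial(self, spec: ModelSpec) -> MixedModelResults:
        from patsy import dmatrices

        if spec.estimation == "REML":
            raise ValueError("REML is not defined for binomial mixed models")
        y_mat, X_mat = dmatrices(spec.fixed_formula, self.data, return_type="dataframe")
        y = y_mat.to_numpy().ravel().astype(float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial response must be coded 0/1")
        X = X_mat.to_numpy()
        fe_names = list(X_mat.columns)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effect design matrix")
        Zs, term_names = [], []
        for term in spec.random:
            data, col = _nested_column(self.data, term)
            codes, levels = pd.factorize(data[col])
            Z = np.zeros((len(y), len(levels)))
            Z[np.arange(len(y)), codes] = 1.0
            Zs.append(Z)
            term_names.append(term)
        fitter = _LaplaceBinomialMM(y, X, Zs)
        beta, sds, llf, ok = fitter.fit()
        bse = fitter.beta_se(beta, sds)
        npar = X.shape[1] + len(Zs)
        return MixedModelResults(
            spec=spec,
            npar=npar,
            llf=float(llf),
            params=pd.Series(beta, index=fe_names),
            bse=pd.Series(bse, index=fe_names),
            vc={name: float(sd**2) for name, sd in zip(term_names, sds)},
            scale=None,
            n_obs=len(y),
            converged=bool(ok),
            method="LaplaceGLMM/ML",
        )


class _GaussianLMM:
    """Exact ML/REML for a Gaussian LMM with crossed random intercepts.

    The marginal covariance is sigma2 * R with R = I + sum_k gamma_k Z_k Z_k';
    beta and sigma2 are profiled out in closed form and the likelihood is
    maximized over the variance ratios gamma_k (log scale, multi-start
    Nelder-Mead).  Sample sizes here are small, so dense Cholesky per
    evaluation is cheap and free of the local-optimum issues iterative
    variance-component solvers can hit on near-boundary fits.
    """

    _LOG_GAMMA_FLOOR = -23.0  # gamma ~ 1e-10: variance component effectively zero

    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: Sequence[np.ndarray]):
        self.y = y
        self.X = X
        self.ZZt = [Z @ Z.T for Z in Zs]
        self.n, self.p = X.shape

    def _profile(self, log_gammas: np.ndarray, reml: bool):
        from scipy.linalg import cho_factor, cho_solve

        R = np.eye(self.n)
        for lg, ZZt in zip(log_gammas, self.ZZt):
            R += np.exp(lg) * ZZt
        try:
            cho = cho_factor(R, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None
        logdet_R = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        Rinv_X = cho_solve(cho, self.X)
        Rinv_y = cho_solve(cho, self.y)
        XtRX = self.X.T @ Rinv_X
        beta = np.linalg.solve(XtRX, self.X.T @ Rinv_y)
        resid = self.y - self.X @ beta
        rss = float(resid @ cho_solve(cho, resid))
        if reml:
            dof = self.n - self.p
            sigma2 = rss / dof
            sign, logdet_XtRX = np.linalg.slogdet(XtRX)
            ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + logdet_R + logdet_XtRX + dof)
        else:
            sigma2 = rss / self.n
            ll = -0.5 * (self.n * np.log(2 * np.pi * sigma2) + logdet_R + self.n)
        cov_beta = sigma2 * np.linalg.inv(XtRX)
        return ll, beta, np.sqrt(np.diag(cov_beta)), sigma2

    def fit(self, reml: bool = False):
        k = len(self.ZZt)
        if k == 0:
            ll, beta, bse, sigma2 = self._profile(np.zeros(0), reml)
            return np.zeros(0), ll, beta, bse, sigma2, True

        def neg(lg):
            return -self._profile(np.clip(lg, self._LOG_GAMMA_FLOOR, 12.0), reml)[0]

        starts = [np.full(k, v) for v in (-2.0, 0.0)]
        starts += [np.array([(-6.0 if i == j else -1.0) for j in range(k)]) for i in range(k)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        lg = np.clip(best.x, self._LOG_GAMMA_FLOOR, 12.0)
        ll, beta, bse, sigma2 = self._profile(lg, reml)
        gammas = np.exp(lg)
        gammas[lg <= self._LOG_GAMMA_FLOOR + 1e-9] = 0.0
        return gammas, ll, beta, bse, sigma2, bool(best.success)


class _LaplaceBinomialMM:
    """Laplace-approximation ML for a binomial GLMM with crossed random intercepts.

    The marginal log-likelihood integrates the random effects u ~ N(0, D)
    out of the Bernoulli-logit likelihood; the integral is approximated at the
    joint mode of the penalized log-likelihood (found by Newton iterations),
    matching lme4's default (nAGQ = 1) Laplace objective.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: Sequence[np.ndarray]):
        self.y = y
        self.X = X
        self.Zs = list(Zs)
        self.Z = np.hstack(Zs) if Zs else np.zeros((len(y), 0))
        self.block_sizes = [Z.shape[1] for Z in Zs]

    def _d_inv_diag(self, sds: np.ndarray) -> np.ndarray:
        out = []
        for size, sd in zip(self.block_sizes, sds):
            out.append(np.full(size, 1.0 / max(sd, 1e-8) ** 2))
        return np.concatenate(out) if out else np.zeros(0)

    def _logdet_term(self, sds: np.ndarray, W: np.ndarray) -> float:
        # log det(D Z'WZ + I); D diagonal by block
        if self.Z.shape[1] == 0:
            return 0.0
        d = np.concatenate(
            [np.full(size, sd**2) for size, sd in zip(self.block_sizes, sds)]
        )
        M = (self.Z.T * W) @ self.Z * d[:, None]
        M[np.diag_indices_from(M)] += 1.0
        sign, logdet = np.linalg.slogdet(M)
        return float(logdet)

    def _mode(self, beta: np.ndarray, sds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Newton mode of the penalized log-likelihood in u; returns (u, W at mode)."""
        q = self.Z.shape[1]
        u = np.zeros(q)
        if q == 0:
            eta = self.X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            return u, p * (1 - p)
        d_inv = self._d_inv_diag(sds)
        xb = self.X @ beta
        for _ in range(100):
            eta = xb + self.Z @ u
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            W = p * (1 - p)
            grad = self.Z.T @ (self.y - p) - d_inv * u
            H = (self.Z.T * W) @ self.Z
            H[np.diag_indices_from(H)] += d_inv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step-halving on the penalized objective
            f0 = self._penalized(xb, u, d_inv)
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                if self._penalized(xb, u_new, d_inv) >= f0 - 1e-12:
                    break
                t /= 2.0
            u = u + t * step
            if np.max(np.abs(t * step)) < 1e-10:
                break
        eta = xb + self.Z @ u
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return u, p * (1 - p)

    def _penalized(self, xb: np.ndarray, u: np.ndarray, d_inv: np.ndarray) -> float:
        eta = np.clip(xb + self.Z @ u, -35, 35)
        ll = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(u @ (d_inv * u))

    def loglike(self, beta: np.ndarray, sds: np.ndarray) -> float:
        u, W = self._mode(beta, sds)
        d_inv = self._d_inv_diag(sds)
        xb = self.X @ beta
        return self._penalized(xb, u, d_inv) - 0.5 * self._logdet_term(sds, W)

    def fit(self) -> tuple[np.ndarray, np.ndarray, float, bool]:
        p = self.X.shape[1]
        k = len(self.Zs)
        # start from the fixed-effects-only logistic fit
        beta0 = self._logistic_start()
        x0 = np.concatenate([beta0, np.full(k, 0.5)])

        def neg(params):
            beta, sds = params[:p], np.abs(params[p:])
            return -self.loglike(beta, sds)

        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        res2 = optimize.minimize(neg, res.x, method="BFGS",
                                 options={"maxiter": 200, "gtol": 1e-6})
        best = res2 if res2.fun <= res.fun else res
        beta = best.x[:p]
        sds = np.abs(best.x[p:])
        return beta, sds, -best.fun, bool(res.success or res2.success)

    def _logistic_start(self) -> np.ndarray:
        beta = np.zeros(self.X.shape[1])
        for _ in range(25):
            eta = np.clip(self.X @ beta, -35, 35)
            p = 1.0 / (1.0 + np.exp(-eta))
            W = np.maximum(p * (1 - p), 1e-10)
            H = (self.X.T * W) @ self.X
            g = self.X.T @ (self.y - p)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return beta

    def beta_se(self, beta: np.ndarray, sds: np.ndarray) -> np.ndarray:
        """SEs from the numerical Hessian of the Laplace log-likelihood in beta."""
        from statsmodels.tools.numdiff import approx_hess1

        def f(b):
            return self.loglike(b, sds)

        try:
            H = approx_hess1(beta, f)
            cov = np.linalg.inv(-H)
            var = np.diag(cov)
            return np.sqrt(np.where(var > 0, var, np.nan))
        except np.linalg.LinAlgError:
            return np.full_like(beta, np.nan)


def fit_mixed(spec: ModelSpec, data: pd.DataFrame, auto_simplify: bool = True) -> MixedModelResults:
    """Fit a mixed model per its spec (ML unless the spec says REML)."""
    return MixedModel(spec, data).fit(auto_simplify=auto_simplify)


def refit_reml(spec: ModelSpec, data: pd.DataFrame) -> MixedModelResults:
    """REML refit of a (gaussian) model selected by the likelihood-ratio test."""
    return fit_mixed(replace(spec, estimation="REML"), data)


@dataclass(frozen=True)
class LrtResult:
    chisq: float
    df: int
    p_value: float
    winner: str  # "full" or "null"

    def __str__(self) -> str:
        return f"LRT: chisq = {self.chisq:.4g}, df = {self.df}, p = {self.p_value:.4g} -> {self.winner}"


def lrt_from_stats(
    deviance_null: float, npar_null: int, deviance_full: float, npar_full: int,
    alpha: float = 0.05,
) -> LrtResult:
    """Likelihood-ratio test from tabulated deviances and parameter counts."""
    df = npar_full - npar_null
    if df < 1:
        raise ValueError("full model must have more parameters than the null")
    chisq = deviance_null - deviance_full
    p = float(stats.chi2.sf(max(chisq, 0.0), df))
    winner = "full" if p < alpha else "null"
    return LrtResult(chisq=float(chisq), df=df, p_value=p, winner=winner)


def lrt(null_fit: MixedModelResults, full_fit: MixedModelResults, alpha: float = 0.05) -> LrtResult:
    """Likelihood-ratio test between nested ML fits.

    The fuller model wins only when p < alpha; ties resolve to the simpler
    model.  Both fits must be ML and structurally nested.
    """
    if null_fit.spec.estimation != "ML" or full_fit.spec.estimation != "ML":
        raise ValueError("likelihood-ratio tests require ML fits")
    if not null_fit.spec.is_nested_in(full_fit.spec):
        raise ValueError("null model is not nested in the full model")
    return lrt_from_stats(null_fit.deviance, null_fit.npar, full_fit.deviance, full_fit.npar, alpha)


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; Welch's t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def oneway_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA between/within decomposition: (F, df1, df2, p)."""
    if isinstance(groups, Mapping):
        arrays = [np.asarray(list(v), dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(list(v), dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; F is undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = len(pooled)
    return float(f), k - 1, n - k, float(p)


@dataclass(frozen=True)
class LogLogResult:
    slope: float
    intercept: float
    adj_r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


def loglog_regression(x: Sequence[float], y: Sequence[float]) -> LogLogResult:
    """OLS of log(y) on log(x) (natural logs), e.g. log(P_crit) ~ log(rate)."""
    import statsmodels.api as sm

    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    for name, arr in (("x", x), ("y", y)):
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValueError(f"non-positive {name} value at record {bad[0]}")
    res = sm.OLS(np.log(y), sm.add_constant(np.log(x))).fit()
    return LogLogResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        p_value=float(res.f_pvalue),
    )


# -- the study's model sets -------------------------------------------------


def timm_model_sets(response: str = "t_imm") -> dict[str, list[ModelSpec]]:
    """The two T_imm model sets: genetic-cluster and subpopulation versions."""
    return {
        "set1": [
            ModelSpec(response, (), ("run", "genetic_cluster:clone"), name="gen0"),
            ModelSpec(response, ("genetic_cluster",), ("run", "genetic_cluster:clone"), name="gen1"),
            ModelSpec(response, ("genetic_cluster", "weight"), ("run", "genetic_cluster:clone"), name="gen2"),
        ],
        "set2": [
            ModelSpec(response, (), ("run", "subpopulation:clone"), name="sub0"),
            ModelSpec(response, ("subpopulation",), ("run", "subpopulation:clone"), name="sub1"),
            ModelSpec(response, ("subpopulation", "weight"), ("run", "subpopulation:clone"), name="sub2"),
        ],
    }


def resp_model_sets(response: str = "resp_standard") -> dict[str, list[ModelSpec]]:
    """Null-vs-full comparisons for standardized respiration rates."""
    return {
        "set1": [
            ModelSpec(response, (), ("run", "genetic_cluster:clone"), name="gen0"),
            ModelSpec(response, ("genetic_cluster",), ("run", "genetic_cluster:clone"), name="gen"),
        ],
        "set2": [
            ModelSpec(response, (), ("run", "subpopulation:clone"), name="sub0"),
            ModelSpec(response, ("subpopulation",), ("run", "subpopulation:clone"), name="sub"),
        ],
    }


def pcrit_model_sets(response: str = "reached") -> dict[str, list[ModelSpec]]:
    """Binomial null-vs-full comparisons for the probability of reaching P_crit."""
    return {
        "set1": [
            ModelSpec(response, (), ("run", "genetic_cluster:clone"), family="binomial", name="pcrit_gen0"),
            ModelSpec(response, ("genetic_cluster",), ("run", "genetic_cluster:clone"), family="binomial", name="pcrit_gen"),
        ],
        "set2": [
            ModelSpec(response, (), ("run", "subpopulation:clone"), family="binomial", name="pcrit_sub0"),
            ModelSpec(response, ("subpopulation",), ("run", "subpopulation:clone"), family="binomial", name="pcrit_sub"),
        ],
    }


def compare_models(specs: Sequence[ModelSpec], data: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit a nested model sequence by ML and tabulate sequential LRTs.

    Returns a table with the columns npar, AIC, BIC, logLik, deviance, Chisq,
    df and p-value (one row per model; the first row has no comparison).
    """
    fits = [fit_mixed(s, data) for s in specs]
    # if the clone random effect broke convergence anywhere in the set, the
    # whole set is rerun without it so the models stay mutually nested
    if any(f.fallback_applied for f in fits):
        specs = [
            replace(s, random=tuple(t for t in s.random if ":" not in t and "clone" not in t.lower()))
            for s in specs
        ]
        fits = [fit_mixed(s, data, auto_simplify=False) for s in specs]
        for f in fits:
            f.fallback_applied = True
    rows = []
    prev = None
    for spec, res in zip(specs, fits):
        row = {
            "model": spec.name or spec.formula(),
            "npar": res.npar,
            "AIC": res.aic,
            "BIC": res.bic,
            "logLik": res.llf,
            "deviance": res.deviance,
            "Chisq": np.nan,
            "df": np.nan,
            "p_value": np.nan,
        }
        if prev is not None:
            test = lrt(prev, res, alpha=alpha)
            row.update({"Chisq": test.chisq, "df": test.df, "p_value": test.p_value})
        rows.append(row)
        prev = res
    out = pd.DataFrame(rows).set_index("model")
    out.attrs["fits"] = fits
    return out
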