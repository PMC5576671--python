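"""Linear mixed models with a single random intercept grouping.

The survey design calls for models of the form

    y = X beta + Z b + e,    b ~ N(0, sigma_s^2 I_q),  e ~ N(0, sigma_e^2 I_n)

with site as the (only) random grouping.  Because site labels are unique
across management levels, "site nested within management" reduces to a
plain site random intercept, which is what is fitted here.

The variance components are estimated by REML (ML on request, for
likelihood-ratio tests); the single variance ratio is profiled out, so the
optimisation is a bounded one-dimensional search and the fit is fast
enough for Monte-Carlo calibration studies.  Per-term F tests are marginal
(Type III, via sum-to-zero coding) with Satterthwaite denominator degrees
of freedom by default and a residual (n - rank) fallback.  Tukey all-pair
comparisons of estimated marginal means use the studentized-range
distribution in the balanced exchangeable case and a seeded multivariate-t
Monte-Carlo otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .survey import SEASONS

__all__ = [
    "CommunityLMM", "CommunityLMMResults", "LmmSpec", "fit_lmm",
    "lrt_vs_null", "nakagawa_r2", "tukey_pairs", "vif",
]


# ---------------------------------------------------------------------------
# Design construction (sum-to-zero coding so term columns give Type III tests)
# ---------------------------------------------------------------------------

def _level_order(name: str, values: pd.Series) -> list:
    levels = list(pd.unique(values))
    if name == "season" and set(levels) <= set(SEASONS):
        return [s for s in SEASONS if s in levels]
    return sorted(levels)


def _sum_coding(n_levels: int) -> np.ndarray:
    m = np.zeros((n_levels, n_levels - 1))
    m[: n_levels - 1] = np.eye(n_levels - 1)
    m[n_levels - 1] = -1.0
    return m


@dataclass
class DesignInfo:
    """Fixed-effect design: terms, factor levels, column layout."""

    terms: tuple[str, ...]
    factor_levels: dict[str, list]
    continuous: list[str]
    column_names: list[str] = field(default_factory=list)
    term_slices: dict[str, slice] = field(default_factory=dict)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, terms: Sequence[str]) -> "DesignInfo":
        factor_levels: dict[str, list] = {}
        continuous: list[str] = []
        for term in terms:
            for part in term.split(":"):
                if part in factor_levels or part in continuous:
                    continue
                if part not in data.columns:
                    raise KeyError(f"model term {part!r} is not a data column")
                col = data[part]
                if pd.api.types.is_numeric_dtype(col) and not isinstance(
                        col.dtype, pd.CategoricalDtype):
                    continuous.append(part)
                else:
                    factor_levels[part] = _level_order(part, col)
        di = cls(tuple(terms), factor_levels, continuous)
        di._layout()
        return di

    def _part_columns(self, part: str) -> list[str]:
        if part in self.factor_levels:
            return [f"{part}[{lv}]" for lv in self.factor_levels[part][:-1]]
        return [part]

    def _layout(self) -> None:
        names = ["Intercept"]
        self.term_slices = {"Intercept": slice(0, 1)}
        for term in self.terms:
            cols = self._part_columns(term.split(":")[0])
            for part in term.split(":")[1:]:
                cols = [f"{a}:{b}" for a in cols for b in self._part_columns(part)]
            self.term_slices[term] = slice(len(names), len(names) + len(cols))
            names.extend(cols)
        self.column_names = names

    def _part_matrix(self, part: str, data: pd.DataFrame) -> np.ndarray:
        if part in self.factor_levels:
            levels = self.factor_levels[part]
            codes = data[part].map({lv: i for i, lv in enumerate(levels)})
            if codes.isna().any():
                bad = sorted(set(data[part]) - set(levels))
                raise ValueError(f"unknown level(s) {bad} for factor {part!r}")
            return _sum_coding(len(levels))[codes.to_numpy(int)]
        return data[part].to_numpy(float)[:, None]

    def build(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(data), 1))]
        for term in self.terms:
            mat = self._part_matrix(term.split(":")[0], data)
            for part in term.split(":")[1:]:
                nxt = self._part_matrix(part, data)
                mat = np.einsum("ij,ik->ijk", mat, nxt).reshape(len(data), -1)
            cols.append(mat)
        return np.column_stack(cols)

    def row(self, assign: dict[str, object], cont: dict[str, float]) -> np.ndarray:
        """One design row for a full assignment of factor levels and
        continuous values (used to build estimated marginal means)."""
        frame = {}
        for f in self.factor_levels:
            frame[f] = [assign[f]]
        for c in self.continuous:
            frame[c] = [cont[c]]
        return self.build(pd.DataFrame(frame))[0]


# ---------------------------------------------------------------------------
# Core REML/ML machinery
# ---------------------------------------------------------------------------

class _GroupOps:
    """Fast per-group operations for V = sigma_e^2 (I + lambda Z Z')."""

    def __init__(self, groups: np.ndarray):
        labels, codes = np.unique(groups, return_inverse=True)
        self.labels = labels
        self.codes = codes
        self.counts = np.bincount(codes).astype(float)
        self.q = len(labels)

    def group_sum(self, a: np.ndarray) -> np.ndarray:
        out = np.zeros((self.q,) + a.shape[1:])
        np.add.at(out, self.codes, a)
        return out

    def winv(self, a: np.ndarray, lam: float) -> np.ndarray:
        """(I + lam Z Z')^{-1} a via the Woodbury identity."""
        if lam == 0:
            return a
        gs = self.group_sum(a)
        shrink = (lam / (1.0 + lam * self.counts))
        if a.ndim == 1:
            return a - (shrink * gs.T).T[self.codes].reshape(a.shape)
        return a - (shrink[:, None] * gs)[self.codes]

    def logdet_w(self, lam: float) -> float:
        return float(np.log1p(lam * self.counts).sum())


def _profile_crit(lam: float, y: np.ndarray, x: np.ndarray, ops: _GroupOps,
                  reml: bool) -> tuple[float, np.ndarray, float]:
    """-2 profiled log-likelihood at variance ratio lam (up to a constant).

    Returns the criterion, the GLS coefficients and the profiled residual
    variance.
    """
    n, p = x.shape
    wx = ops.winv(x, lam)
    wy = ops.winv(y, lam)
    xtwx = x.T @ wx
    beta = np.linalg.solve(xtwx, x.T @ wy)
    r = y - x @ beta
    rss = float(r @ ops.winv(r, lam))
    # deterministic responses would drive log(sigma2) to -inf; floor keeps
    # the criterion finite while leaving regular fits untouched
    rss = max(rss, 1e-24 * n * float(np.var(y)))
    if reml:
        sigma2 = rss / (n - p)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        crit = ((n - p) * np.log(sigma2) + ops.logdet_w(lam) + logdet_xtwx)
    else:
        sigma2 = rss / n
        crit = n * np.log(sigma2) + ops.logdet_w(lam)
    return crit, beta, sigma2


def _loglike(theta: tuple[float, float], y: np.ndarray, x: np.ndarray,
             ops: _GroupOps, reml: bool) -> float:
    """Exact (restricted) log-likelihood at theta = (sigma_s^2, sigma_e^2)."""
    sigma_s2, sigma_e2 = theta
    n, p = x.shape
    lam = sigma_s2 / sigma_e2
    wx = ops.winv(x, lam)
    wy = ops.winv(y, lam)
    xtwx = x.T @ wx
    beta = np.linalg.solve(xtwx, x.T @ wy)
    r = y - x @ beta
    rss = float(r @ ops.winv(r, lam))
    sigma_e2 = max(sigma_e2, 1e-24 * float(np.var(y)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + ops.logdet_w(lam)
                 + rss / sigma_e2)
    if reml:
        _, logdet = np.linalg.slogdet(xtwx / sigma_e2)
        ll += 0.5 * p * np.log(2 * np.pi) - 0.5 * logdet
    return ll


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class LmmSpec:
    """Declarative model description for :func:`fit_lmm`."""

    response: str
    fixed: tuple[str, ...] = ("season", "management", "season:management")
    group: str = "site"
    reml: bool = True


class CommunityLMM:
    """Linear mixed model with a single random-intercept grouping.

    Build with :meth:`from_dataframe`; ``fit`` returns a
    :class:`CommunityLMMResults`.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray, groups: np.ndarray,
                 design_info: DesignInfo | None = None,
                 exog_names: list[str] | None = None,
                 data: pd.DataFrame | None = None, response_name: str = "y"):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.std() == 0:
            raise ValueError("response has zero variance")
        self.ops = _GroupOps(np.asarray(groups))
        if self.ops.q < 2:
            raise ValueError("random grouping needs at least 2 levels")
        n, p = self.exog.shape
        if np.linalg.matrix_rank(self.exog) < p:
            raise ValueError("fixed-effect design is rank deficient")
        if n <= p:
            raise ValueError("more fixed parameters than observations")
        self.design_info = design_info
        self.exog_names = exog_names or (design_info.column_names if design_info
                                         else [f"x{i}" for i in range(p)])
        self.data = data
        self.response_name = response_name

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       fixed: Sequence[str] = ("season", "management",
                                               "season:management"),
                       group: str = "site") -> "CommunityLMM":
        di = DesignInfo.from_dataframe(data, fixed)
        x = di.build(data)
        return cls(data[response].to_numpy(float), x, data[group].to_numpy(),
                   design_info=di, data=data, response_name=response)

    def fit(self, reml: bool = True) -> "CommunityLMMResults":
        y, x, ops = self.endog, self.exog, self.ops

        def crit(loglam: float) -> float:
            return _profile_crit(np.exp(loglam), y, x, ops, reml)[0]

        res = optimize.minimize_scalar(crit, bounds=(-14.0, 14.0),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        crit0, _, _ = _profile_crit(0.0, y, x, ops, reml)
        if crit0 <= res.fun + 1e-10:
            lam = 0.0
        _, beta, sigma_e2 = _profile_crit(lam, y, x, ops, reml)
        sigma_s2 = lam * sigma_e2
        llf = _loglike((sigma_s2, sigma_e2), y, x, ops, reml)
        wx = ops.winv(x, lam)
        cov_beta = sigma_e2 * np.linalg.inv(x.T @ wx)
        return CommunityLMMResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            cov_params_=pd.DataFrame(cov_beta, index=self.exog_names,
                                     columns=self.exog_names),
            sigma2_site=sigma_s2, sigma2_resid=sigma_e2, lambda_=lam,
            llf=float(llf), reml=reml, converged=bool(res.success))


@dataclass
class CommunityLMMResults:
    """REML/ML fit: coefficients, variance components, tests, R^2."""

    model: CommunityLMM
    params: pd.Series
    cov_params_: pd.DataFrame
    sigma2_site: float
    sigma2_resid: float
    lambda_: float
    llf: float
    reml: bool
    converged: bool

    # -- basic accessors ---------------------------------------------------

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def k_fixed(self) -> int:
        return self.model.exog.shape[1]

    @property
    def df_resid(self) -> int:
        return self.nobs - self.k_fixed

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params_.to_numpy())),
                         index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self.cov_params_

    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params.to_numpy()

    # -- Satterthwaite machinery ------------------------------------------

    def _theta_cov(self) -> np.ndarray | None:
        """Covariance of (sigma_s^2, sigma_e^2) from the observed REML/ML
        information, by central finite differences; None when the site
        variance sits on the boundary."""
        theta = np.array([self.sigma2_site, self.sigma2_resid])
        if theta[0] <= 1e-12 * theta[1]:
            return None
        y, x, ops = self.model.endog, self.model.exog, self.model.ops

        def nll(t):
            return -_loglike((t[0], t[1]), y, x, ops, self.reml)

        h = np.maximum(theta * 1e-4, 1e-10)
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                val = (nll(theta + ei + ej) - nll(theta + ei - ej)
                       - nll(theta - ei + ej) + nll(theta - ei - ej)) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(cov).all() or cov[0, 0] < 0 or cov[1, 1] < 0:
            return None
        return cov

    def _contrast_var(self, l: np.ndarray, theta: np.ndarray) -> float:
        sigma_s2, sigma_e2 = theta
        lam = sigma_s2 / sigma_e2
        x, ops = self.model.exog, self.model.ops
        c = sigma_e2 * np.linalg.inv(x.T @ ops.winv(x, lam))
        return float(l @ c @ l)

    def satterthwaite_df(self, l: np.ndarray,
                         theta_cov: np.ndarray | None = ...) -> float:
        """Satterthwaite denominator df for the scalar contrast l'beta."""
        if theta_cov is ...:
            theta_cov = self._theta_cov()
        if theta_cov is None:
            return float(self.df_resid)
        theta = np.array([self.sigma2_site, self.sigma2_resid])
        f0 = self._contrast_var(l, theta)
        h = np.maximum(theta * 1e-4, 1e-10)
        grad = np.zeros(2)
        for i in range(2):
            ei = np.eye(2)[i] * h[i]
            grad[i] = (self._contrast_var(l, theta + ei)
                       - self._contrast_var(l, theta - ei)) / (2 * h[i])
        denom = float(grad @ theta_cov @ grad)
        if denom <= 0:
            return float(self.df_resid)
        return float(2.0 * f0 ** 2 / denom)

    # -- tests -------------------------------------------------------------

    def contrast(self, l: np.ndarray, ddf: str = "satterthwaite"
                 ) -> tuple[float, float, float, float]:
        """t test of l'beta = 0: (estimate, se, df, p)."""
        l = np.asarray(l, dtype=float)
        est = float(l @ self.params.to_numpy())
        se = float(np.sqrt(l @ self.cov_params_.to_numpy() @ l))
        df = (self.satterthwaite_df(l) if ddf == "satterthwaite"
              else float(self.df_resid))
        if se == 0:
            return est, se, df, (1.0 if est == 0 else 0.0)
        t = est / se
        return est, se, df, float(2 * stats.t.sf(abs(t), df))

    def f_test_term(self, term: str, ddf: str = "satterthwaite"
                    ) -> tuple[float, int, float, float]:
        """Marginal (Type III) F test of one model term.

        Returns (F, df_num, df_den, p).  The denominator df is the
        Satterthwaite value combined over the term's eigencontrasts, or
        n - rank with ``ddf='residual'``.
        """
        di = self.model.design_info
        if di is None or term not in di.term_slices:
            raise KeyError(f"term {term!r} not in the fitted design")
        sl = di.term_slices[term]
        p = self.k_fixed
        idx = range(sl.start, sl.stop)
        lmat = np.zeros((len(list(idx)), p))
        for row, j in enumerate(range(sl.start, sl.stop)):
            lmat[row, j] = 1.0
        beta = self.params.to_numpy()
        c = self.cov_params_.to_numpy()
        m = lmat @ c @ lmat.T
        r = lmat.shape[0]
        fstat = float(beta @ lmat.T @ np.linalg.solve(m, lmat @ beta) / r)
        if ddf == "residual":
            dfd = float(self.df_resid)
        else:
            theta_cov = self._theta_cov()
            if theta_cov is None:
                dfd = float(self.df_resid)
            else:
                evals, evecs = np.linalg.eigh(m)
                nus = []
                for j in range(r):
                    lvec = lmat.T @ evecs[:, j]
                    nus.append(self.satterthwaite_df(lvec, theta_cov))
                nus = [nu for nu in nus if nu > 2.0]
                if not nus:
                    dfd = float(self.df_resid)
                else:
                    e = sum(nu / (nu - 2.0) for nu in nus)
                    dfd = 2.0 * e / (e - r) if e > r else float(self.df_resid)
        pval = float(stats.f.sf(fstat, r, dfd))
        return fstat, r, dfd, pval

    def anova(self, ddf: str = "satterthwaite") -> pd.DataFrame:
        """Per-term marginal F table (Table-1 shape)."""
        rows = []
        for term in self.model.design_info.terms:
            f, dfn, dfd, p = self.f_test_term(term, ddf)
            rows.append({"term": term, "F": f, "DFnum": dfn, "DFden": dfd, "P": p})
        return pd.DataFrame(rows).set_index("term")

    def tukey(self, factor: str, within: dict[str, object] | None = None,
              ddf: str = "satterthwaite", mc_draws: int = 200_000,
              mc_seed: int = 0) -> pd.DataFrame:
        return tukey_pairs(self, factor, within=within, ddf=ddf,
                           mc_draws=mc_draws, mc_seed=mc_seed)

    # -- output ------------------------------------------------------------

    def summary(self) -> str:
        r2m, r2c = nakagawa_r2(self)
        lines = [
            f"Linear mixed model ({'REML' if self.reml else 'ML'}), "
            f"response {self.model.response_name!r}",
            f"n = {self.nobs}, groups = {self.model.ops.q}, "
            f"log-likelihood = {self.llf:.3f}",
            f"variance components: site = {self.sigma2_site:.4f}, "
            f"residual = {self.sigma2_resid:.4f}",
            f"R2 marginal = {r2m:.3f}, R2 conditional = {r2c:.3f}", "",
            pd.DataFrame({"coef": self.params, "se": self.bse}).to_string(
                float_format=lambda v: f"{v:.4f}"),
        ]
        if self.model.design_info is not None and self.model.design_info.terms:
            lines += ["", self.anova().to_string(
                float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        r2m, r2c = nakagawa_r2(self)
        return {
            "response": self.model.response_name,
            "reml": self.reml,
            "coefficients": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "sigma2_site": self.sigma2_site,
            "sigma2_resid": self.sigma2_resid,
            "loglik": self.llf,
            "r2_marginal": r2m,
            "r2_conditional": r2c,
        }


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def fit_lmm(spec: LmmSpec, data: pd.DataFrame) -> CommunityLMMResults:
    model = CommunityLMM.from_dataframe(data, spec.response, spec.fixed, spec.group)
    return model.fit(reml=spec.reml)


def lrt_vs_null(full: CommunityLMMResults, null: CommunityLMMResults
                ) -> tuple[float, int, float]:
    """Likelihood-ratio test of the fixed structure against the
    random-effects-only null; both fits must be ML on the same data."""
    if full.reml or null.reml:
        raise ValueError("likelihood-ratio tests require ML fits (reml=False)")
    if full.nobs != null.nobs:
        raise ValueError("fits are not on the same data")
    df = full.k_fixed - null.k_fixed
    if df <= 0:
        raise ValueError("full model must have more fixed parameters than the null")
    null_names = set(null.params.index)
    if not null_names <= set(full.params.index):
        raise ValueError("models are not nested")
    chi2 = 2.0 * (full.llf - null.llf)
    if chi2 < -1e-6:
        raise ValueError(f"full model fits worse than the null (chi2 = {chi2:.3g})")
    chi2 = max(chi2, 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def nakagawa_r2(fit: CommunityLMMResults) -> tuple[float, float]:
    """Marginal and conditional R^2 for a mixed model.

    R2_marginal = var(X beta) / (var(X beta) + sigma_site^2 + sigma_res^2)
    and R2_conditional adds the site variance to the numerator.
    """
    var_fixed = float(np.var(fit.fittedvalues(), ddof=0))
    total = var_fixed + fit.sigma2_site + fit.sigma2_resid
    if total == 0:
        raise ValueError("all variance components are zero")
    return var_fixed / total, (var_fixed + fit.sigma2_site) / total


def _is_balanced_exchangeable(corr: np.ndarray, dfs: np.ndarray,
                              tol: float = 1e-6) -> bool:
    off = np.abs(corr[~np.eye(corr.shape[0], dtype=bool)])
    return (np.allclose(off, 0.5, atol=tol)
            and np.allclose(dfs, dfs.mean(), atol=max(1e-6, 1e-4 * dfs.mean())))


def tukey_pairs(fit: CommunityLMMResults, factor: str,
                within: dict[str, object] | None = None,
                ddf: str = "satterthwaite", mc_draws: int = 200_000,
                mc_seed: int = 0) -> pd.DataFrame:
    """Tukey all-pair comparisons of estimated marginal means.

    Marginal means per level of ``factor`` average the model predictions
    over the levels of the other factors (continuous covariates held at
    their data mean); ``within`` pins named factors to one level, which is
    how interactions are dissected.  Adjusted p-values are single-step:
    the studentized-range distribution when the contrasts are balanced and
    exchangeable, otherwise a seeded multivariate-t Monte-Carlo.
    """
    di = fit.model.design_info
    if di is None or factor not in di.factor_levels:
        raise KeyError(f"factor {factor!r} is not in the fitted design")
    within = within or {}
    levels = di.factor_levels[factor]
    other_factors = [f for f in di.factor_levels
                     if f != factor and f not in within]
    cont = {c: float(fit.model.data[c].mean()) for c in di.continuous}

    emm_rows = {}
    for lv in levels:
        rows = []
        combos = itertools.product(*[di.factor_levels[f] for f in other_factors])
        for combo in combos:
            assign = {factor: lv, **within,
                      **dict(zip(other_factors, combo))}
            rows.append(di.row(assign, cont))
        emm_rows[lv] = np.mean(rows, axis=0)

    pairs = list(itertools.combinations(levels, 2))
    lmat = np.array([emm_rows[a] - emm_rows[b] for a, b in pairs])
    beta = fit.params.to_numpy()
    cov = fit.cov_params_.to_numpy()
    est = lmat @ beta
    vmat = lmat @ cov @ lmat.T
    se = np.sqrt(np.diag(vmat))
    theta_cov = fit._theta_cov() if ddf == "satterthwaite" else None
    dfs = np.array([
        fit.satterthwaite_df(l, theta_cov) if ddf == "satterthwaite"
        else float(fit.df_resid) for l in lmat])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, est / np.where(se > 0, se, 1.0),
                         np.where(est == 0, 0.0, np.inf))
    k = len(levels)
    denom_ok = se > 0
    corr = np.eye(len(pairs))
    if denom_ok.all():
        corr = vmat / np.outer(se, se)
    if denom_ok.all() and _is_balanced_exchangeable(corr, dfs):
        padj = stats.studentized_range.sf(np.abs(tvals) * np.sqrt(2.0), k,
                                          dfs.mean())
        method = "studentized-range"
    else:
        rng = np.random.default_rng(mc_seed)
        df_mc = float(np.median(dfs))
        jitter = 1e-10 * np.eye(len(pairs))
        chol = np.linalg.cholesky(corr + jitter)
        z = rng.standard_normal((mc_draws, len(pairs))) @ chol.T
        s = np.sqrt(rng.chisquare(df_mc, size=mc_draws) / df_mc)
        tmax = np.abs(z / s[:, None]).max(axis=1)
        padj = np.array([np.mean(tmax >= abs(t)) if np.isfinite(t) else 0.0
                         for t in tvals])
        method = "mvt-montecarlo"
    padj = np.where(est == 0.0, 1.0, np.clip(padj, 0.0, 1.0))
    out = pd.DataFrame({
        "contrast": [f"{a}-{b}" for a, b in pairs],
        "estimate": est, "se": se, "df": dfs, "t": tvals,
        "p_adjusted": padj,
    })
    out.attrs["method"] = method
    out.attrs["within"] = dict(within)
    return out


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor column.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing column j on
    the remaining columns (with intercept).  Perfectly collinear columns
    get ``inf``.
    """
    x = pd.DataFrame(design).astype(float)
    if x.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if (x.std(ddof=0) == 0).any():
        bad = list(x.columns[x.std(ddof=0) == 0])
        raise ValueError(f"constant predictor column(s): {bad}")
    out = {}
    for col in x.columns:
        others = np.column_stack([np.ones(len(x)),
                                  x.drop(columns=[col]).to_numpy()])
        yj = x[col].to_numpy()
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")
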