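"""Models linking TBT burden, methylation, imposex level and body mass.

The centrepiece is a proportional-odds (cumulative-logit) model for the
ordinal imposex scale: P(y <= k) = logistic(zeta_k - x'beta) with common
slopes and ordered cutpoints, fitted by maximum likelihood with Wald
summaries (t, p, OR, CI, AIC) in the layout population-level monitoring
studies report.  Ordinary least squares, one-way ANOVA with Tukey HSD,
Mann-Whitney comparisons and a trait PCA cover the remaining analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "ProportionalOdds",
    "ProportionalOddsResults",
    "ConvergenceError",
    "fit_proportional_odds",
    "wald_summary",
    "LinearFit",
    "fit_linear",
    "anova_lm",
    "GroupComparison",
    "group_compare",
    "PcaResult",
    "pca_scores",
]


class ConvergenceError(RuntimeError):
    pass


def _logistic_pdf(z: np.ndarray) -> np.ndarray:
    p = expit(z)
    return p * (1.0 - p)


class ProportionalOdds:
    """Cumulative-logit proportional-odds model for an ordinal response.

    Parameters
    ----------
    y : array-like
        Ordinal response; categories are its sorted unique values.  Declared
        ``levels`` with zero observed counts are collapsed into the adjacent
        category with a warning (their cutpoints are unidentifiable).
    X : DataFrame or 2-D array, optional
        Predictors (no intercept; the cutpoints absorb location).
    """

    def __init__(self, y, X=None, levels=None):
        y = np.asarray(pd.Series(y).to_numpy())
        if X is None:
            Xd = pd.DataFrame(index=range(len(y)))
        elif isinstance(X, pd.DataFrame):
            Xd = X.reset_index(drop=True)
        else:
            Xarr = np.atleast_2d(np.asarray(X, dtype=float))
            if Xarr.shape[0] != len(y):
                Xarr = Xarr.T
            Xd = pd.DataFrame(Xarr, columns=[f"x{i + 1}" for i in range(Xarr.shape[1])])
        mask = ~pd.isna(y)
        if len(Xd.columns):
            mask &= Xd.notna().all(axis=1).to_numpy()
        y, Xd = y[mask], Xd.loc[mask]
        observed = np.unique(y)
        if levels is not None:
            missing = [lv for lv in levels if lv not in observed]
            if missing:
                warnings.warn(
                    f"ordinal categories with zero counts collapsed into their "
                    f"adjacent category: {missing}",
                    stacklevel=2,
                )
            cats = [lv for lv in levels if lv in observed]
        else:
            cats = list(observed)
        if len(cats) < 2:
            raise ValueError("ordinal response needs at least two observed categories")
        self.categories = cats
        self.cutpoint_names = [f"{cats[k]}|{cats[k + 1]}" for k in range(len(cats) - 1)]
        code = {c: i for i, c in enumerate(cats)}
        self.k_idx = np.array([code[v] for v in y])
        self.X = Xd.to_numpy(dtype=float)
        self.exog_names = list(Xd.columns)
        self.n_obs = len(y)
        self.K = len(cats)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors):
        return cls(data[response], data[list(predictors)])

    # -- likelihood machinery (natural parameters: beta, ordered cutpoints) --

    def _probs(self, beta: np.ndarray, zeta: np.ndarray):
        eta = self.X @ beta if len(beta) else np.zeros(self.n_obs)
        z = np.concatenate([[-np.inf], zeta, [np.inf]])
        upper = z[self.k_idx + 1] - eta
        lower = z[self.k_idx] - eta
        p = expit(upper) - expit(lower)
        return np.clip(p, 1e-300, None), upper, lower

    def loglike(self, beta, zeta) -> float:
        p, _, _ = self._probs(np.asarray(beta, float), np.asarray(zeta, float))
        return float(np.log(p).sum())

    def _unpack(self, theta: np.ndarray):
        p = len(self.exog_names)
        beta = theta[:p]
        raw = theta[p:]
        zeta = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
        return beta, zeta

    def _nll_grad(self, theta: np.ndarray):
        beta, zeta = self._unpack(theta)
        nll = -self.loglike(beta, zeta)
        nat = self._natural_grad(beta, zeta)  # d ll / d(beta, zeta)
        p = len(self.exog_names)
        dbeta, dzeta = nat[:p], nat[p:]
        # zeta_j = z1 + sum_{l<=j, l>=2} exp(u_l): chain rule to (z1, u)
        raw = theta[p:]
        J = self.K - 1
        dz1 = dzeta.sum()
        du = np.array([dzeta[j:].sum() * np.exp(raw[j]) for j in range(1, J)])
        grad_ll = np.concatenate([dbeta, [dz1], du])
        return nll, -grad_ll

    def _natural_grad(self, beta, zeta):
        """Gradient of the log-likelihood in (beta, zeta)."""
        p, upper, lower = self._probs(beta, zeta)
        f_up = np.where(np.isfinite(upper), _logistic_pdf(upper), 0.0)
        f_lo = np.where(np.isfinite(lower), _logistic_pdf(lower), 0.0)
        w_up, w_lo = f_up / p, f_lo / p
        J = self.K - 1
        dzeta = np.zeros(J)
        for j in range(J):
            dzeta[j] = w_up[self.k_idx == j].sum() - w_lo[self.k_idx == j + 1].sum()
        dbeta = -(self.X * (w_up - w_lo)[:, None]).sum(axis=0)
        return np.concatenate([dbeta, dzeta])

    def _start(self) -> np.ndarray:
        cum = np.cumsum(np.bincount(self.k_idx, minlength=self.K))[:-1] / self.n_obs
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        zeta0 = np.log(cum / (1 - cum))
        zeta0 = np.maximum.accumulate(zeta0 + 1e-6 * np.arange(len(zeta0)))
        raw = np.concatenate(
            [[zeta0[0]], np.log(np.clip(np.diff(zeta0), 1e-4, None))]
        )
        return np.concatenate([np.zeros(len(self.exog_names)), raw])

    def fit(self, maxiter: int = 200, gtol: float = 1e-8) -> "ProportionalOddsResults":
        """Maximum likelihood via Newton iterations with step-halving.

        Predictors are standardised internally (the fit is then transformed
        back), so the optimisation is well conditioned and the reported
        t/p/AIC are exactly invariant to predictor rescaling.  Convergence
        requires the standardised score's max-norm below ``gtol``.
        """
        import copy

        from statsmodels.tools.numdiff import approx_fprime, approx_hess2

        p = len(self.exog_names)
        if p:
            means = self.X.mean(axis=0)
            sds = self.X.std(axis=0, ddof=0)
            if (sds == 0).any():
                bad = self.exog_names[int(np.argmax(sds == 0))]
                raise ValueError(f"predictor {bad!r} is constant")
            work = copy.copy(self)
            work.X = (self.X - means) / sds
        else:
            means = sds = np.array([])
            work = self

        theta = work._start()
        nll, grad = work._nll_grad(theta)
        history = [-nll]
        for _ in range(maxiter):
            if np.max(np.abs(grad)) < gtol * 0.1:
                break
            H = approx_fprime(theta, lambda t: work._nll_grad(t)[1], centered=True)
            H = (H + H.T) / 2.0
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(len(theta)), -grad)
            except np.linalg.LinAlgError:
                step = -grad
            if step @ grad > 0:  # not a descent direction
                step = -grad
            scale = 1.0
            for _ in range(40):
                cand = theta + scale * step
                nll_new, grad_new = work._nll_grad(cand)
                if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                    break
                scale *= 0.5
            else:
                break
            theta, nll, grad = cand, nll_new, grad_new
            history.append(-nll)
        beta_s, zeta_s = work._unpack(theta)
        nat_grad = work._natural_grad(beta_s, zeta_s)
        converged = bool(np.max(np.abs(nat_grad)) < gtol)
        if p and np.abs(beta_s).max() > 15.0:
            name = self.exog_names[int(np.argmax(np.abs(beta_s)))]
            raise ConvergenceError(
                f"proportional-odds fit did not converge; predictor {name!r} "
                "appears to separate the response completely"
            )
        if not converged and not np.isfinite(nll):
            raise ConvergenceError("proportional-odds likelihood became degenerate")

        # observed information in the standardised natural parameterisation
        full_s = np.concatenate([beta_s, zeta_s])

        def nll_nat(v):
            return -work.loglike(v[:p], v[p:])

        H_nat = approx_hess2(full_s, nll_nat)
        H_nat = (H_nat + H_nat.T) / 2.0
        try:
            cov_s = np.linalg.inv(H_nat)
        except np.linalg.LinAlgError:
            cov_s = np.full_like(H_nat, np.nan)
        # back-transform: beta = beta_s / sd, zeta = zeta_s + sum m/sd * beta_s
        J = np.eye(p + self.K - 1)
        if p:
            beta = beta_s / sds
            zeta = zeta_s + float((means / sds) @ beta_s)
            for j in range(p):
                J[j, j] = 1.0 / sds[j]
            for k in range(self.K - 1):
                J[p + k, :p] = means / sds
        else:
            beta, zeta = beta_s, zeta_s
        cov = J @ cov_s @ J.T
        return ProportionalOddsResults(self, beta, zeta, -nll, converged, history, cov)


@dataclass
class ProportionalOddsResults:
    """MLE results: coefficients, cutpoints, observed-information SEs."""

    model: ProportionalOdds
    params: np.ndarray  # beta
    cutpoints: np.ndarray  # zeta, strictly increasing
    llf: float
    converged: bool
    llf_history: list
    cov_params: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.params)
        se = np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))
        self.bse = se[:p]
        self.cutpoint_bse = se[p:]

    @property
    def n_params(self) -> int:
        return len(self.params) + len(self.cutpoints)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame(
            dict(OR=np.exp(self.params), ci_low=lo, ci_high=hi),
            index=self.model.exog_names,
        )

    def summary(self) -> pd.DataFrame:
        return wald_summary(self)


def wald_cells(value: float, se: float, z: float = 1.96) -> dict:
    """Wald-table arithmetic for one coefficient: t, OR and the 95% CI.

    t = value/se; OR = exp(value); CI = exp(value ± z·se).  This is the
    arithmetic behind each coefficient row of an ordinal-regression summary
    table (odds-ratio scale, normal reference).
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    return dict(
        t=value / se,
        OR=float(np.exp(value)),
        ci_low=float(np.exp(value - z * se)),
        ci_high=float(np.exp(value + z * se)),
    )


def fit_proportional_odds(y, X=None, levels=None, **fit_kwargs) -> ProportionalOddsResults:
    """Convenience wrapper: build the model and fit it."""
    return ProportionalOdds(y, X, levels=levels).fit(**fit_kwargs)


def wald_summary(fit: ProportionalOddsResults) -> pd.DataFrame:
    """Coefficients then cutpoints: Value, SE, t, p, OR, 95% CI, AIC.

    t = estimate/SE with a two-sided normal reference; OR and its Wald CI
    only make sense for the slope coefficients, AIC is printed on the first
    row (the model-level statistic).
    """
    if not fit.converged:
        raise ValueError("Wald summary requires a converged fit")
    if np.any(fit.bse == 0) or np.any(fit.cutpoint_bse == 0):
        raise ValueError("zero standard error: information matrix is singular")
    m = fit.model
    rows = []
    ors = fit.odds_ratios()
    for i, name in enumerate(m.exog_names):
        rows.append(
            dict(term=name, kind="coefficient", value=fit.params[i], se=fit.bse[i],
                 t_value=fit.tvalues[i], p_value=fit.pvalues[i],
                 OR=ors["OR"].iloc[i], ci_low=ors["ci_low"].iloc[i],
                 ci_high=ors["ci_high"].iloc[i], AIC=np.nan)
        )
    zc = fit.cutpoints / fit.cutpoint_bse
    pc = 2.0 * stats.norm.sf(np.abs(zc))
    for j, name in enumerate(m.cutpoint_names):
        rows.append(
            dict(term=name, kind="cutpoint", value=fit.cutpoints[j],
                 se=fit.cutpoint_bse[j], t_value=zc[j], p_value=pc[j],
                 OR=np.nan, ci_low=np.nan, ci_high=np.nan, AIC=np.nan)
        )
    out = pd.DataFrame(rows).set_index("term")
    out.iloc[0, out.columns.get_loc("AIC")] = fit.aic
    return out


# ---------------------------------------------------------------------------
# Linear models


@dataclass
class LinearFit:
    """OLS fit summary: coefficients, F test, adjusted R²."""

    params: pd.Series
    bse: pd.Series
    fvalue: float
    df_model: int
    df_resid: int
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    resid: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(dict(coef=self.params, se=self.bse))


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        aliased = []
        cols = list(X.columns)
        for i in range(len(cols)):
            sub = np.delete(arr, i + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(cols[i])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_linear(y, X) -> LinearFit:
    """Ordinary least squares of y on X (intercept added)."""
    import statsmodels.api as sm

    Xd = pd.DataFrame(X)
    yv = pd.Series(y).astype(float)
    mask = yv.notna() & Xd.notna().all(axis=1)
    Xd, yv = Xd.loc[mask], yv.loc[mask]
    if len(yv) <= Xd.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    _check_rank(Xd)
    res = sm.OLS(yv, sm.add_constant(Xd.astype(float))).fit()
    return LinearFit(
        params=res.params,
        bse=res.bse,
        fvalue=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        f_pvalue=float(res.f_pvalue),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        resid=np.asarray(res.resid),
    )


def anova_lm(y, factor) -> LinearFit:
    """One-way ANOVA as an OLS fit on factor dummies (overall F test)."""
    f = pd.Series(factor).astype("category")
    dummies = pd.get_dummies(f, drop_first=True, prefix="level").astype(float)
    dummies.index = pd.RangeIndex(len(dummies))
    yv = pd.Series(np.asarray(y, dtype=float))
    return fit_linear(yv, dummies)


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None
    letters: dict | None


def _compact_letters(groups: list, means: dict, nonsig_pairs: set) -> dict:
    """Compact letter display: two groups share a letter iff their difference
    is non-significant.  Letters are the maximal cliques of the
    non-significance graph, ordered by mean."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nonsig_pairs)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: np.mean([means[x] for x in c]))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        for grp in clique:
            letters[grp] += alphabet[i % len(alphabet)]
    return {g_: "".join(sorted(v)) for g_, v in letters.items()}


def group_compare(
    values, groups, method: str = "anova_tukey", alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD (Tukey–Kramer for unequal n), or
    Mann–Whitney U for exactly two groups.

    Mann–Whitney uses full enumeration (exact p) when both groups have
    n <= 8 and no ties, otherwise the normal approximation with tie
    correction.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(groups)
    mask = v.notna()
    v, g = v[mask], g.reset_index(drop=True)[mask.reset_index(drop=True)]
    names = list(pd.unique(g))
    samples = [v[g == name].to_numpy() for name in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    if method == "mann_whitney":
        if len(names) != 2:
            raise ValueError("Mann–Whitney compares exactly two groups")
        a, b = samples
        exact = len(a) <= 8 and len(b) <= 8 and len(np.unique(np.r_[a, b])) == len(a) + len(b)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return GroupComparison(
            test="mann_whitney", statistic=float(res.statistic),
            p_value=float(res.pvalue), pairwise=None, letters=None,
        )
    if method != "anova_tukey":
        raise ValueError(f"unknown method: {method}")
    if len(names) < 2:
        raise ValueError("ANOVA needs at least two groups")
    fres = stats.f_oneway(*samples)
    grand = v.to_numpy()
    if np.allclose(grand, grand[0]):
        fval, pval = 0.0, 1.0
    else:
        fval, pval = float(fres.statistic), float(fres.pvalue)
    if np.isnan(fval):
        fval, pval = 0.0, 1.0
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tuk = pairwise_tukeyhsd(v.to_numpy(), g.to_numpy(), alpha=alpha)
    pair_tab = pd.DataFrame(
        tuk.summary().data[1:], columns=tuk.summary().data[0]
    )
    means = {name: float(np.mean(s)) for name, s in zip(names, samples)}
    nonsig = set()
    for _, row in pair_tab.iterrows():
        if not bool(row["reject"]):
            nonsig.add((row["group1"], row["group2"]))
    letters = _compact_letters(names, means, nonsig)
    return GroupComparison(
        test="anova_tukey", statistic=fval, p_value=pval,
        pairwise=pair_tab, letters=letters,
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    percent_variance: np.ndarray


def pca_scores(
    traits: pd.DataFrame,
    preprocess: str | None = "standardise",
    length_col: str | None = None,
) -> PcaResult:
    """PCA of a trait table after the chosen preprocessing.

    ``log_length_norm`` log-transforms every trait and subtracts the log of
    the reference length column (allometric normalisation; the length column
    itself is excluded).  ``standardise`` z-scores columns.  Complete-case
    rows only; constant columns are dropped with a warning.
    """
    df = pd.DataFrame(traits).dropna()
    if preprocess == "log_length_norm":
        if length_col is None or length_col not in df.columns:
            raise ValueError("log_length_norm needs a valid length_col")
        if (df <= 0).any().any():
            raise ValueError("log transform requires strictly positive traits")
        logs = np.log(df)
        df = logs.drop(columns=[length_col]).sub(logs[length_col], axis=0)
    elif preprocess == "standardise":
        df = (df - df.mean()) / df.std(ddof=1)
    elif preprocess is not None:
        raise ValueError(f"unknown preprocess: {preprocess}")
    const = df.columns[df.std(ddof=0).fillna(0.0) < 1e-12]
    if len(const):
        warnings.warn(f"constant columns dropped: {list(const)}", stacklevel=2)
        df = df.drop(columns=list(const))
    if df.shape[1] == 0:
        raise ValueError("no variable traits left for PCA")
    from sklearn.decomposition import PCA

    k = min(len(df) - 1, df.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(df.to_numpy(dtype=float))
    axes = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=df.index, columns=axes),
        loadings=pd.DataFrame(pca.components_.T, index=df.columns, columns=axes),
        percent_variance=100.0 * pca.explained_variance_ratio_,
    )
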