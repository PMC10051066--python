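"""Diversity, differentiation, ordination and matrix-correlation statistics.

All differentiation statistics work on squared-Euclidean distances between
binary dominant-marker rows, the standard molecular distance for AMOVA on
band data.  Fixation indices (Φ_ST-type) partition that molecular variance
among and within populations; significance comes from permuting individuals
among populations.  PCoA is classical metric scaling of the same distances,
and the Mantel test correlates two distance matrices with joint row/column
permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "DiversityIndices",
    "PcoaResult",
    "MantelResult",
    "pairwise_distance",
    "amova",
    "pairwise_fst",
    "diversity_indices",
    "pcoa",
    "mantel",
    "population_proximity",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    values: np.ndarray
    ids: pd.Index

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v
        self.ids = pd.Index(self.ids)
        if len(self.ids) != v.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def pairwise_distance(matrix: pd.DataFrame, metric: str = "sq_euclidean") -> DistanceMatrix:
    """Squared-Euclidean distances between individuals (rows).

    Missing cells: each pair is compared over loci scored in both, and the
    raw sum is rescaled by L / L_shared so pairs with different completeness
    stay comparable.  A pair sharing zero loci is an error.
    """
    if metric != "sq_euclidean":
        raise ValueError(f"unsupported metric: {metric}")
    X = np.asarray(matrix, dtype=float)
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    mask = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    # raw d_ij over shared loci: expand (x_i - x_j)^2 restricted to both-scored
    sq = X0**2
    shared = mask @ mask.T
    raw = (sq * mask) @ mask.T + mask @ (sq * mask).T - 2 * (X0 * mask) @ (X0 * mask).T
    if (shared[np.triu_indices(n, 1)] == 0).any():
        iu = np.triu_indices(n, 1)
        bad = np.argwhere(shared[iu] == 0)[0]
        i, j = iu[0][bad[0]], iu[1][bad[0]]
        raise ValueError(
            f"individuals {matrix.index[i]!r} and {matrix.index[j]!r} share no scored loci"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = raw * (L / shared)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else pd.Index(range(n))
    return DistanceMatrix(d, idx)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """Variance components and Φ-statistics from a (possibly two-level) AMOVA.

    ``sigma2`` holds the raw (possibly negative) components; percentages and
    the reported Φ use components truncated at zero, so
    ``phi_st == percent_variation["among_populations"] / 100`` (one-level).
    """

    ssd: dict
    df: dict
    sigma2: dict
    percent_variation: dict
    phi_st: float
    p_value: float
    n_permutations: int
    phi_ct: float | None = None
    phi_sc: float | None = None
    p_ct: float | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for level in self.sigma2:
            rows.append(
                dict(
                    source=level,
                    ssd=self.ssd.get(level, np.nan),
                    df=self.df.get(level, np.nan),
                    sigma2=self.sigma2[level],
                    percent_variation=self.percent_variation[level],
                )
            )
        return pd.DataFrame(rows)


def _ssd_within_groups(d: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    total = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        total += d[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


def _one_level_components(d: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    N = d.shape[0]
    P = len(sizes)
    ssd_total = d.sum() / (2.0 * N)
    ssd_within = _ssd_within_groups(d, codes, P)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = P - 1, N - P
    ms_within = ssd_within / df_within if df_within > 0 else 0.0
    ms_among = ssd_among / df_among
    n_prime = (N - (sizes**2).sum() / N) / (P - 1)
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n_prime
    return ssd_total, ssd_within, ssd_among, sigma_among, sigma_within


def _phi_from(sigma_among: float, sigma_within: float) -> float:
    """Reported Phi: negative components truncated to zero."""
    sa, sw = max(sigma_among, 0.0), max(sigma_within, 0.0)
    tot = sa + sw
    return 0.0 if tot == 0 else sa / tot


# Permutation statistics: with SSD_total invariant under relabelling, a
# smaller within-group SSD is exactly a larger Phi, so the one-level (and
# two-level Phi_ST) tests compare SSD_within directly — a continuous,
# untruncated statistic (truncated Phi would pile null p-values at 1).


def amova(
    dist: DistanceMatrix,
    populations,
    groups=None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Excoffier-style AMOVA on a squared-distance matrix.

    One level (populations only): sums of squared deviations come directly
    from the distances, variance components from the expected mean squares
    with unequal sample sizes, and Φ_ST's permutation p-value from shuffling
    individuals among populations, p = (#{Φ* >= Φ} + 1) / (n_perm + 1).

    With ``groups`` (a mapping population -> group) a higher among-groups
    level is added (Φ_CT, Φ_SC); its p-value permutes whole populations among
    groups.
    """
    pops = pd.Series(populations)
    if isinstance(populations, (pd.Series, dict)) and set(pops.index) == set(dist.ids):
        pops = pops.reindex(dist.ids)
    if len(pops) != dist.n or pops.isna().any():
        raise ValueError("populations must label every individual")
    codes, uniques = pd.factorize(pops.to_numpy())
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniques[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"populations of size < 2: {small}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = dist.values
    N, P = d.shape[0], len(sizes)
    rng = np.random.default_rng(seed)

    if groups is None:
        ssd_total, ssd_within, ssd_among, s_a, s_w = _one_level_components(d, codes, sizes)
        phi_obs = _phi_from(s_a, s_w)
        if ssd_total <= 1e-12:  # degenerate: all-identical individuals
            return AmovaResult(
                ssd=dict(among_populations=0.0, within_populations=0.0, total=0.0),
                df=dict(among_populations=P - 1, within_populations=N - P, total=N - 1),
                sigma2=dict(among_populations=0.0, within_populations=0.0),
                percent_variation=dict(among_populations=0.0, within_populations=100.0),
                phi_st=0.0,
                p_value=1.0,
                n_permutations=n_perm,
            )
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _ssd_within_groups(d, perm, P) <= ssd_within + 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        sa_t, sw_t = max(s_a, 0.0), max(s_w, 0.0)
        tot_t = sa_t + sw_t
        pct_a = 0.0 if tot_t == 0 else 100.0 * sa_t / tot_t
        return AmovaResult(
            ssd=dict(among_populations=ssd_among, within_populations=ssd_within,
                     total=ssd_total),
            df=dict(among_populations=P - 1, within_populations=N - P, total=N - 1),
            sigma2=dict(among_populations=s_a, within_populations=s_w),
            percent_variation=dict(among_populations=pct_a,
                                   within_populations=100.0 - pct_a),
            phi_st=phi_obs,
            p_value=p,
            n_permutations=n_perm,
        )

    # two-level design: groups of populations
    gmap = dict(groups) if not isinstance(groups, dict) else groups
    pop_group = np.array([gmap[uniques[c]] for c in range(P)])
    gcodes_pop, gunique = pd.factorize(pop_group)
    G = len(gunique)
    if G < 2:
        raise ValueError("need at least two groups")
    ind_group = gcodes_pop[codes]

    def _two_level(codes_i, gcodes_p):
        ind_g = gcodes_p[codes_i]
        sizes_p = np.bincount(codes_i, minlength=P)
        ssd_total = d.sum() / (2.0 * N)
        ssd_wp = _ssd_within_groups(d, codes_i, P)
        ssd_wg = _ssd_within_groups(d, ind_g, G)
        ssd_ap_wg = ssd_wg - ssd_wp
        ssd_ag = ssd_total - ssd_wg
        df_ag, df_ap, df_wp = G - 1, P - G, N - P
        n_g = np.bincount(ind_g, minlength=G)
        sum_npg2_over_ng = sum(
            (sizes_p[gcodes_p == g] ** 2).sum() / n_g[g] for g in range(G)
        )
        n1 = (N - sum_npg2_over_ng) / df_ap
        n2 = (sum_npg2_over_ng - (sizes_p**2).sum() / N) / df_ag
        n3 = (N - (n_g**2).sum() / N) / df_ag
        ms_wp = ssd_wp / df_wp
        ms_ap = ssd_ap_wg / df_ap
        ms_ag = ssd_ag / df_ag
        s_c = ms_wp
        s_b = (ms_ap - s_c) / n1
        s_a = (ms_ag - s_c - n2 * s_b) / n3
        return (ssd_total, ssd_wp, ssd_ap_wg, ssd_ag, s_a, s_b, s_c,
                dict(among_groups=df_ag, among_populations_within_groups=df_ap,
                     within_populations=df_wp))

    (ssd_total, ssd_wp, ssd_ap, ssd_ag, s_a, s_b, s_c, dfs) = _two_level(
        codes, gcodes_pop
    )
    sa_t, sb_t, sc_t = (max(s, 0.0) for s in (s_a, s_b, s_c))
    tot = sa_t + sb_t + sc_t
    pct = (
        dict(among_groups=0.0, among_populations_within_groups=0.0,
             within_populations=100.0)
        if tot == 0
        else dict(
            among_groups=100 * sa_t / tot,
            among_populations_within_groups=100 * sb_t / tot,
            within_populations=100 * sc_t / tot,
        )
    )
    phi_st = 0.0 if tot == 0 else (sa_t + sb_t) / tot
    phi_ct = 0.0 if tot == 0 else sa_t / tot
    phi_sc = 0.0 if (sb_t + sc_t) == 0 else sb_t / (sb_t + sc_t)

    # p for Phi_CT: permute whole populations among groups; the raw
    # among-groups variance component is the statistic
    count_ct = 0
    for _ in range(n_perm):
        perm_g = rng.permutation(gcodes_pop)
        _, _, _, _, ps_a, _, _, _ = _two_level(codes, perm_g)
        if ps_a >= s_a - 1e-12:
            count_ct += 1
    p_ct = (count_ct + 1) / (n_perm + 1)
    # p for Phi_ST: permute individuals among populations (SSD_within stat)
    count_st = 0
    for _ in range(n_perm):
        perm_i = rng.permutation(codes)
        if _ssd_within_groups(d, perm_i, P) <= ssd_wp + 1e-12:
            count_st += 1
    p_st = (count_st + 1) / (n_perm + 1)
    return AmovaResult(
        ssd=dict(among_groups=ssd_ag, among_populations_within_groups=ssd_ap,
                 within_populations=ssd_wp, total=ssd_total),
        df={**dfs, "total": N - 1},
        sigma2=dict(among_groups=s_a, among_populations_within_groups=s_b,
                    within_populations=s_c),
        percent_variation=pct,
        phi_st=phi_st,
        p_value=p_st,
        n_permutations=n_perm,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        p_ct=p_ct,
    )


def pairwise_fst(
    matrix: pd.DataFrame,
    populations,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Population-pairwise Φ_ST with permutation significance flags.

    Each pair gets its own two-population AMOVA on the pair's individuals;
    negative estimates are reported as 0.  Returns (fst, p_values, significant)
    with significance at p <= alpha.
    """
    pops = pd.Series(populations, index=matrix.index)
    names = list(pd.unique(pops))
    k = len(names)
    fst = pd.DataFrame(0.0, index=names, columns=names)
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ids = matrix.index[(pops == names[i]) | (pops == names[j])]
            sub = matrix.loc[ids]
            d = pairwise_distance(sub)
            res = amova(d, pops.loc[ids], n_perm=n_perm,
                        seed=int(rng.integers(2**31 - 1)))
            fst.iloc[i, j] = fst.iloc[j, i] = max(res.phi_st, 0.0)
            pvals.iloc[i, j] = pvals.iloc[j, i] = res.p_value
    sig = (pvals <= alpha).fillna(False)
    np.fill_diagonal(sig.values, False)
    return fst, pvals, sig


# ---------------------------------------------------------------------------
# Diversity


@dataclass
class DiversityIndices:
    """Per-population dominant-marker diversity summaries.

    ``per_population``: n, n_loci and mean ± SD over loci of the effective
    number of alleles (Ne), Nei's gene diversity (h) and Shannon's
    information index (I).  ``per_locus`` maps population -> per-locus table.
    """

    per_population: pd.DataFrame
    per_locus: dict


def _locus_diversity(x: float, n: int) -> tuple[float, float, float, float]:
    """(q_hat, Ne, h, I) from the null-phenotype frequency x at one locus."""
    if x <= 0.0:
        q = 0.0
    elif x >= 1.0:
        q = 1.0
    else:
        q = float(np.clip(np.sqrt(x), 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    p = 1.0 - q
    ne = 1.0 / (p**2 + q**2)
    h = 1.0 - p**2 - q**2
    i = 0.0
    for f in (p, q):
        if f > 0:
            i -= f * np.log(f)
    return q, ne, h, i


def diversity_indices(
    matrix: pd.DataFrame, populations, estimator: str = "sqrt"
) -> DiversityIndices:
    """Ne, Nei's h and Shannon's I per population from dominant 0/1 data.

    The recessive (null) allele frequency is estimated per locus as the
    square root of the null-phenotype frequency, floored/capped at 1/(2n)
    for polymorphic loci; monomorphic loci return exact Ne=1, h=0, I=0.
    """
    if estimator != "sqrt":
        raise ValueError(f"unknown estimator: {estimator}")
    pops = pd.Series(populations, index=matrix.index)
    rows = []
    per_locus: dict = {}
    for name, idx in pops.groupby(pops).groups.items():
        sub = matrix.loc[idx]
        n_ind = len(idx)
        if n_ind < 2:
            raise ValueError(f"population {name!r} has fewer than 2 individuals")
        recs = []
        for locus in sub.columns:
            col = sub[locus].dropna()
            if len(col) == 0:
                continue
            x = float((col == 0).mean())
            q, ne, h, i = _locus_diversity(x, len(col))
            recs.append(dict(locus=locus, x_null=x, q_hat=q, Ne=ne, h=h, I=i))
        tab = pd.DataFrame(recs).set_index("locus")
        per_locus[name] = tab
        rows.append(
            dict(
                population=name,
                n=n_ind,
                n_loci=len(tab),
                Ne_mean=tab["Ne"].mean(), Ne_sd=tab["Ne"].std(ddof=1),
                h_mean=tab["h"].mean(), h_sd=tab["h"].std(ddof=1),
                I_mean=tab["I"].mean(), I_sd=tab["I"].std(ddof=1),
            )
        )
    return DiversityIndices(
        per_population=pd.DataFrame(rows).set_index("population"),
        per_locus=per_locus,
    )


# ---------------------------------------------------------------------------
# Ordination & Mantel


@dataclass
class PcoaResult:
    eigenvalues: np.ndarray
    coordinates: pd.DataFrame  # individuals x axes, positive eigenvalues only
    percent_variance: np.ndarray  # per positive axis, sums to 100

    @property
    def n_negative(self) -> int:
        return int((self.eigenvalues < -1e-10).sum())


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling (principal coordinates) of squared distances.

    The input is treated as a matrix of *squared* dissimilarities (the
    package's standard squared-Euclidean distance), so Gower centring is
    B = -0.5 J D J.  Axes with positive eigenvalues carry coordinates; the
    percent variance is each positive eigenvalue over the positive total.
    Negative eigenvalues are reported, not dropped silently.
    """
    if dist.n < 3:
        raise ValueError("PCoA needs at least 3 individuals")
    d = dist.values
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = 100.0 * evals[pos] / evals[pos].sum()
    axes = [f"PCo{i + 1}" for i in range(pos.sum())]
    return PcoaResult(
        eigenvalues=evals,
        coordinates=pd.DataFrame(coords, index=dist.ids, columns=axes),
        percent_variance=pct,
    )


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    alternative: str = "greater"


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the p-value
    permutes rows and columns of the second matrix jointly,
    p = (#{r* >= r} + 1) / (n_perm + 1) for the one-sided (greater) test
    appropriate to isolation-by-distance.
    """
    if d1.n != d2.n:
        raise ValueError("matrices differ in size")
    if not d1.ids.equals(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("matrix labels do not match")
        # align d2 to d1's ordering
        pos = [list(d2.ids).index(i) for i in d1.ids]
        d2 = DistanceMatrix(d2.values[np.ix_(pos, pos)], d1.ids)
    iu = np.triu_indices(d1.n, k=1)
    x, y = d1.values[iu], d2.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Mantel r undefined for a constant distance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    v2 = d2.values
    for _ in range(n_perm):
        perm = rng.permutation(d1.n)
        r_p = np.corrcoef(x, v2[np.ix_(perm, perm)][iu])[0, 1]
        if alternative == "greater":
            hit = r_p >= r_obs - 1e-12
        elif alternative == "less":
            hit = r_p <= r_obs + 1e-12
        else:
            hit = abs(r_p) >= abs(r_obs) - 1e-12
        count += bool(hit)
    return MantelResult(
        r=r_obs,
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        alternative=alternative,
    )


def population_proximity(traits: pd.DataFrame, populations) -> DistanceMatrix:
    """Squared-Euclidean proximity between population mean trait vectors.

    Populations without any complete trait data are excluded with a warning.
    Traits are used as given (log-transform / length-normalise upstream).
    """
    pops = pd.Series(populations, index=traits.index)
    means = traits.groupby(pops).mean()
    empty = means.index[means.isna().all(axis=1)]
    if len(empty):
        warnings.warn(f"populations without trait data excluded: {list(empty)}",
                      stacklevel=2)
        means = means.drop(index=empty)
    M = means.to_numpy()
    diff = M[:, None, :] - M[None, :, :]
    d = np.nansum(diff**2, axis=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, means.index)
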