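"""Dfdist-style FST-outlier scan for dominant markers.

Dominant bands hide heterozygotes, so per-locus allele frequencies are first
estimated with Zhivotovsky's Bayesian method: a Beta prior fitted by moments
to the across-locus distribution of null-phenotype frequencies, then the
posterior mean of q = sqrt(x) given each locus's null counts.  Observed loci
are placed on the (He, FST) plane and compared against a neutral envelope
simulated from a Balding–Nichols island model calibrated to the dataset's
mean FST; loci above the upper-tail quantile at their heterozygosity are
flagged, optionally after one trim-and-recalibrate pass ("neutral FST").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln

__all__ = [
    "BetaPrior",
    "NeutralEnvelope",
    "OutlierScanResult",
    "fit_beta_prior",
    "fit_population_priors",
    "zhivotovsky_frequencies",
    "locus_fst",
    "simulate_envelope",
    "detect_outliers",
    "scan",
]


@dataclass
class BetaPrior:
    """Beta(a, b) prior on the null-phenotype frequency x = q^2."""

    a: float
    b: float


def fit_beta_prior(null_counts: np.ndarray, sample_sizes: np.ndarray) -> BetaPrior:
    """Method-of-moments Beta prior for null-phenotype frequencies.

    Corrects the across-locus variance of the observed frequencies x̂ = m/n
    for binomial sampling: Var(x̂) ≈ σ²(1 − 1/n̄) + x̄(1 − x̄)/n̄ with n̄ the
    mean sample size, solved for the latent variance σ².  Degenerate inputs
    (all loci monomorphic) are an error; a non-positive corrected variance is
    floored at a small fraction of x̄(1 − x̄) with a warning.
    """
    m = np.asarray(null_counts, dtype=float)
    n = np.broadcast_to(np.asarray(sample_sizes, dtype=float), m.shape)
    x = m / n
    xbar = float(x.mean())
    if xbar <= 0.0 or xbar >= 1.0:
        raise ValueError("all loci monomorphic: Beta prior cannot be fitted")
    v = float(x.var(ddof=1)) if len(x) > 1 else 0.0
    nbar = float(n.mean())
    sigma2 = (v - xbar * (1 - xbar) / nbar) / (1.0 - 1.0 / nbar)
    floor = 1e-4 * xbar * (1 - xbar)
    if sigma2 < floor:
        warnings.warn("across-locus variance at/below sampling noise; prior variance "
                      "floored", stacklevel=2)
        sigma2 = floor
    sigma2 = min(sigma2, 0.95 * xbar * (1 - xbar))
    t = xbar * (1 - xbar) / sigma2 - 1.0
    return BetaPrior(a=xbar * t, b=(1 - xbar) * t)


def _posterior_mean_q(prior: BetaPrior, m, n) -> np.ndarray:
    """E[sqrt(x) | m null of n] under x ~ Beta(a, b), m ~ Binom(n, x).

    The posterior of x is Beta(a+m, b+n−m); the expectation of sqrt(x) has
    the closed Beta-function form evaluated on the log scale.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    a_post = prior.a + m
    b_post = prior.b + n - m
    return np.exp(betaln(a_post + 0.5, b_post) - betaln(a_post, b_post))


def fit_population_priors(
    matrix: pd.DataFrame, populations, pooled_prior: bool = False
) -> dict:
    """Fit the Zhivotovsky Beta prior per population on a binary matrix."""
    pops = pd.Series(populations, index=matrix.index)
    names = list(pd.unique(pops))
    counts = {}
    for name in names:
        sub = matrix.loc[pops == name]
        scored = sub.notna().sum(axis=0).to_numpy(dtype=float)
        nulls = (sub == 0).sum(axis=0).to_numpy(dtype=float)
        counts[name] = (nulls, scored)
    if pooled_prior:
        all_m = np.concatenate([counts[n][0] for n in names])
        all_n = np.concatenate([counts[n][1] for n in names])
        prior = fit_beta_prior(all_m, all_n)
        return {n: prior for n in names}
    return {n: fit_beta_prior(*counts[n]) for n in names}


def zhivotovsky_frequencies(
    matrix: pd.DataFrame,
    populations,
    pooled_prior: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus, per-population recessive-allele frequencies q̂.

    The Beta prior is fitted per population by default (each population's
    loci share one prior); ``pooled_prior`` fits a single prior across all
    populations' null frequencies instead.  Returns (q_hat, n_scored), loci
    as rows and populations as columns; q̂ is strictly inside (0, 1).
    """
    pops = pd.Series(populations, index=matrix.index)
    names = list(pd.unique(pops))
    loci = matrix.columns
    qhat = pd.DataFrame(index=loci, columns=names, dtype=float)
    nmat = pd.DataFrame(index=loci, columns=names, dtype=float)
    counts = {}
    for name in names:
        sub = matrix.loc[pops == name]
        if len(sub) < 2:
            raise ValueError(f"population {name!r} has fewer than 2 individuals")
        scored = sub.notna().sum(axis=0).to_numpy(dtype=float)
        nulls = (sub == 0).sum(axis=0).to_numpy(dtype=float)
        counts[name] = (nulls, scored)
        nmat[name] = scored
    if pooled_prior:
        all_m = np.concatenate([counts[n][0] for n in names])
        all_n = np.concatenate([counts[n][1] for n in names])
        prior = fit_beta_prior(all_m, all_n)
        priors = {n: prior for n in names}
    else:
        priors = {n: fit_beta_prior(*counts[n]) for n in names}
    for name in names:
        nulls, scored = counts[name]
        qhat[name] = _posterior_mean_q(priors[name], nulls, scored)
    return qhat, nmat


def locus_fst(q_hat: pd.DataFrame, sample_sizes: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-locus heterozygosity and FST from per-population frequencies.

    He (= Hs) is the unweighted mean within-population 2q(1−q); Ht comes from
    the sample-size-weighted pooled frequency; FST = (Ht − Hs)/Ht.  Loci with
    Ht = 0 are skipped with a note column.
    """
    q = np.asarray(q_hat, dtype=float)
    if q.shape[1] < 2:
        raise ValueError("need at least two populations")
    n = np.broadcast_to(np.asarray(sample_sizes, dtype=float), q.shape)
    hs = (2 * q * (1 - q)).mean(axis=1)
    qbar = (q * n).sum(axis=1) / n.sum(axis=1)
    ht = 2 * qbar * (1 - qbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    out = pd.DataFrame(
        dict(He=hs, Hs=hs, Ht=ht, fst=fst),
        index=q_hat.index if isinstance(q_hat, pd.DataFrame) else None,
    )
    out["note"] = np.where(ht > 0, "", "Ht=0: skipped")
    return out


@dataclass
class NeutralEnvelope:
    """Binned quantiles of simulated neutral FST across the He range.

    Bins partition the simulated He range into equal-count intervals; a
    locus is compared against the quantiles of the bin its He falls in
    (step-function lookup).  Interpolating across bins is deliberately
    avoided: the Bayesian frequency estimator concentrates near-monomorphic
    loci at a few He atoms, where the conditional FST distribution is
    discontinuous and interpolation would mis-calibrate the tail.
    """

    he_centers: np.ndarray
    he_edges: np.ndarray  # inner bin boundaries, length n_bins - 1
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    confidence: float
    n_sim: int
    target_mean_fst: float
    f_input: float  # calibrated Balding–Nichols F actually simulated
    realized_mean_fst: float
    simulated: pd.DataFrame | None = None

    def quantiles_at(self, he: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        he = np.asarray(he, dtype=float)
        idx = np.searchsorted(self.he_edges, he, side="right")
        return self.lower[idx], self.median[idx], self.upper[idx]


def _simulate_neutral_loci(
    f_input: float,
    sample_sizes: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
    priors: list | None = None,
) -> pd.DataFrame:
    """Simulate dominant loci under the Balding–Nichols island model.

    Ancestral null-allele frequency ~ U(0.01, 0.99); population frequencies
    ~ Beta(p(1−F)/F, (1−p)(1−F)/F); null phenotypes ~ Binom(n_i, q_i²);
    statistics are then computed exactly as for observed data.  ``priors``
    (one BetaPrior per population, usually fitted on the observed dataset)
    fixes the q̂ mapping so simulated and observed loci share the same
    estimator; without it a prior is refitted on the simulated loci.
    """
    n_pops = len(sample_sizes)
    p = rng.uniform(0.01, 0.99, size=n_sim)
    ratio = (1.0 - f_input) / f_input
    a = np.clip(p * ratio, 1e-6, None)[:, None]
    b = np.clip((1.0 - p) * ratio, 1e-6, None)[:, None]
    q = rng.beta(a, b, size=(n_sim, n_pops))
    n = np.broadcast_to(np.asarray(sample_sizes, dtype=float), (n_sim, n_pops))
    m = rng.binomial(n.astype(int), q**2)
    qhat = np.empty_like(q)
    for j in range(n_pops):
        prior = priors[j] if priors is not None else fit_beta_prior(m[:, j], n[:, j])
        qhat[:, j] = _posterior_mean_q(prior, m[:, j], n[:, j])
    tab = locus_fst(pd.DataFrame(qhat), pd.DataFrame(n))
    return tab.dropna(subset=["fst"])


def simulate_envelope(
    target_mean_fst: float,
    sample_sizes,
    n_sim: int = 10000,
    confidence: float = 0.99,
    seed: int | None = None,
    n_bins: int = 25,
    min_bin_count: int = 50,
    calibrate: bool = True,
    priors: list | None = None,
) -> NeutralEnvelope:
    """Simulate the neutral FST envelope conditional on heterozygosity.

    ``calibrate`` runs short trial batches adjusting the Beta-model F until
    the realized mean simulated FST matches the target (Fdist's "force mean
    FST" behaviour); the final full simulation then has mean FST at the
    target up to Monte-Carlo error.  The envelope is formed from equal-count
    He bins; the upper bound is the one-sided ``confidence`` quantile.  Bins
    thinner than ``min_bin_count`` are widened by merging with a warning.
    """
    if not 0.0 < target_mean_fst < 1.0:
        raise ValueError("target_mean_fst must be in (0, 1)")
    sizes = np.asarray(sample_sizes, dtype=float)
    if len(sizes) < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)
    f_input = float(target_mean_fst)
    if calibrate:
        batch = min(n_sim, 3000)
        for _ in range(6):
            trial = _simulate_neutral_loci(f_input, sizes, batch, rng, priors=priors)
            realized = float(trial["fst"].mean())
            if abs(realized - target_mean_fst) < 0.01 * target_mean_fst:
                break
            f_input = float(np.clip(f_input * target_mean_fst / max(realized, 1e-6),
                                    1e-5, 0.9))
    sim = _simulate_neutral_loci(f_input, sizes, n_sim, rng, priors=priors)
    he = sim["He"].to_numpy()
    fst = sim["fst"].to_numpy()
    order = np.argsort(he)
    he, fst = he[order], fst[order]
    n_eff = len(he)
    bins = max(1, min(n_bins, n_eff // max(min_bin_count, 1)))
    if bins < n_bins:
        warnings.warn(
            f"too few simulated loci for {n_bins} bins; widened to {bins}",
            stacklevel=2,
        )
    edges = np.linspace(0, n_eff, bins + 1).astype(int)
    centers, lo, med, up = [], [], [], []
    inner_edges = []
    alpha = 1.0 - confidence
    for k in range(bins):
        sl = slice(edges[k], edges[k + 1])
        centers.append(np.median(he[sl]))
        lo.append(np.quantile(fst[sl], alpha))
        med.append(np.quantile(fst[sl], 0.5))
        up.append(np.quantile(fst[sl], confidence))
        if k:  # boundary between bin k-1 and bin k
            inner_edges.append(0.5 * (he[edges[k] - 1] + he[edges[k]]))
    return NeutralEnvelope(
        he_centers=np.array(centers),
        he_edges=np.array(inner_edges),
        lower=np.array(lo),
        median=np.array(med),
        upper=np.array(up),
        confidence=confidence,
        n_sim=n_sim,
        target_mean_fst=target_mean_fst,
        f_input=f_input,
        realized_mean_fst=float(np.mean(fst)),
        simulated=sim,
    )


@dataclass
class OutlierScanResult:
    """Per-locus flags against the neutral envelope, both scan passes."""

    table: pd.DataFrame
    envelope_initial: NeutralEnvelope
    envelope_final: NeutralEnvelope
    mean_fst_initial: float
    neutral_mean_fst: float
    trimmed: bool

    @property
    def outliers(self) -> pd.Index:
        return self.table.index[self.table["flagged"]]


def detect_outliers(
    observed: pd.DataFrame,
    envelope: NeutralEnvelope,
    sample_sizes=None,
    trim_and_recalibrate: bool = True,
    seed: int | None = None,
    priors: list | None = None,
) -> OutlierScanResult:
    """Flag loci with FST above the envelope's upper tail at their He.

    With ``trim_and_recalibrate``, flagged loci are removed, the mean FST of
    the remainder becomes a new target, the envelope is re-simulated once,
    and all loci are re-flagged against it (the "neutral FST" behaviour).
    Low-tail status is reported (``below_lower``) but never flagged.
    """
    obs = observed.dropna(subset=["fst"]).copy()
    if len(obs) == 0:
        raise ValueError("no observed loci with defined FST")
    he = obs["He"].to_numpy()
    fst = obs["fst"].to_numpy()
    lo1, med1, up1 = envelope.quantiles_at(he)
    pass1 = fst > up1
    env_final = envelope
    trimmed = False
    if trim_and_recalibrate and pass1.any() and pass1.sum() < len(obs):
        neutral_mean = float(fst[~pass1].mean())
        if 0.0 < neutral_mean < 1.0:
            trimmed = True
            sizes = sample_sizes
            env_final = simulate_envelope(
                neutral_mean,
                sizes,
                n_sim=envelope.n_sim,
                confidence=envelope.confidence,
                seed=seed,
                priors=priors,
            )
    lo2, med2, up2 = env_final.quantiles_at(he)
    final = fst > up2
    table = obs.assign(
        upper_q=up2,
        median_q=med2,
        lower_q=lo2,
        flagged_pass1=pass1,
        flagged=final,
        below_lower=fst < lo2,
    )
    return OutlierScanResult(
        table=table,
        envelope_initial=envelope,
        envelope_final=env_final,
        mean_fst_initial=float(fst.mean()),
        neutral_mean_fst=env_final.target_mean_fst,
        trimmed=trimmed,
    )


def scan(
    matrix: pd.DataFrame,
    populations,
    n_sim: int = 10000,
    confidence: float = 0.99,
    seed: int | None = None,
    trim_and_recalibrate: bool = True,
    force_mean_fst: float | None = None,
    pooled_prior: bool = False,
) -> OutlierScanResult:
    """Full scan: estimate frequencies, place loci on (He, FST), flag outliers.

    ``force_mean_fst`` skips the data-driven target (and the recalibration
    pass) and simulates the envelope at the supplied mean FST.
    """
    qhat, nmat = zhivotovsky_frequencies(matrix, populations, pooled_prior=pooled_prior)
    summary = locus_fst(qhat, nmat)
    pops = pd.Series(populations, index=matrix.index)
    names = list(pd.unique(pops))
    sizes = pops.value_counts().reindex(names).to_numpy()
    # the envelope reuses the observed-data priors so simulated and observed
    # loci pass through the same estimator (conditioning the scan on the
    # fitted q-hat mapping)
    prior_map = fit_population_priors(matrix, populations, pooled_prior=pooled_prior)
    priors = [prior_map[n] for n in names]
    rng = np.random.default_rng(seed)
    if force_mean_fst is not None:
        target = float(force_mean_fst)
        trim = False
    else:
        target = float(summary["fst"].dropna().mean())
        target = float(np.clip(target, 1e-4, 0.99))
        trim = trim_and_recalibrate
    env = simulate_envelope(
        target, sizes, n_sim=n_sim, confidence=confidence,
        seed=int(rng.integers(2**31 - 1)), priors=priors,
    )
    return detect_outliers(
        summary, env, sample_sizes=sizes, trim_and_recalibrate=trim,
        seed=int(rng.integers(2**31 - 1)), priors=priors,
    )
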