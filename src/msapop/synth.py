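"""Synthetic MSAP study generator.

Emulates the statistical structure of a multi-population organotin-pollution
survey of a marine gastropod: seven populations along a TBT gradient, a few
hundred methylation-susceptible loci (MSL) whose population frequencies
follow a Balding–Nichols island model at a configurable epigenetic FST, a
smaller panel of genetic loci (NML) at a lower FST, population-level
TBT-driven hypomethylation, an ordinal imposex response generated from a
proportional-odds model, a soft-tissue-mass linear model, replicate plates
with scoring noise, and optional planted high-FST outlier loci.  Every draw
flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .qc import ReplicatePair
from .scoring import FragmentProfilePair

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticStudy", "generate_study",
           "make_toy_fixture", "simulate_ordinal"]


@dataclass
class SyntheticConfig:
    """Study-design parameters; defaults mirror the emulated survey.

    TBT means (ng Sn g^-1 dry weight) follow the reported gradient: two
    lowly polluted sites (1.8, 2.6), one intermediate (10.7), four highly
    polluted sites spanning 21.4–43.1.  Counts of polymorphic loci (355 MSL,
    43 NML), sample size (7 x 30), the epigenetic/genetic FST pair
    (0.026 / 0.010) and population-level hypomethylation are all emulated.
    """

    n_pops: int = 7
    n_per_pop: int = 30
    n_msl: int = 355
    n_nml: int = 43
    fst_epi: float = 0.026
    fst_gen: float = 0.010
    nml_null_range: tuple = (0.12, 0.20)  # ancestral null-allele frequency span
    pop_tbt: tuple = (1.8, 2.6, 10.7, 21.4, 27.5, 34.9, 43.1)
    tbt_lognorm_sigma: float = 0.5
    tbt_measured_per_pop: int = 9
    methylation_slope: float = -0.008  # logit shift per ng Sn g^-1 (population level)
    methylation_leak: float = 0.0  # individual-level slope (null by default)
    state_ratio: tuple = (0.4, 0.4, 0.2)  # H : I : F split of methylated mass
    imposex_beta: tuple = (0.03, -47.17)  # (beta_TBT, beta_methylation)
    imposex_cutpoints: tuple = (-23.3, -22.6, -21.9, -20.4, -19.8, -19.2, -18.6)
    mass_intercept: float = 18.0
    mass_slopes: tuple = (0.04, -10.0, 0.25)  # TBT, methylation, imposex
    mass_noise_sd: float = 2.0
    plate_error_rate: float = 0.021
    irreproducible_shift_rate: float = 0.45
    n_replicate_samples: int = 24
    n_junk_fragments: int = 30
    n_planted_outliers: int = 0
    planted_freqs: tuple = (0.05, 0.95)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fst_epi < 1 and 0 < self.fst_gen < 1):
            raise ValueError("FST values must be in (0, 1)")
        if self.n_per_pop < 2:
            raise ValueError("n_per_pop must be >= 2")
        if len(self.pop_tbt) != self.n_pops:
            raise ValueError("pop_tbt must have one mean per population")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.state_ratio) - 1.0) > 1e-9:
            raise ValueError("state_ratio must sum to 1")
        shift = self.methylation_slope * max(self.pop_tbt)
        if not np.isfinite(expit(logit(0.5) + shift)):
            raise ValueError("methylation shift pushes frequencies out of (0,1)")
        if self.n_replicate_samples > self.n_per_pop:
            raise ValueError("replicate samples must fit inside one population")


@dataclass
class GroundTruth:
    """Everything needed to score recovery tests against the generator."""

    msl_labels: list
    nml_labels: list
    junk_labels: list
    planted_outlier_labels: list
    pop_methylated_freq: pd.DataFrame  # realized methylated-state prob, loci x pops
    expected_pop_methylation: pd.Series  # island-noise-free mean per population
    pop_null_freq: pd.DataFrame  # NML recessive-allele freq, loci x pops
    individual_methylation: pd.Series  # realized per-individual methylated fraction
    fst_epi: float
    fst_gen: float
    imposex_beta: tuple
    imposex_cutpoints: tuple
    mass_coefficients: dict
    plate_error_rate: float


@dataclass
class SyntheticStudy:
    pair: FragmentProfilePair
    replicate: ReplicatePair
    samples: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig


def simulate_ordinal(
    eta: np.ndarray, cutpoints: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw 1..K ordinal outcomes from a cumulative-logit model.

    P(y <= k) = logistic(zeta_k - eta); returns integer levels 1..K.
    """
    zeta = np.asarray(cutpoints, dtype=float)
    cum = expit(zeta[None, :] - np.asarray(eta, dtype=float)[:, None])
    u = rng.uniform(size=len(eta))
    return 1 + (u[:, None] > cum).sum(axis=1)


def _island_freqs(
    ancestral: np.ndarray, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    ratio = (1.0 - fst) / fst
    a = np.clip(ancestral * ratio, 1e-6, None)[:, None]
    b = np.clip((1.0 - ancestral) * ratio, 1e-6, None)[:, None]
    return rng.beta(a, b, size=(len(ancestral), n_pops))


def _beta_around(
    means: np.ndarray, var: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Beta draws with the given per-cell means and per-row variances.

    ``means`` is loci x pops, ``var`` per locus; a (near-)zero variance
    returns the means unchanged.
    """
    means = np.clip(means, 1e-6, 1 - 1e-6)
    out = means.copy()
    v = np.broadcast_to(np.asarray(var, dtype=float)[:, None], means.shape)
    vmax = means * (1 - means)
    v = np.minimum(v, 0.95 * vmax)
    active = v > 1e-12
    t = np.where(active, vmax / np.where(active, v, 1.0) - 1.0, 1.0)
    a = np.clip(means * t, 1e-6, None)
    b = np.clip((1 - means) * t, 1e-6, None)
    draws = rng.beta(a, b)
    out[active] = draws[active]
    return out


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full synthetic study (profiles, replicates, sample sheet).

    MSL loci: ancestral methylated-state propensity ~ U(0.1, 0.9), population
    propensities from the island Beta at ``fst_epi``, shifted on the logit
    scale by ``methylation_slope`` x population TBT; individual states are
    multinomial over {U, H, I, F} with the methylated mass split H:I:F at
    ``state_ratio``.  NML loci: recessive null-allele frequencies from the
    island Beta at ``fst_gen`` around low ancestral values (so double
    absences stay below the MSL threshold), dominant diploid sampling.
    Replicate plates rescore ``n_replicate_samples`` individuals with
    independent per-cell flips at ``plate_error_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P, n = config.n_pops, config.n_per_pop
    N = P * n
    pop_names = [f"Pop{i + 1}" for i in range(P)]
    pops = np.repeat(pop_names, n)
    sample_ids = [f"{p}_{i + 1:02d}" for p in pop_names for i in range(n)]
    tbt_pop = np.asarray(config.pop_tbt, dtype=float)

    # --- individual TBT (lognormal around the population mean) -------------
    sig = config.tbt_lognorm_sigma
    mu = np.log(tbt_pop) - sig**2 / 2.0
    tbt_ind = rng.lognormal(mean=np.repeat(mu, n), sigma=sig)

    # --- MSL loci ----------------------------------------------------------
    # The configured fst_epi is the *band-level* (methylated-indicator) AMOVA
    # target: the TBT-driven spread of population means spends part of the
    # among-population variance budget fst_epi * mu(1-mu); island Beta noise
    # supplies the remainder, so the realized multi-locus Phi_ST matches the
    # config up to Monte-Carlo error.
    n_msl = config.n_msl
    msl_labels = [f"MSL{i + 1:04d}" for i in range(n_msl)]
    anc = rng.uniform(0.1, 0.9, size=n_msl)
    shift_pop = config.methylation_slope * tbt_pop  # per population
    mu = expit(logit(anc)[:, None] + shift_pop[None, :])  # deterministic means
    w = np.full(P, n / N)
    mu_bar = mu @ w
    b_shift = ((mu - mu_bar[:, None]) ** 2) @ w
    target_b = config.fst_epi * mu_bar * (1 - mu_bar)
    # the TBT shift is a fixed effect: AMOVA's among-population component
    # estimates sum (mu_p - mu_bar)^2 / (P-1), i.e. P/(P-1) times the ddof-0
    # spread, so the budget charges it at that rate
    resid_var = target_b - b_shift * P / (P - 1)
    infeasible = resid_var < 0
    if infeasible.mean() > 0.10:
        raise ValueError(
            "infeasible config: the TBT methylation gradient alone exceeds the "
            "fst_epi among-population variance budget at most loci"
        )
    resid_var = np.clip(resid_var, 0.0, None)
    prop_shifted = _beta_around(mu, resid_var, rng)  # loci x pops
    if config.n_planted_outliers:
        k = config.n_planted_outliers
        lo, hi = config.planted_freqs
        planted_idx = rng.choice(n_msl, size=k, replace=False)
        half = P // 2
        for idx in planted_idx:
            prop_shifted[idx, :half] = lo
            prop_shifted[idx, half:] = hi
        planted_labels = [msl_labels[i] for i in sorted(planted_idx)]
    else:
        planted_labels = []
    # expand to individuals; optional individual-level leak around the pop mean
    prop_ind = prop_shifted[:, np.repeat(np.arange(P), n)]  # loci x N
    if config.methylation_leak:
        leak = config.methylation_leak * (tbt_ind - np.repeat(tbt_pop, n))
        prop_ind = expit(logit(np.clip(prop_ind, 1e-9, 1 - 1e-9)) + leak[None, :])
    methylated = rng.uniform(size=prop_ind.shape) < prop_ind  # loci x N
    r_h, r_i, r_f = config.state_ratio
    u = rng.uniform(size=prop_ind.shape)
    state = np.full(prop_ind.shape, "U", dtype=object)
    state[methylated & (u < r_h)] = "H"
    state[methylated & (u >= r_h) & (u < r_h + r_i)] = "I"
    state[methylated & (u >= r_h + r_i)] = "F"

    msl_hpa = np.where((state == "U") | (state == "H"), 1.0, 0.0)
    msl_msp = np.where((state == "U") | (state == "I"), 1.0, 0.0)

    # --- NML loci ----------------------------------------------------------
    # fst_gen is likewise the band-level AMOVA target.  Bands are dominant
    # (present unless the null allele is homozygous, prob q^2), so the island
    # variance on q is inflated by the delta-method factor (2q)^-2 to hit the
    # required among-population band variance.  Ancestral null frequencies
    # are kept low so double absences stay under the MSL threshold.
    n_nml = config.n_nml
    nml_labels = [f"NML{i + 1:04d}" for i in range(n_nml)]
    anc_q = rng.uniform(*config.nml_null_range, size=n_nml)
    y_anc = 1.0 - anc_q**2  # band presence probability
    target_b_gen = config.fst_gen * y_anc * (1 - y_anc)
    var_q = target_b_gen / (4.0 * anc_q**2)
    pop_q = np.clip(_beta_around(np.tile(anc_q[:, None], (1, P)), var_q, rng), 0.0, 1.0)
    q_ind = pop_q[:, np.repeat(np.arange(P), n)]
    present = rng.uniform(size=q_ind.shape) >= q_ind**2  # dominant band
    nml_hpa = present.astype(float)
    nml_msp = present.astype(float)

    # --- junk fragments exercising the QC filters --------------------------
    junk_labels = []
    junk_cols_hpa, junk_cols_msp, junk_sizes = [], [], []
    n_junk = config.n_junk_fragments
    for j in range(n_junk):
        label = f"JNK{j + 1:03d}"
        junk_labels.append(label)
        kind = j % 3
        if kind == 0:  # out-of-range size
            size = int(rng.integers(20, 50)) if rng.uniform() < 0.5 else int(
                rng.integers(401, 500)
            )
            col = (rng.uniform(size=N) < 0.5).astype(float)
        elif kind == 1:  # rare: singleton presence
            size = int(rng.integers(50, 401))
            col = np.zeros(N)
            col[rng.integers(N)] = 1.0
        else:  # irreproducible between plates (extra flips added later)
            size = int(rng.integers(50, 401))
            col = (rng.uniform(size=N) < 0.5).astype(float)
        junk_sizes.append(size)
        junk_cols_hpa.append(col)
        junk_cols_msp.append(col.copy())

    labels = msl_labels + nml_labels + junk_labels
    hpa = np.vstack([msl_hpa, nml_hpa] + ([np.array(junk_cols_hpa)] if n_junk else [])).T
    msp = np.vstack([msl_msp, nml_msp] + ([np.array(junk_cols_msp)] if n_junk else [])).T

    primer_pairs = ["Eco-AAG/Hpa-TCC", "Eco-ACT/Hpa-TAC", "Eco-ACG/Hpa-TAG"]
    sizes_retained = rng.integers(50, 401, size=n_msl + n_nml)
    meta = pd.DataFrame(
        dict(
            size_bp=np.concatenate([sizes_retained, np.array(junk_sizes, dtype=int)])
            if n_junk
            else sizes_retained,
            primer_pair=[primer_pairs[i % 3] for i in range(len(labels))],
            dye=["HEX" if i % 2 else "6-FAM" for i in range(len(labels))],
        ),
        index=pd.Index(labels, name="label"),
    )
    hpa_df = pd.DataFrame(hpa, index=sample_ids, columns=labels)
    msp_df = pd.DataFrame(msp, index=sample_ids, columns=labels)
    pair = FragmentProfilePair(hpa_df, msp_df, meta)

    # --- replicate plates --------------------------------------------------
    rep_ids = sample_ids[: config.n_replicate_samples]
    e = config.plate_error_rate

    def _noisy(mat: pd.DataFrame, extra_irreproducible: bool) -> pd.DataFrame:
        sub = mat.loc[rep_ids].to_numpy().copy()
        flips = rng.uniform(size=sub.shape) < e
        if extra_irreproducible and n_junk:
            # the "kind 2" junk fragments get gross plate-B frequency shifts
            for j, label in enumerate(junk_labels):
                if j % 3 == 2:
                    c = labels.index(label)
                    flips[:, c] |= (
                        rng.uniform(size=sub.shape[0]) < config.irreproducible_shift_rate
                    ) & (sub[:, c] == 0)
        sub[flips] = 1.0 - sub[flips]
        return pd.DataFrame(sub, index=rep_ids, columns=labels)

    plate_a = FragmentProfilePair(_noisy(hpa_df, False), _noisy(msp_df, False), meta)
    plate_b = FragmentProfilePair(_noisy(hpa_df, True), _noisy(msp_df, True), meta)
    replicate = ReplicatePair(plate_a, plate_b)

    # --- phenotypes --------------------------------------------------------
    meth_ind = pd.Series(methylated.mean(axis=0), index=sample_ids,
                         name="methylation_frequency")
    b_tbt, b_meth = config.imposex_beta
    eta = b_tbt * tbt_ind + b_meth * meth_ind.to_numpy()
    sex = np.where(rng.uniform(size=N) < 0.5, "F", "M")
    imposex = np.where(
        sex == "F",
        simulate_ordinal(eta, np.asarray(config.imposex_cutpoints), rng),
        np.nan,
    )
    a_tbt, a_meth, a_imp = config.mass_slopes
    imp_for_mass = np.where(np.isnan(imposex), 0.0, imposex)
    mass = (
        config.mass_intercept
        + a_tbt * tbt_ind
        + a_meth * meth_ind.to_numpy()
        + a_imp * imp_for_mass
        + rng.normal(scale=config.mass_noise_sd, size=N)
    )
    # TBT chemistry on a subset of females per population (as surveyed)
    tbt_measured = np.full(N, np.nan)
    for p_i, name in enumerate(pop_names):
        females = np.flatnonzero((pops == name) & (sex == "F"))
        take = females[: config.tbt_measured_per_pop]
        tbt_measured[take] = tbt_ind[take]

    # morphometrics: allometric around shell length, no pollution signal
    tl = rng.normal(55.0, 5.0, size=N)
    morpho = dict(
        tl_mm=tl,
        tb_mm=0.62 * tl * np.exp(rng.normal(0, 0.04, N)),
        aw_mm=0.33 * tl * np.exp(rng.normal(0, 0.05, N)),
        al_mm=0.52 * tl * np.exp(rng.normal(0, 0.05, N)),
        tm_g=0.0012 * tl**2.9 * np.exp(rng.normal(0, 0.08, N)),
    )
    # site coordinates: a small coastal box, uncorrelated with differentiation
    lat = 43.0 + rng.uniform(-0.6, 0.6, size=P)
    lon = 16.2 + rng.uniform(-0.8, 0.8, size=P)

    samples = pd.DataFrame(
        dict(
            id=sample_ids,
            population=pops,
            plate=["P1"] * N,
            sex=sex,
            imposex_level=imposex,
            tbt_ng_sn_g=tbt_measured,
            tbt_true=tbt_ind,
            dbt_ng_sn_g=tbt_measured * rng.uniform(0.8, 2.0, size=N),
            wet_mass_g=mass,
            methylation_true=meth_ind.to_numpy(),
            lat=np.repeat(lat, n),
            lon=np.repeat(lon, n),
            **morpho,
        )
    ).set_index("id")

    truth = GroundTruth(
        msl_labels=msl_labels,
        nml_labels=nml_labels,
        junk_labels=junk_labels,
        planted_outlier_labels=planted_labels,
        pop_methylated_freq=pd.DataFrame(prop_shifted, index=msl_labels,
                                         columns=pop_names),
        expected_pop_methylation=pd.Series(mu.mean(axis=0), index=pop_names),
        pop_null_freq=pd.DataFrame(pop_q, index=nml_labels, columns=pop_names),
        individual_methylation=meth_ind,
        fst_epi=config.fst_epi,
        fst_gen=config.fst_gen,
        imposex_beta=config.imposex_beta,
        imposex_cutpoints=config.imposex_cutpoints,
        mass_coefficients=dict(
            intercept=config.mass_intercept,
            tbt=a_tbt, methylation=a_meth, imposex=a_imp,
            noise_sd=config.mass_noise_sd,
        ),
        plate_error_rate=e,
    )
    return SyntheticStudy(pair=pair, replicate=replicate, samples=samples,
                          truth=truth, config=config)


def make_toy_fixture(seed: int = 7) -> SyntheticStudy:
    """Tiny hand-checkable study: 3 populations x 4 individuals x 12 loci."""
    config = SyntheticConfig(
        n_pops=3,
        n_per_pop=4,
        n_msl=8,
        n_nml=4,
        fst_epi=0.05,
        fst_gen=0.02,
        pop_tbt=(2.0, 10.0, 40.0),
        tbt_measured_per_pop=2,
        n_replicate_samples=4,
        n_junk_fragments=0,
        seed=seed,
    )
    return generate_study(config)
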