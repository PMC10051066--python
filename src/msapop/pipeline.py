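"""End-to-end orchestration: score, filter, partition, analyse, model, report.

``run_study`` drives the whole analysis on in-memory inputs (a fragment
pair, optional replicate plates, a sample sheet) and returns a
``PipelineReport`` whose ``report`` dict is JSON-serialisable and whose
``tables`` hold the underlying DataFrames.  Every stochastic stage draws its
own child seed from the config seed, so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import outliers as ol
from . import phenotype as ph
from . import popdiff as pdiff
from . import qc as qcmod
from . import scoring as sc
from .qc import ReplicatePair
from .scoring import FragmentProfilePair

__all__ = ["PipelineConfig", "PipelineReport", "run_study", "run",
           "validate_report", "geographic_distances"]


@dataclass
class PipelineConfig:
    """Thresholds and permutation counts; defaults mirror the study design."""

    msl_threshold: float = 0.05
    min_size: int = 50
    max_size: int = 400
    min_rfu: float = 100.0
    max_freq_diff: float = 0.15
    n_perm_amova: int = 1000
    n_perm_pairwise: int = 100
    pairwise_alpha: float = 0.05
    scan_sims: int = 10000
    scan_confidence: float = 0.99
    n_perm_mantel: int = 999
    low_imposex_levels: tuple = (1, 2, 3, 4)
    f_as_missing: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.msl_threshold < 1:
            raise ValueError("msl_threshold out of range")
        if self.min_size > self.max_size:
            raise ValueError("min_size > max_size")
        for name in ("n_perm_amova", "n_perm_pairwise", "scan_sims", "n_perm_mantel"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.scan_confidence < 1:
            raise ValueError("scan_confidence must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class PipelineReport:
    report: dict
    tables: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.report, indent=1, sort_keys=True, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


REQUIRED_KEYS = (
    "seed", "qc", "scoring", "methylation", "diversity", "amova",
    "pairwise_fst", "pcoa", "mantel", "outliers", "models", "decisions",
)


def validate_report(report: dict) -> None:
    missing = [k for k in REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing required sections: {missing}")
    for key in ("msl", "nml"):
        if key not in report["amova"]:
            raise ValueError(f"amova section missing {key}")


def geographic_distances(lat: np.ndarray, lon: np.ndarray, ids) -> pdiff.DistanceMatrix:
    """Great-circle distances (km, haversine) between site coordinates."""
    lat, lon = np.radians(np.asarray(lat)), np.radians(np.asarray(lon))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(
        dlon / 2
    ) ** 2
    d = 2 * 6371.0 * np.arcsin(np.clip(np.sqrt(a), 0, 1))
    np.fill_diagonal(d, 0.0)
    return pdiff.DistanceMatrix((d + d.T) / 2, pd.Index(ids))


def _fst_distance(fst: pd.DataFrame) -> pdiff.DistanceMatrix:
    v = np.clip(fst.to_numpy(dtype=float), 0.0, None)
    np.fill_diagonal(v, 0.0)
    return pdiff.DistanceMatrix((v + v.T) / 2, fst.index)


def _pop_summary(series: pd.Series, pops: pd.Series) -> dict:
    g = series.groupby(pops)
    return {str(k): dict(mean=float(m), sd=float(s), n=int(n))
            for k, m, s, n in zip(g.mean().index, g.mean(), g.std(ddof=1), g.count())}


def _amova_dict(res: pdiff.AmovaResult) -> dict:
    out = dict(
        percent_variation={k: float(v) for k, v in res.percent_variation.items()},
        sigma2={k: float(v) for k, v in res.sigma2.items()},
        phi_st=float(res.phi_st),
        p_value=float(res.p_value),
        n_permutations=int(res.n_permutations),
    )
    if res.phi_ct is not None:
        out.update(phi_ct=float(res.phi_ct), phi_sc=float(res.phi_sc),
                   p_ct=float(res.p_ct))
    return out


def _linear_dict(fit: ph.LinearFit) -> dict:
    return dict(
        f=float(fit.fvalue), df1=int(fit.df_model), df2=int(fit.df_resid),
        p=float(fit.f_pvalue), r2_adj=float(fit.rsquared_adj),
        coefficients={str(k): float(v) for k, v in fit.params.items()},
    )


def _po_dict(fit: ph.ProportionalOddsResults) -> dict:
    tab = ph.wald_summary(fit)
    coef = tab[tab["kind"] == "coefficient"]
    return dict(
        coefficients={
            str(t): dict(value=float(r["value"]), se=float(r["se"]),
                         t=float(r["t_value"]), p=float(r["p_value"]),
                         OR=float(r["OR"]), ci_low=float(r["ci_low"]),
                         ci_high=float(r["ci_high"]))
            for t, r in coef.iterrows()
        },
        cutpoints={
            str(t): dict(value=float(r["value"]), se=float(r["se"]))
            for t, r in tab[tab["kind"] == "cutpoint"].iterrows()
        },
        aic=float(fit.aic),
        loglik=float(fit.llf),
        converged=bool(fit.converged),
    )


def run_study(
    pair: FragmentProfilePair,
    samples: pd.DataFrame,
    replicate: ReplicatePair | None = None,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Run the full MSAP analysis; see the module docstring for the stages."""
    config = config or PipelineConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    def child_seed() -> int:
        return int(rng.integers(2**31 - 1))

    decisions: list[str] = []
    tables: dict = {}
    samples = samples.loc[pair.sample_ids]
    pops = samples["population"]

    # ---- stage 1: QC ------------------------------------------------------
    stage = "qc"
    try:
        qc_report: dict = dict()
        if replicate is not None:
            raw_err = qcmod.error_rate(replicate.plate_a, replicate.plate_b)
            qc_report["error_rate_raw"] = dict(
                hpa_percent=raw_err.hpa_percent, msp_percent=raw_err.msp_percent,
                state_percent=raw_err.state_percent,
            )
            rep_pops = pops.reindex(replicate.plate_a.sample_ids)
        else:
            rep_pops = None
        filtered, filt_report = qcmod.filter_fragments(
            pair,
            min_size=config.min_size,
            max_size=config.max_size,
            replicate_pair=replicate,
            populations=rep_pops,
            max_freq_diff=config.max_freq_diff,
        )
        tables["filter_report"] = filt_report
        qc_report["n_fragments_input"] = int(pair.n_fragments)
        qc_report["n_fragments_retained"] = int(filtered.n_fragments)
        qc_report["n_dropped_by_reason"] = (
            filt_report["reason"].value_counts().to_dict() if len(filt_report) else {}
        )
        if replicate is not None:
            keep = [l for l in filtered.fragment_labels
                    if l in replicate.plate_a.fragment_labels]
            filt_err = qcmod.error_rate(
                replicate.plate_a.subset_fragments(keep),
                replicate.plate_b.subset_fragments(keep),
            )
            qc_report["error_rate_filtered"] = dict(
                hpa_percent=filt_err.hpa_percent, msp_percent=filt_err.msp_percent,
                state_percent=filt_err.state_percent,
            )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 2: scoring -------------------------------------------------
    stage = "scoring"
    try:
        states = sc.score_methylation_states(filtered)
        partition = sc.partition_loci(states, msl_threshold=config.msl_threshold)
        epi, gen = sc.encode_binary(states, partition, f_as_missing=config.f_as_missing)
        meth_freq = sc.individual_methylation_frequency(
            states, partition, f_as_missing=config.f_as_missing
        )
        tables["states"] = states
        tables["partition"] = partition.table
        tables["epi_matrix"] = epi
        tables["gen_matrix"] = gen
        tables["methylation_frequency"] = meth_freq
        scoring_report = dict(
            n_msl=int(len(partition.msl_labels)),
            n_nml=int(len(partition.nml_labels)),
            n_retained_msl=int(len(partition.retained_msl)),
            n_retained_nml=int(len(partition.retained_nml)),
        )
        n_dropped = int((~partition.table["retained"]).sum())
        decisions.append(f"{n_dropped} loci not retained (monomorphic or singleton-driven)")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 3: methylation summaries ----------------------------------
    def _optional(fn, *args, **kwargs):
        """Run a secondary analysis; skip (None) when the data cannot support it."""
        try:
            return fn(*args, **kwargs)
        except (ValueError, ph.ConvergenceError) as exc:
            decisions.append(f"skipped {fn.__name__}: {exc}")
            return None

    stage = "methylation"
    try:
        meth_by_pop = _pop_summary(meth_freq, pops)
        cmp_pop = ph.group_compare(meth_freq, pops, method="anova_tukey")
        females = samples["sex"] == "F" if "sex" in samples else pd.Series(True, index=samples.index)
        imp = samples["imposex_level"] if "imposex_level" in samples else None
        meth_report = dict(
            per_population=meth_by_pop,
            anova_f=cmp_pop.statistic,
            anova_p=cmp_pop.p_value,
            tukey_letters=cmp_pop.letters,
        )
        if imp is not None:
            low = imp.isin(config.low_imposex_levels)
            grp = pd.Series(np.where(low, "low", "high"), index=samples.index)
            sel = females & imp.notna()
            if grp[sel].nunique() == 2:
                cmp_imp = _optional(
                    ph.group_compare, meth_freq[sel], grp[sel], method="anova_tukey"
                )
                if cmp_imp is not None:
                    meth_report["low_vs_high_imposex"] = dict(
                        f=cmp_imp.statistic, p=cmp_imp.p_value
                    )
        if "tbt_ng_sn_g" in samples:
            tbt = samples["tbt_ng_sn_g"]
            sel = tbt.notna() & imp.notna() if imp is not None else tbt.notna()
            if imp is not None and sel.any():
                low = imp[sel].isin(config.low_imposex_levels)
                if low.nunique() == 2:
                    mw = _optional(
                        ph.group_compare, tbt[sel], np.where(low, "low", "high"),
                        method="mann_whitney",
                    )
                    if mw is not None:
                        meth_report["tbt_low_vs_high_imposex_mannwhitney"] = dict(
                            u=mw.statistic, p=mw.p_value
                        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 4: diversity ----------------------------------------------
    stage = "diversity"
    try:
        div_report = {}
        for name, mat in (("msl", epi), ("nml", gen)):
            if mat.shape[1] == 0:
                div_report[name] = None
                continue
            div = pdiff.diversity_indices(mat, pops)
            tables[f"diversity_{name}"] = div.per_population
            div_report[name] = {
                str(p): dict(Ne=float(r["Ne_mean"]), h=float(r["h_mean"]),
                             I=float(r["I_mean"]))
                for p, r in div.per_population.iterrows()
            }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 5: AMOVA + pairwise FST ------------------------------------
    stage = "amova"
    try:
        amova_report = {}
        dists = {}
        for name, mat in (("msl", epi), ("nml", gen)):
            if mat.shape[1] == 0:
                amova_report[name] = None
                decisions.append(f"no retained {name.upper()} loci; {name} analyses skipped")
                continue
            d = pdiff.pairwise_distance(mat)
            dists[name] = d
            res = pdiff.amova(d, pops, n_perm=config.n_perm_amova, seed=child_seed())
            amova_report[name] = _amova_dict(res)
            if any(v < 0 for v in res.sigma2.values()):
                decisions.append(f"negative variance component truncated to 0 ({name})")
        if imp is not None and females.any():
            sel = females & imp.notna()
            lvl = imp[sel].astype(int)
            counts = lvl.value_counts()
            ok_levels = counts[counts >= 2].index
            dropped_lv = sorted(set(counts.index) - set(ok_levels))
            if dropped_lv:
                decisions.append(
                    f"imposex levels with <2 females dropped from the group AMOVA: {dropped_lv}"
                )
            sel2 = sel & imp.isin(ok_levels)
            if imp[sel2].nunique() >= 2:
                d_imp = pdiff.pairwise_distance(epi.loc[sel2])
                groups = {
                    int(l): ("low" if l in config.low_imposex_levels else "high")
                    for l in ok_levels
                }
                if len(set(groups.values())) == 2:
                    res_imp = pdiff.amova(
                        d_imp, imp[sel2].astype(int), groups=groups,
                        n_perm=config.n_perm_amova, seed=child_seed(),
                    )
                    amova_report["imposex_groups"] = _amova_dict(res_imp)
        fst_report = {}
        for name, mat in (("msl", epi), ("nml", gen)):
            if mat.shape[1] == 0:
                fst_report[name] = None
                continue
            fst, pv, sig = pdiff.pairwise_fst(
                mat, pops, n_perm=config.n_perm_pairwise,
                alpha=config.pairwise_alpha, seed=child_seed(),
            )
            tables[f"pairwise_fst_{name}"] = fst
            tables[f"pairwise_fst_{name}_p"] = pv
            fst_report[name] = dict(
                fst=fst.round(6).to_dict(),
                significant={a: {b: bool(v) for b, v in row.items()}
                             for a, row in sig.to_dict().items()},
            )
        # combined layout: MSL (epigenetic) below the diagonal, NML above
        if fst_report.get("msl") and fst_report.get("nml"):
            msl_fst, nml_fst = tables["pairwise_fst_msl"], tables["pairwise_fst_nml"]
            combined = msl_fst.copy()
            iu = np.triu_indices(len(combined), k=1)
            cvals = combined.to_numpy()
            cvals[iu] = nml_fst.to_numpy()[iu]
            tables["pairwise_fst_combined"] = pd.DataFrame(
                cvals, index=combined.index, columns=combined.columns
            )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 6: PCoA -----------------------------------------------------
    stage = "pcoa"
    try:
        pcoa_report = {}
        if "msl" in dists:
            pc = pdiff.pcoa(dists["msl"])
            tables["pcoa_coordinates"] = pc.coordinates
            k = min(2, pc.coordinates.shape[1])
            pcoa_report = dict(
                percent_variance_first_two=float(pc.percent_variance[:2].sum()),
                n_negative_eigenvalues=pc.n_negative,
            )
            for ax in range(k):
                cmp_ax = _optional(ph.group_compare, pc.coordinates.iloc[:, ax], pops)
                if cmp_ax is not None:
                    pcoa_report[f"pco{ax + 1}_anova"] = dict(
                        f=cmp_ax.statistic, p=cmp_ax.p_value, letters=cmp_ax.letters
                    )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 7: Mantel ---------------------------------------------------
    stage = "mantel"
    try:
        mantel_report = {}
        if {"lat", "lon"}.issubset(samples.columns):
            site = samples.groupby(pops)[["lat", "lon"]].first()
            geo = geographic_distances(site["lat"].to_numpy(), site["lon"].to_numpy(),
                                       site.index)
            for name in ("msl", "nml"):
                if f"pairwise_fst_{name}" not in tables:
                    continue
                fst_mat = tables[f"pairwise_fst_{name}"].loc[site.index, site.index]
                try:
                    mres = pdiff.mantel(
                        _fst_distance(fst_mat), geo, n_perm=config.n_perm_mantel,
                        seed=child_seed(),
                    )
                except ValueError:  # constant FST matrix at toy scale
                    continue
                mantel_report[f"{name}_vs_geography"] = dict(r=mres.r, p=mres.p_value)
            morpho_cols = [c for c in ("tl_mm", "tb_mm", "aw_mm", "al_mm", "tm_g")
                           if c in samples.columns]
            if morpho_cols and females.any():
                traits = samples.loc[females, morpho_cols]
                logs = np.log(traits[traits.gt(0).all(axis=1)])
                norm = logs.drop(columns=["tl_mm"]).sub(logs["tl_mm"], axis=0)
                prox = pdiff.population_proximity(norm, pops[norm.index])
                shared = prox.ids.intersection(site.index)
                prox_s = pdiff.DistanceMatrix(
                    prox.to_frame().loc[shared, shared].to_numpy(), shared
                )
                geo_s = pdiff.DistanceMatrix(
                    geo.to_frame().loc[shared, shared].to_numpy(), shared
                )
                mres = pdiff.mantel(prox_s, geo_s, n_perm=config.n_perm_mantel,
                                    seed=child_seed())
                mantel_report["morphometry_vs_geography"] = dict(r=mres.r, p=mres.p_value)
                for name in ("msl", "nml"):
                    if f"pairwise_fst_{name}" not in tables:
                        continue
                    fst_mat = tables[f"pairwise_fst_{name}"].loc[shared, shared]
                    try:
                        mres = pdiff.mantel(
                            prox_s, _fst_distance(fst_mat),
                            n_perm=config.n_perm_mantel, seed=child_seed(),
                        )
                    except ValueError:
                        continue
                    mantel_report[f"morphometry_vs_{name}"] = dict(r=mres.r, p=mres.p_value)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 8: outlier scan --------------------------------------------
    stage = "outliers"
    try:
        outlier_report = {}
        for name, mat in (("msl", epi), ("nml", gen)):
            if mat.shape[1] < 10:
                outlier_report[name] = None
                continue
            res = ol.scan(
                mat, pops, n_sim=config.scan_sims,
                confidence=config.scan_confidence, seed=child_seed(),
            )
            tables[f"outlier_scan_{name}"] = res.table
            outlier_report[name] = dict(
                n_outliers=int(res.table["flagged"].sum()),
                outlier_loci=[str(x) for x in res.outliers],
                mean_fst=res.mean_fst_initial,
                neutral_mean_fst=res.neutral_mean_fst,
            )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 9: phenotype models ----------------------------------------
    stage = "models"
    try:
        models_report: dict = {}
        tbt = samples.get("tbt_ng_sn_g")

        def _add(key, fn, *args, **kwargs):
            res = _optional(fn, *args, **kwargs)
            if res is not None:
                models_report[key] = (
                    _po_dict(res) if isinstance(res, ph.ProportionalOddsResults)
                    else _linear_dict(res)
                )

        if imp is not None:
            levels = sorted(imp.dropna().astype(int).unique())
            if tbt is not None:
                sel = females & imp.notna() & tbt.notna()
                if sel.sum() >= 20:
                    _add("imposex_vs_tbt", ph.fit_proportional_odds,
                         imp[sel].astype(int), pd.DataFrame({"TBT": tbt[sel]}),
                         levels=levels)
            sel = females & imp.notna() & meth_freq.notna()
            if sel.sum() >= 20:
                _add("imposex_vs_methylation", ph.fit_proportional_odds,
                     imp[sel].astype(int),
                     pd.DataFrame({"methylation": meth_freq[sel]}), levels=levels)
        if "wet_mass_g" in samples:
            wm = samples["wet_mass_g"]
            if tbt is not None:
                sel = wm.notna() & tbt.notna()
                _add("mass_vs_tbt", ph.fit_linear, wm[sel],
                     pd.DataFrame({"TBT": tbt[sel]}))
            sel = wm.notna() & meth_freq.notna()
            _add("mass_vs_methylation", ph.fit_linear, wm[sel],
                 pd.DataFrame({"methylation": meth_freq[sel]}))
            if imp is not None:
                sel = females & wm.notna() & imp.notna()
                if imp[sel].nunique() >= 2:
                    _add("mass_vs_imposex_anova", ph.anova_lm,
                         wm[sel].to_numpy(), imp[sel].astype(int).to_numpy())
        if tbt is not None:
            sel = tbt.notna() & meth_freq.notna()
            _add("methylation_vs_tbt_individual", ph.fit_linear, meth_freq[sel],
                 pd.DataFrame({"TBT": tbt[sel]}))
            pop_meth = meth_freq.groupby(pops).mean()
            pop_tbt = tbt.groupby(pops).mean()
            ok = pop_meth.notna() & pop_tbt.notna()
            if ok.sum() >= 4:
                _add("methylation_vs_tbt_population", ph.fit_linear, pop_meth[ok],
                     pd.DataFrame({"TBT": pop_tbt[ok]}))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = dict(
        seed=int(config.seed),
        qc=qc_report,
        scoring=scoring_report,
        methylation=meth_report,
        diversity=div_report,
        amova=amova_report,
        pairwise_fst=fst_report,
        pcoa=pcoa_report,
        mantel=mantel_report,
        outliers=outlier_report,
        models=models_report,
        decisions=decisions,
    )
    validate_report(report)
    return PipelineReport(report=report, tables=tables)


def run(
    input_dir=None,
    study=None,
    config: PipelineConfig | None = None,
    outdir=None,
) -> PipelineReport:
    """Run the pipeline from a CSV bundle directory or a SyntheticStudy.

    With ``outdir``, the report JSON and the main result tables are written
    there as UTF-8 CSVs.
    """
    if (input_dir is None) == (study is None):
        raise ValueError("provide exactly one of input_dir or study")
    if study is not None:
        pair, replicate, samples = study.pair, study.replicate, study.samples
    else:
        from .io import load_study

        pair, replicate, samples = load_study(input_dir)
    rep = run_study(pair, samples, replicate=replicate, config=config)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rep.to_json(out / "report.json")
        for name, tab in rep.tables.items():
            if isinstance(tab, (pd.DataFrame, pd.Series)):
                tab.to_csv(out / f"{name}.csv", na_rep="NA")
    return rep
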