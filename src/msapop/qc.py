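"""Fragment retention filters and between-run scoring error rate.

AFLP/MSAP scoring is noisy: peak calling near the detection limit, size
mis-binning and plate effects all inject discordant presence calls.  The
filters here mirror common practice for capillary AFLP data: a size window,
an intensity (RFU) floor applied at matrix construction, removal of
singleton-driven fragments, and a replicate-plate reproducibility screen on
within-population band frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import FragmentProfilePair

__all__ = [
    "ReplicatePair",
    "ErrorRates",
    "filter_fragments",
    "error_rate",
    "presence_from_peak_table",
]


@dataclass
class ReplicatePair:
    """The same individuals scored on two different plates.

    Both members must cover identical sample ids and fragment labels.
    """

    plate_a: FragmentProfilePair
    plate_b: FragmentProfilePair

    def __post_init__(self) -> None:
        a, b = self.plate_a, self.plate_b
        if set(a.sample_ids) != set(b.sample_ids):
            raise ValueError("replicate plates cover different individuals")
        if set(a.fragment_labels) != set(b.fragment_labels):
            raise ValueError("replicate plates cover different fragments")
        # align orderings once so downstream comparisons are positional
        self.plate_b = FragmentProfilePair(
            b.hpa.loc[a.sample_ids, a.fragment_labels],
            b.msp.loc[a.sample_ids, a.fragment_labels],
            b.fragment_meta,
        )


@dataclass
class ErrorRates:
    """Between-run scoring error, in percent, per digest set.

    error = discordant cells x 100 / (n_fragments x n_individuals), counted
    separately for the EcoRI–HpaII and EcoRI–MspI matrices.  ``state_percent``
    is a diagnostic discordance on the derived methylation states.
    """

    hpa_percent: float
    msp_percent: float
    state_percent: float
    n_fragments: int
    n_individuals: int


def presence_from_peak_table(
    peaks: pd.DataFrame,
    sample_ids,
    fragment_labels,
    min_rfu: float = 100.0,
) -> pd.DataFrame:
    """Convert a long peak table to a presence matrix, applying the RFU floor.

    ``peaks`` needs columns ``sample``, ``fragment`` and ``rfu``; a peak below
    ``min_rfu`` is scored 0 (absent), exactly as if it had not been called.
    Samples/fragments without any row default to 0.
    """
    mat = pd.DataFrame(0.0, index=pd.Index(sample_ids), columns=pd.Index(fragment_labels))
    ok = peaks[peaks["rfu"] >= min_rfu]
    for _, row in ok.iterrows():
        if row["sample"] in mat.index and row["fragment"] in mat.columns:
            mat.loc[row["sample"], row["fragment"]] = 1.0
    return mat


def _presence(pair: FragmentProfilePair) -> pd.DataFrame:
    """Band presence in at least one digest (NaN only if both missing)."""
    h, m = pair.hpa.to_numpy(), pair.msp.to_numpy()
    both_missing = np.isnan(h) & np.isnan(m)
    pres = (np.nan_to_num(h) + np.nan_to_num(m) > 0).astype(float)
    pres[both_missing] = np.nan
    return pd.DataFrame(pres, index=pair.sample_ids, columns=pair.fragment_labels)


def filter_fragments(
    pair: FragmentProfilePair,
    min_size: int = 50,
    max_size: int = 400,
    replicate_pair: ReplicatePair | None = None,
    populations: pd.Series | None = None,
    max_freq_diff: float = 0.15,
) -> tuple[FragmentProfilePair, pd.DataFrame]:
    """Apply the retention filters; return the retained pair and a report.

    Stages, in order (size and rarity act on fixed inputs and commute; the
    reproducibility screen runs last, on the survivors):

    1. size window: drop fragments with ``size_bp`` outside [min_size, max_size]
       (fragments lacking a size are kept);
    2. rare fragments: drop fragments whose presence/absence differs in
       exactly one individual — minor-call count equal to 1 in either digest;
    3. reproducibility (only with ``replicate_pair``): drop fragments whose
       within-population band frequency differs by more than ``max_freq_diff``
       between the two plates in any population, in either digest.
       ``populations`` maps replicate sample ids to populations; omitted, all
       replicate individuals form one population.

    The report lists one row per dropped fragment: label, reason, statistic.
    """
    meta = pair.fragment_meta
    report_rows: list[dict] = []
    keep = list(pair.fragment_labels)

    # 1. size window
    if meta is not None and "size_bp" in meta.columns:
        sizes = meta["size_bp"]
        survivors = []
        for label in keep:
            size = sizes.get(label, np.nan)
            if pd.notna(size) and not (min_size <= size <= max_size):
                report_rows.append(dict(label=label, reason="size", statistic=float(size)))
            else:
                survivors.append(label)
        keep = survivors

    # 2. rare fragments (singleton presence or absence in either digest)
    survivors = []
    for label in keep:
        rare = False
        stat = np.nan
        for mat in (pair.hpa, pair.msp):
            col = mat[label].dropna()
            ones = int((col == 1).sum())
            zeros = int((col == 0).sum())
            minor = min(ones, zeros)
            if minor == 1:
                rare, stat = True, float(minor)
                break
        if rare:
            report_rows.append(dict(label=label, reason="rare", statistic=stat))
        else:
            survivors.append(label)
    keep = survivors

    # 3. replicate-plate reproducibility on survivors
    if replicate_pair is not None:
        rep = replicate_pair
        ids = rep.plate_a.sample_ids
        if len(pd.Index(ids).intersection(pair.sample_ids)) == 0:
            raise ValueError("replicate pair shares no individuals with the dataset")
        if populations is None:
            pops = pd.Series("all", index=ids)
        else:
            pops = pd.Series(populations).reindex(ids)
            if pops.isna().any():
                raise ValueError("populations missing for some replicate individuals")
        survivors = []
        for label in keep:
            worst = 0.0
            for mat_a, mat_b in (
                (rep.plate_a.hpa, rep.plate_b.hpa),
                (rep.plate_a.msp, rep.plate_b.msp),
            ):
                if label not in mat_a.columns:
                    continue
                for _, idx in pops.groupby(pops).groups.items():
                    fa = mat_a.loc[idx, label].mean(skipna=True)
                    fb = mat_b.loc[idx, label].mean(skipna=True)
                    if pd.notna(fa) and pd.notna(fb):
                        worst = max(worst, abs(fa - fb))
            if worst > max_freq_diff:
                report_rows.append(
                    dict(label=label, reason="reproducibility", statistic=worst)
                )
            else:
                survivors.append(label)
        keep = survivors

    report = pd.DataFrame(report_rows, columns=["label", "reason", "statistic"])
    return pair.subset_fragments(keep), report


def error_rate(rep_a: FragmentProfilePair, rep_b: FragmentProfilePair) -> ErrorRates:
    """Between-run scoring error on raw presence calls, per digest set.

    The denominator is the literal product n_fragments x n_individuals; a
    cell missing in either run is counted concordant (no imputation).
    Symmetric in its two arguments.
    """
    if set(rep_a.sample_ids) != set(rep_b.sample_ids) or set(
        rep_a.fragment_labels
    ) != set(rep_b.fragment_labels):
        raise ValueError("replicates must cover identical individuals and fragments")
    b_hpa = rep_b.hpa.loc[rep_a.sample_ids, rep_a.fragment_labels]
    b_msp = rep_b.msp.loc[rep_a.sample_ids, rep_a.fragment_labels]
    n_frag, n_ind = rep_a.n_fragments, rep_a.n_individuals
    if n_frag == 0 or n_ind == 0:
        raise ValueError("error rate undefined for empty replicate matrices")

    def _disc(a: pd.DataFrame, b: pd.DataFrame) -> int:
        av, bv = a.to_numpy(), b.to_numpy()
        both = ~np.isnan(av) & ~np.isnan(bv)
        return int((both & (av != bv)).sum())

    denom = n_frag * n_ind
    hpa_pct = _disc(rep_a.hpa, b_hpa) * 100.0 / denom
    msp_pct = _disc(rep_a.msp, b_msp) * 100.0 / denom

    from .scoring import score_methylation_states

    sa = score_methylation_states(rep_a).to_numpy(dtype=object)
    sb = score_methylation_states(
        FragmentProfilePair(b_hpa, b_msp, rep_b.fragment_meta)
    ).to_numpy(dtype=object)
    both = ~pd.isna(sa) & ~pd.isna(sb)
    state_pct = float((both & (sa != sb)).sum()) * 100.0 / denom
    return ErrorRates(
        hpa_percent=hpa_pct,
        msp_percent=msp_pct,
        state_percent=state_pct,
        n_fragments=n_frag,
        n_individuals=n_ind,
    )
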