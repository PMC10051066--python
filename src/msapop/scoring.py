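"""MSAP fragment scoring: methylation states, MSL/NML partition, binary encodings.

MSAP profiles each locus with two isoschizomer digests (EcoRI–HpaII and
EcoRI–MspI) whose differential sensitivity to cytosine methylation turns the
pair of presence/absence calls into a four-way methylation state:

======  ======  =====  =========================================
HpaII   MspI    state  interpretation
======  ======  =====  =========================================
1       1       U      non-methylated
1       0      H      hemimethylated (external cytosine)
0       1      I      internal cytosine methylation
0       0      F      hypermethylation (or genetic absence)
======  ======  =====  =========================================

Loci whose proportion of methylated scores (H, I, F) exceeds a threshold
(default 5%) are *methylation-susceptible loci* (MSL) and feed the epigenetic
analyses; the rest are *non-methylation loci* (NML) and feed the genetic
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "FragmentProfilePair",
    "LocusPartition",
    "score_methylation_states",
    "partition_loci",
    "encode_binary",
    "individual_methylation_frequency",
]

#: methylation state codes, in (hpa, msp) order of definition
STATES = ("U", "H", "I", "F")

_METHYLATED = frozenset({"H", "I", "F"})


class ShapeMismatchError(ValueError):
    """Raised when the two digest matrices are not aligned."""


@dataclass
class FragmentProfilePair:
    """Paired binary digest matrices (individuals x fragments).

    Parameters
    ----------
    hpa : pandas.DataFrame
        EcoRI–HpaII presence/absence calls; cells in {0, 1, NaN}.
    msp : pandas.DataFrame
        EcoRI–MspI calls, same index (sample ids) and columns (fragment
        labels) as ``hpa``.
    fragment_meta : pandas.DataFrame, optional
        Per-fragment metadata indexed by fragment label; recognised columns
        are ``size_bp`` (positive int), ``primer_pair`` and ``dye``.
    """

    hpa: pd.DataFrame
    msp: pd.DataFrame
    fragment_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.hpa = _as_binary_frame(self.hpa, "hpa")
        self.msp = _as_binary_frame(self.msp, "msp")
        if self.hpa.shape != self.msp.shape:
            raise ShapeMismatchError(
                f"digest matrices differ in shape: hpa {self.hpa.shape} vs "
                f"msp {self.msp.shape}"
            )
        if not self.hpa.index.equals(self.msp.index):
            raise ShapeMismatchError("sample ids (rows) differ between digests")
        if not self.hpa.columns.equals(self.msp.columns):
            raise ShapeMismatchError("fragment labels (columns) differ between digests")
        if self.fragment_meta is not None:
            meta = self.fragment_meta
            if "size_bp" in meta.columns:
                sizes = meta["size_bp"].dropna()
                if (sizes <= 0).any():
                    raise ValueError("fragment sizes must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.hpa.index

    @property
    def fragment_labels(self) -> pd.Index:
        return self.hpa.columns

    @property
    def n_individuals(self) -> int:
        return self.hpa.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.hpa.shape[1]

    def subset_fragments(self, labels) -> "FragmentProfilePair":
        labels = pd.Index(labels)
        meta = None
        if self.fragment_meta is not None:
            meta = self.fragment_meta.loc[self.fragment_meta.index.intersection(labels)]
        return FragmentProfilePair(
            self.hpa.loc[:, labels].copy(), self.msp.loc[:, labels].copy(), meta
        )

    def subset_samples(self, ids) -> "FragmentProfilePair":
        ids = pd.Index(ids)
        return FragmentProfilePair(
            self.hpa.loc[ids].copy(), self.msp.loc[ids].copy(), self.fragment_meta
        )


def _as_binary_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
    df = pd.DataFrame(df).astype(float)
    vals = df.to_numpy()
    ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
    if not ok.all():
        bad = np.unique(vals[~ok])
        raise ValueError(f"{name} matrix contains non-binary values: {bad[:5]}")
    return df


@dataclass
class LocusPartition:
    """Per-locus MSL/NML classification and retention flags.

    ``table`` holds one row per fragment with columns:

    - ``n_scored``: non-missing state count
    - ``prop_methylated``: fraction of scored cells in {H, I, F}
    - ``locus_class``: "MSL" if the fraction strictly exceeds the threshold,
      else "NML"; NaN for all-missing loci (excluded)
    - ``polymorphic``: state-level rule — at least two distinct observed
      states, each observed state occurring at least twice
    - ``retained``: polymorphic *and* its binary encoding has >=2 cells on
      each side (so retained columns are informative downstream)
    """

    table: pd.DataFrame
    msl_threshold: float = 0.05

    @property
    def msl_labels(self) -> pd.Index:
        t = self.table
        return t.index[t["locus_class"] == "MSL"]

    @property
    def nml_labels(self) -> pd.Index:
        t = self.table
        return t.index[t["locus_class"] == "NML"]

    @property
    def retained_msl(self) -> pd.Index:
        t = self.table
        return t.index[(t["locus_class"] == "MSL") & t["retained"]]

    @property
    def retained_nml(self) -> pd.Index:
        t = self.table
        return t.index[(t["locus_class"] == "NML") & t["retained"]]


def score_methylation_states(pair: FragmentProfilePair) -> pd.DataFrame:
    """Map each (HpaII, MspI) call pair to its methylation state.

    Returns a DataFrame of {"U","H","I","F"} with NaN wherever either digest
    call is missing.  Scoring is purely cell-wise.
    """
    hpa = pair.hpa.to_numpy()
    msp = pair.msp.to_numpy()
    out = np.full(hpa.shape, np.nan, dtype=object)
    missing = np.isnan(hpa) | np.isnan(msp)
    out[(hpa == 1) & (msp == 1)] = "U"
    out[(hpa == 1) & (msp == 0)] = "H"
    out[(hpa == 0) & (msp == 1)] = "I"
    out[(hpa == 0) & (msp == 0)] = "F"
    out[missing] = np.nan
    return pd.DataFrame(out, index=pair.sample_ids, columns=pair.fragment_labels)


def _state_counts(col: np.ndarray) -> dict[str, int]:
    return {s: int((col == s).sum()) for s in STATES}


def partition_loci(states: pd.DataFrame, msl_threshold: float = 0.05) -> LocusPartition:
    """Classify loci as MSL/NML and flag polymorphic, retainable loci.

    A locus is MSL iff its proportion of methylated scores among non-missing
    cells is *strictly* greater than ``msl_threshold`` ("exceeded" read as
    strict inequality; the boundary case falls to NML).
    """
    if states.size == 0:
        raise ValueError("state matrix is empty")
    rows = []
    all_missing = []
    for label in states.columns:
        col = states[label].to_numpy(dtype=object)
        scored = col[~pd.isna(col)]
        n = len(scored)
        if n == 0:
            all_missing.append(label)
            rows.append(
                dict(label=label, n_scored=0, prop_methylated=np.nan,
                     locus_class=np.nan, polymorphic=False, retained=False)
            )
            continue
        counts = _state_counts(scored)
        n_meth = counts["H"] + counts["I"] + counts["F"]
        prop = n_meth / n
        cls = "MSL" if prop > msl_threshold else "NML"
        observed = {s: c for s, c in counts.items() if c > 0}
        polymorphic = len(observed) >= 2 and all(c >= 2 for c in observed.values())
        if cls == "MSL":
            ones, zeros = n_meth, counts["U"]
        else:  # NML: band present in >=1 digest <-> state != F
            zeros = counts["F"]
            ones = n - zeros
        retained = polymorphic and ones >= 2 and zeros >= 2
        rows.append(
            dict(label=label, n_scored=n, prop_methylated=prop, locus_class=cls,
                 polymorphic=polymorphic, retained=retained)
        )
    if all_missing:
        warnings.warn(
            f"{len(all_missing)} loci with all-missing scores excluded: "
            f"{all_missing[:5]}",
            stacklevel=2,
        )
    table = pd.DataFrame(rows).set_index("label")
    return LocusPartition(table=table, msl_threshold=msl_threshold)


def encode_binary(
    states: pd.DataFrame,
    partition: LocusPartition,
    f_as_missing: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the epigenetic (MSL) and genetic (NML) 0/1 analysis matrices.

    MSL columns: U -> 0, H/I/F -> 1 (methylated).  With ``f_as_missing`` the
    ambiguous 0/0 state is treated as missing instead of methylated, since a
    doubly absent band can also reflect a genetic absence.
    NML columns: band present in at least one digest (U/H/I) -> 1, F -> 0.
    Missing states propagate as NaN.
    """
    epi_cols = partition.retained_msl
    gen_cols = partition.retained_nml

    def _encode(cols: pd.Index, msl: bool) -> pd.DataFrame:
        sub = states.loc[:, cols].to_numpy(dtype=object)
        out = np.full(sub.shape, np.nan)
        if msl:
            out[sub == "U"] = 0.0
            out[(sub == "H") | (sub == "I")] = 1.0
            out[sub == "F"] = np.nan if f_as_missing else 1.0
        else:
            out[(sub == "U") | (sub == "H") | (sub == "I")] = 1.0
            out[sub == "F"] = 0.0
        return pd.DataFrame(out, index=states.index, columns=cols)

    return _encode(epi_cols, msl=True), _encode(gen_cols, msl=False)


def individual_methylation_frequency(
    states: pd.DataFrame,
    partition: LocusPartition,
    f_as_missing: bool = False,
) -> pd.Series:
    """Per-individual frequency of methylated states across retained MSL.

    frequency = #{H, I, F} / #non-missing over that individual's retained MSL
    (with ``f_as_missing``, F cells drop out of both counts).  An individual
    with no scored MSL gets NaN with a warning.
    """
    cols = partition.retained_msl
    if len(cols) == 0:
        raise ValueError("no retained MSL loci")
    sub = states.loc[:, cols].to_numpy(dtype=object)
    meth = (sub == "H") | (sub == "I") | ((sub == "F") & (not f_as_missing))
    scored = ~pd.isna(sub)
    if f_as_missing:
        scored = scored & (sub != "F")
    denom = scored.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, meth.sum(axis=1) / denom, np.nan)
    if np.isnan(freq).any():
        bad = list(states.index[np.isnan(freq)][:5])
        warnings.warn(f"individuals with no scored MSL: {bad}", stacklevel=2)
    return pd.Series(freq, index=states.index, name="methylation_frequency")
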