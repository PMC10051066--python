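"""CSV bundle readers/writers for MSAP studies.

All files are UTF-8, comma-delimited, with ``NA`` for missing.  The bundle
layout (one directory) is:

- ``hpa.csv`` / ``msp.csv`` — presence matrices, rows = individuals
- ``fragment_meta.csv`` — label, size_bp, primer_pair, dye
- ``samples.csv`` — sample sheet (id, population, sex, imposex_level, ...)
- ``replicate_{a,b}_{hpa,msp}.csv`` — replicate plates (optional)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import ReplicatePair
from .scoring import FragmentProfilePair
from .synth import SyntheticStudy

__all__ = [
    "read_matrix",
    "read_fragment_pair",
    "read_replicate_pair",
    "read_sample_sheet",
    "write_study",
    "load_study",
]

_CSV_KW = dict(na_values=["NA"], keep_default_na=True)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, **_CSV_KW).astype(float)


def read_fragment_pair(hpa_path, msp_path, meta_path=None) -> FragmentProfilePair:
    meta = pd.read_csv(meta_path, index_col=0, **_CSV_KW) if meta_path else None
    return FragmentProfilePair(read_matrix(hpa_path), read_matrix(msp_path), meta)


def read_replicate_pair(dirpath, meta=None) -> ReplicatePair:
    d = Path(dirpath)
    a = FragmentProfilePair(
        read_matrix(d / "replicate_a_hpa.csv"), read_matrix(d / "replicate_a_msp.csv"), meta
    )
    b = FragmentProfilePair(
        read_matrix(d / "replicate_b_hpa.csv"), read_matrix(d / "replicate_b_msp.csv"), meta
    )
    return ReplicatePair(a, b)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_CSV_KW)
    if "id" in df.columns:
        df = df.set_index("id")
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, na_rep="NA")


def write_study(study: SyntheticStudy, outdir) -> Path:
    """Write a synthetic study as a CSV bundle plus a ground-truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(study.pair.hpa, out / "hpa.csv")
    _write_csv(study.pair.msp, out / "msp.csv")
    _write_csv(study.pair.fragment_meta, out / "fragment_meta.csv")
    _write_csv(study.samples.reset_index().set_index("id"), out / "samples.csv")
    rep = study.replicate
    _write_csv(rep.plate_a.hpa, out / "replicate_a_hpa.csv")
    _write_csv(rep.plate_a.msp, out / "replicate_a_msp.csv")
    _write_csv(rep.plate_b.hpa, out / "replicate_b_hpa.csv")
    _write_csv(rep.plate_b.msp, out / "replicate_b_msp.csv")
    truth = study.truth
    truth_json = dict(
        msl_labels=truth.msl_labels,
        nml_labels=truth.nml_labels,
        junk_labels=truth.junk_labels,
        planted_outlier_labels=truth.planted_outlier_labels,
        fst_epi=truth.fst_epi,
        fst_gen=truth.fst_gen,
        imposex_beta=list(truth.imposex_beta),
        imposex_cutpoints=list(truth.imposex_cutpoints),
        mass_coefficients=truth.mass_coefficients,
        plate_error_rate=truth.plate_error_rate,
    )
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    return out


def load_study(dirpath) -> tuple[FragmentProfilePair, ReplicatePair | None, pd.DataFrame]:
    """Load a CSV bundle: (pair, replicate or None, sample sheet)."""
    d = Path(dirpath)
    meta_path = d / "fragment_meta.csv"
    pair = read_fragment_pair(
        d / "hpa.csv", d / "msp.csv", meta_path if meta_path.exists() else None
    )
    replicate = None
    if (d / "replicate_a_hpa.csv").exists():
        replicate = read_replicate_pair(d, pair.fragment_meta)
    samples = read_sample_sheet(d / "samples.csv")
    return pair, replicate, samples
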