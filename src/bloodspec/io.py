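"""CSV I/O for SpectraSets, splits, and selection results.

Spectra travel as two CSVs: ``spectra.csv`` (header row = wavenumbers,
first column = sample_id) and ``meta.csv`` (sample_id, class, f_dbt, f_cbg,
f_pbg).  Round-trips are lossless at full float precision; files with
descending wavenumber order are re-sorted ascending on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpectraIOError
from .select import SelectionResult
from .split import SplitIndices
from .synth import SpectraSet

META_COLUMNS = ("sample_id", "class", "f_dbt", "f_cbg", "f_pbg")


def write_spectra(spectra: SpectraSet, spectra_path, meta_path) -> None:
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[repr(float(w)) for w in spectra.wavenumbers],
    )
    df.to_csv(spectra_path)
    meta = pd.DataFrame(
        {
            "sample_id": spectra.sample_ids,
            "class": spectra.class_labels,
            "f_dbt": spectra.fractions[:, 0],
            "f_cbg": spectra.fractions[:, 1],
            "f_pbg": spectra.fractions[:, 2],
        }
    )
    meta.to_csv(meta_path, index=False)


def read_spectra(spectra_path, meta_path) -> SpectraSet:
    try:
        df = pd.read_csv(spectra_path, index_col=0, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise SpectraIOError(f"cannot parse {spectra_path}: {exc}") from exc
    try:
        wavenumbers = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise SpectraIOError(f"non-numeric wavenumber header in {spectra_path}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise SpectraIOError(f"non-numeric absorbance cells in {spectra_path}") from exc
    if not np.all(np.isfinite(values)):
        raise SpectraIOError(f"non-numeric or missing absorbance cells in {spectra_path}")
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        raise SpectraIOError("duplicate sample ids in spectra file")

    order = np.argsort(wavenumbers)
    wavenumbers = wavenumbers[order]
    values = values[:, order]

    meta = pd.read_csv(meta_path, float_precision="round_trip")
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise SpectraIOError(f"meta file missing columns: {sorted(missing_cols)}")
    meta = meta.set_index(meta["sample_id"].astype(str))
    for sid in ids:
        if sid not in meta.index:
            raise SpectraIOError(f"sample id {sid!r} missing from meta file")
    meta = meta.loc[ids]
    fractions = meta[["f_dbt", "f_cbg", "f_pbg"]].to_numpy(dtype=float)
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=values,
        sample_ids=ids,
        class_labels=meta["class"].to_numpy(dtype=object),
        fractions=fractions,
    )


def write_split(split: SplitIndices, sample_ids: list[str], path) -> None:
    roles = {i: "train" for i in split.train_idx}
    roles.update({i: "test" for i in split.test_idx})
    pd.DataFrame(
        {"sample_id": sample_ids, "role": [roles[i] for i in range(len(sample_ids))]}
    ).to_csv(path, index=False)


def read_split(path, sample_ids: list[str]) -> SplitIndices:
    df = pd.read_csv(path)
    role_of = dict(zip(df["sample_id"].astype(str), df["role"]))
    train, test = [], []
    for i, sid in enumerate(sample_ids):
        if sid not in role_of:
            raise SpectraIOError(f"sample id {sid!r} missing from split file")
        (train if role_of[sid] == "train" else test).append(i)
    return SplitIndices(train_idx=np.array(train), test_idx=np.array(test))


def write_selection(result: SelectionResult, wavenumbers: np.ndarray, csv_path, trace_path) -> None:
    pd.DataFrame(
        {
            "variable_index": result.selected,
            "wavenumber_cm1": wavenumbers[result.selected],
        }
    ).to_csv(csv_path, index=False)
    Path(trace_path).write_text(
        json.dumps({"method": result.method, "trace": result.trace}, indent=1)
    )
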