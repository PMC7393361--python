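"""Spectral data model and I/O.

A :class:`SpectralDataset` is the wide matrix chemometricians work with:
samples (or sample replicates) as rows, wavenumbers as columns, absorbance
values in the cells.  Wavenumbers are stored strictly ascending in cm^-1;
files with a descending axis are accepted on read and reordered.

Labels are binary: ``BC`` (the positive, disease class) and ``HC`` (the
negative, healthy-control class), stored internally as 1/0 integers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

POSITIVE_LABEL = "BC"
NEGATIVE_LABEL = "HC"

_LABEL_TO_INT = {POSITIVE_LABEL: 1, NEGATIVE_LABEL: 0, "1": 1, "0": 0, 1: 1, 0: 0}
_INT_TO_LABEL = {1: POSITIVE_LABEL, 0: NEGATIVE_LABEL}

ID_COLUMNS = ("sample_id", "replicate", "label")


class SpectraFormatError(ValueError):
    """Malformed spectral file (bad header, duplicate wavenumbers, ...)."""


class SpectraParseError(ValueError):
    """Non-numeric or otherwise unparseable absorbance value."""


class LabelConsistencyError(ValueError):
    """Replicates of one sample carry conflicting class labels."""


@dataclass
class SpectralDataset:
    """Absorbance matrix with wavenumber axis, sample ids and labels.

    Parameters
    ----------
    wavenumbers
        Strictly increasing positions in cm^-1, one per column.
    absorbance
        2-D array, one row per measurement (replicate) or per sample once
        replicates have been averaged.
    sample_ids
        Per-row sample identifier (string).
    replicate_ids
        Per-row replicate number (1-based), or ``None`` after averaging.
    labels
        Per-row class label as int (1 = positive/BC, 0 = negative/HC), or
        ``None`` for prediction-only data.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    replicate_ids: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        self._validate()

    def _validate(self) -> None:
        w = self.wavenumbers
        if w.ndim != 1:
            raise SpectraFormatError("wavenumbers must be a 1-D vector")
        d = np.diff(w)
        if np.any(d == 0):
            raise SpectraFormatError("duplicate wavenumber values in axis")
        if np.any(d < 0) and np.any(d > 0):
            raise SpectraFormatError("wavenumber axis is not monotone")
        if np.any(d < 0):  # stored ascending; flip a descending axis
            self.wavenumbers = w[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise SpectraFormatError(
                f"absorbance has {p} columns but axis has {self.wavenumbers.size}"
            )
        for name, arr in (
            ("sample_ids", self.sample_ids),
            ("replicate_ids", self.replicate_ids),
            ("labels", self.labels),
        ):
            if arr is not None and arr.shape != (n,):
                raise SpectraFormatError(f"{name} length {arr.shape} != {n} rows")
        if self.labels is not None:
            for sid in np.unique(self.sample_ids):
                lab = self.labels[self.sample_ids == sid]
                if np.unique(lab).size > 1:
                    raise LabelConsistencyError(
                        f"sample {sid!r} has conflicting labels across replicates"
                    )

    # -- convenience -----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    @property
    def is_averaged(self) -> bool:
        return self.replicate_ids is None

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber`` (cm^-1)."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def with_absorbance(self, a: np.ndarray) -> "SpectralDataset":
        return replace(self, absorbance=np.asarray(a, dtype=float))


# ---------------------------------------------------------------------------
# I/O — wide and long CSV dialects
# ---------------------------------------------------------------------------


def _labels_from_column(col: pd.Series) -> np.ndarray:
    out = np.empty(len(col), dtype=int)
    for i, v in enumerate(col):
        key = v if not isinstance(v, str) else v.strip()
        if key not in _LABEL_TO_INT:
            raise SpectraParseError(f"unrecognised class label {v!r} in row {i}")
        out[i] = _LABEL_TO_INT[key]
    return out


def read_spectra(path, dialect: str = "wide-csv") -> SpectralDataset:
    """Read a spectral dataset from CSV.

    ``wide-csv``: columns ``sample_id,replicate,label,<wn1>,<wn2>,...`` with
    numeric wavenumber headers; one row per measurement.
    ``long-csv``: columns ``sample_id,replicate,label,wavenumber,absorbance``.
    """
    if dialect == "wide-csv":
        _check_duplicate_headers(path)
        df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
        return _from_wide_frame(df)
    if dialect == "long-csv":
        df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
        wide = df.pivot_table(
            index=["sample_id", "replicate", "label"],
            columns="wavenumber",
            values="absorbance",
            sort=False,
        ).reset_index()
        wide.columns = [str(c) for c in wide.columns]
        return _from_wide_frame(wide)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_duplicate_headers(path) -> None:
    # pandas mangles duplicate column names ("1000", "1000.1"), silently
    # turning a malformed file into different wavenumbers — check the raw
    # header line instead
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    spec_cols = [c for c in header if c not in ID_COLUMNS]
    if len(set(spec_cols)) != len(spec_cols):
        raise SpectraFormatError("duplicate wavenumber columns in header")


def _from_wide_frame(df: pd.DataFrame) -> SpectralDataset:
    for col in ("sample_id",):
        if col not in df.columns:
            raise SpectraFormatError(f"missing required column {col!r}")
    spec_cols = [c for c in df.columns if c not in ID_COLUMNS]
    try:
        wavenumbers = np.array([float(c) for c in spec_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header: {exc}") from exc
    values = df[spec_cols]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise SpectraParseError(
            f"non-numeric absorbance at row {r}, wavenumber {spec_cols[c]}"
        )
    labels = _labels_from_column(df["label"]) if "label" in df.columns else None
    replicate = (
        df["replicate"].to_numpy(dtype=int) if "replicate" in df.columns else None
    )
    return SpectralDataset(
        wavenumbers=wavenumbers,
        absorbance=numeric.to_numpy(dtype=float),
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        replicate_ids=replicate,
        labels=labels,
    )


def write_spectra(ds: SpectralDataset, path, dialect: str = "wide-csv") -> None:
    """Write a dataset as CSV (inverse of :func:`read_spectra`)."""
    if dialect != "wide-csv":
        raise ValueError(f"unsupported write dialect {dialect!r}")
    cols: dict = {"sample_id": ds.sample_ids}
    if ds.replicate_ids is not None:
        cols["replicate"] = ds.replicate_ids
    if ds.labels is not None:
        cols["label"] = [_INT_TO_LABEL[int(v)] for v in ds.labels]
    df = pd.DataFrame(cols)
    spec = pd.DataFrame(
        ds.absorbance, columns=[_format_wavenumber(w) for w in ds.wavenumbers]
    )
    pd.concat([df, spec.set_index(df.index)], axis=1).to_csv(path, index=False)


def _format_wavenumber(w: float) -> str:
    return f"{w:g}"


# ---------------------------------------------------------------------------
# Replicate averaging and truncation
# ---------------------------------------------------------------------------


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Average replicate rows of each sample into a single row.

    Triplicate acquisition is standard practice; downstream statistics assume
    one row per sample.  The operation is idempotent on averaged data and
    preserves labels (which are validated to agree across replicates).
    """
    sids, first = np.unique(ds.sample_ids, return_index=True)
    order = np.argsort(first)  # keep first-appearance order
    sids = sids[order]
    rows = np.empty((sids.size, ds.n_wavenumbers))
    labels = np.empty(sids.size, dtype=int) if ds.labels is not None else None
    for i, sid in enumerate(sids):
        mask = ds.sample_ids == sid
        rows[i] = ds.absorbance[mask].mean(axis=0)
        if labels is not None:
            labels[i] = ds.labels[mask][0]
    return SpectralDataset(
        wavenumbers=ds.wavenumbers.copy(),
        absorbance=rows,
        sample_ids=sids,
        replicate_ids=None,
        labels=labels,
    )


def truncate(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Restrict to the closed wavenumber interval [lo, hi] (cm^-1).

    The biofingerprint window 900-1800 cm^-1 carries most biomolecular
    absorption; truncating to it is the first preprocessing step.
    """
    if not lo < hi:
        raise ValueError(f"invalid range: lo={lo} must be < hi={hi}")
    mask = (ds.wavenumbers >= lo) & (ds.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"no wavenumbers in [{lo}, {hi}]")
    return replace(
        ds,
        wavenumbers=ds.wavenumbers[mask].copy(),
        absorbance=ds.absorbance[:, mask].copy(),
    )
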