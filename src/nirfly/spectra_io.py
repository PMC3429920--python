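"""Spectra containers and CSV input/output.

A :class:`SpectrumSet` holds one absorbance (or reflectance) trace per fly on
a shared, uniformly spaced wavelength grid, together with a sample-metadata
table.  The native on-disk format is plain CSV:

* wide form — first column ``sample_id``, remaining column headers are
  wavelengths in nm, one row per sample;
* long form — columns ``sample_id,wavelength,value``.

A comment line ``# units: reflectance`` (or ``absorbance``) on top of the
file records the measurement unit; silent unit guessing is never performed.
Reflectance R in (0, 1] converts to apparent absorbance as log10(1/R), the
working unit for all calibration work.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SpectraFormatError, ValidationError

UNITS = ("reflectance", "absorbance")

#: Columns of the sample-metadata table, in canonical order.
META_COLUMNS = ["sample_id", "line", "species", "sex", "age_days", "infection", "split"]

SPLITS = ("calibration", "independent")

_GRID_TOL = 1e-9


@dataclass
class SpectrumSet:
    """A set of spectra on one wavelength grid plus aligned sample metadata.

    Parameters
    ----------
    wavelengths : ndarray, shape (p,)
        Strictly increasing, uniformly spaced wavelengths in nm.
    values : ndarray, shape (n, p)
        One spectrum per row, in the unit named by ``units``.
    meta : DataFrame
        One row per spectrum; must contain at least ``sample_id`` (unique).
    units : str
        ``"reflectance"`` (fraction in (0, 1]) or ``"absorbance"`` (log10(1/R)).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame
    units: str = "absorbance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.units not in UNITS:
            raise ValidationError(f"unknown units {self.units!r}; expected one of {UNITS}")
        w = self.wavelengths
        if w.ndim != 1 or w.size < 1:
            raise ValidationError("wavelength grid must be a non-empty 1-D array")
        if w.size > 1:
            d = np.diff(w)
            if np.any(d <= 0):
                raise ValidationError("wavelength grid must be strictly increasing")
            if np.max(d) - np.min(d) > _GRID_TOL:
                raise ValidationError("wavelength grid must be uniformly spaced")
        if self.values.shape[1] != w.size:
            raise ValidationError(
                f"values have {self.values.shape[1]} columns for a grid of {w.size}"
            )
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        if "sample_id" not in self.meta.columns:
            raise ValidationError("metadata must contain a sample_id column")
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != self.values.shape[0]:
            raise ValidationError(
                f"{self.values.shape[0]} spectra but {len(self.meta)} metadata rows"
            )
        ids = self.meta["sample_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicated sample_id(s): {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("spectra contain non-finite values")
        if self.units == "reflectance":
            if np.any(self.values <= 0) or np.any(self.values > 1):
                raise ValidationError("reflectance values must lie in (0, 1]")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def spacing(self) -> float:
        """Grid spacing in nm (1.0 for a single-point grid)."""
        if self.wavelengths.size < 2:
            return 1.0
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].astype(str).tolist()

    # -- subsetting ----------------------------------------------------------

    def take(self, index: np.ndarray | Iterable[int]) -> "SpectrumSet":
        """Row subset (positional indices or boolean mask)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectrumSet(
            wavelengths=self.wavelengths,
            values=self.values[index],
            meta=self.meta.iloc[index].reset_index(drop=True),
            units=self.units,
        )

    def where(self, **criteria) -> "SpectrumSet":
        """Subset by metadata equality, e.g. ``s.where(species="melanogaster")``.

        A criterion value may be a scalar or a collection of admissible values.
        """
        mask = np.ones(self.n_samples, dtype=bool)
        for col, val in criteria.items():
            if col not in self.meta.columns:
                raise ValidationError(f"metadata has no column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset, np.ndarray)):
                mask &= self.meta[col].isin(list(val)).to_numpy()
            else:
                mask &= (self.meta[col] == val).to_numpy()
        return self.take(mask)

    def with_values(self, values: np.ndarray, wavelengths: np.ndarray | None = None,
                    units: str | None = None) -> "SpectrumSet":
        """Copy with new values (and optionally a new grid / unit)."""
        return SpectrumSet(
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            values=values,
            meta=self.meta.copy(),
            units=self.units if units is None else units,
        )


# ---------------------------------------------------------------------------
# unit transforms


def reflectance_to_absorbance(s: SpectrumSet) -> SpectrumSet:
    """Transform reflectance R to apparent absorbance log10(1/R)."""
    if s.units != "reflectance":
        raise ValidationError(f"expected reflectance input, got units={s.units!r}")
    if np.any(s.values <= 0):
        i, j = np.argwhere(s.values <= 0)[0]
        raise ValidationError(
            f"non-positive reflectance for sample {s.sample_ids[i]!r} "
            f"at {s.wavelengths[j]:g} nm"
        )
    return s.with_values(np.log10(1.0 / s.values), units="absorbance")


def absorbance_to_reflectance(s: SpectrumSet) -> SpectrumSet:
    """Inverse transform R = 10**(-A); exact round-trip partner."""
    if s.units != "absorbance":
        raise ValidationError(f"expected absorbance input, got units={s.units!r}")
    r = np.power(10.0, -s.values)
    if np.any(r > 1):
        raise ValidationError("negative absorbance maps outside (0, 1] reflectance")
    return s.with_values(r, units="reflectance")


# ---------------------------------------------------------------------------
# replicate averaging


def average_replicates(s: SpectrumSet, group_key: Mapping[str, str]) -> SpectrumSet:
    """Average replicate scans into one spectrum per group.

    ``group_key`` maps each replicate ``sample_id`` to a group identifier
    (the fly).  The mean is the plain arithmetic mean per wavelength in the
    stored unit, mirroring instruments that store the average of repeated
    scans of one specimen.  All metadata fields other than ``sample_id`` must
    agree within a group.
    """
    ids = s.sample_ids
    missing = [i for i in ids if i not in group_key]
    if missing:
        raise ValidationError(f"no group for sample_id(s): {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for row, sid in enumerate(ids):
        groups.setdefault(str(group_key[sid]), []).append(row)

    out_rows, out_meta = [], []
    other = [c for c in s.meta.columns if c != "sample_id"]
    for gid, rows in groups.items():
        sub = s.meta.iloc[rows]
        for col in other:
            if sub[col].nunique(dropna=False) > 1:
                raise ValidationError(
                    f"group {gid!r} has conflicting metadata in column {col!r}"
                )
        out_rows.append(s.values[rows].mean(axis=0))
        rec = {c: sub.iloc[0][c] for c in other}
        rec["sample_id"] = gid
        out_meta.append(rec)
    meta = pd.DataFrame(out_meta)
    meta = meta[["sample_id"] + other] if other else meta
    return SpectrumSet(s.wavelengths, np.vstack(out_rows), meta, units=s.units)


# ---------------------------------------------------------------------------
# CSV input/output


def _read_csv_with_units(path, units_override: str | None):
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    units = units_override
    lines = text.splitlines(keepends=True)
    body_start = 0
    for ln in lines:
        if ln.startswith("#"):
            body_start += 1
            stripped = ln.lstrip("#").strip()
            if stripped.lower().startswith("units:"):
                file_units = stripped.split(":", 1)[1].strip().lower()
                if units_override is None:
                    units = file_units
        else:
            break
    if units is None:
        raise SpectraFormatError(
            f"{path}: no '# units:' header line and no units override given"
        )
    body = "".join(lines[body_start:])
    return body, units


def read_spectra(path, format: str = "wide", units: str | None = None) -> SpectrumSet:
    """Read a spectra CSV (wide or long form) into a :class:`SpectrumSet`.

    The measurement unit is taken from a leading ``# units:`` comment line,
    or from the ``units`` argument which overrides the file header.
    """
    body, units = _read_csv_with_units(path, units)
    try:
        df = pd.read_csv(io.StringIO(body))
    except Exception as exc:  # ragged rows, empty file, ...
        raise SpectraFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.isna().any().any():
        raise SpectraFormatError(f"{path}: missing values (ragged rows?)")

    if format == "wide":
        if df.columns[0] != "sample_id":
            raise SpectraFormatError(f"{path}: first wide-CSV column must be sample_id")
        try:
            wl = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: non-numeric wavelength header") from exc
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        meta = pd.DataFrame({"sample_id": df["sample_id"].astype(str)})
    elif format == "long":
        needed = {"sample_id", "wavelength", "value"}
        if not needed.issubset(df.columns):
            raise SpectraFormatError(f"{path}: long CSV needs columns {sorted(needed)}")
        pivot = df.pivot(index="sample_id", columns="wavelength", values="value")
        pivot = pivot.reindex(index=df["sample_id"].astype(str).unique())
        pivot = pivot.sort_index(axis=1)
        if pivot.isna().any().any():
            raise SpectraFormatError(f"{path}: incomplete wavelength coverage per sample")
        wl = pivot.columns.to_numpy(dtype=float)
        values = pivot.to_numpy(dtype=float)
        meta = pd.DataFrame({"sample_id": pivot.index.astype(str)})
    else:
        raise SpectraFormatError(f"unknown spectra format {format!r}")
    return SpectrumSet(wl, values, meta, units=units)


def write_spectra(s: SpectrumSet, path, format: str = "wide") -> None:
    """Write spectra as CSV with a ``# units:`` header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {s.units}\n")
        if format == "wide":
            cols = ["sample_id"] + [f"{w:.10g}" for w in s.wavelengths]
            df = pd.DataFrame(s.values, columns=cols[1:])
            df.insert(0, "sample_id", s.sample_ids)
            df.to_csv(fh, index=False)
        elif format == "long":
            n, p = s.values.shape
            df = pd.DataFrame({
                "sample_id": np.repeat(s.sample_ids, p),
                "wavelength": np.tile(s.wavelengths, n),
                "value": s.values.ravel(),
            })
            df.to_csv(fh, index=False)
        else:
            raise SpectraFormatError(f"unknown spectra format {format!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata CSV (columns of :data:`META_COLUMNS`)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"{path}: metadata missing columns {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    bad = set(df["split"].unique()) - set(SPLITS)
    if bad:
        raise ValidationError(f"{path}: unknown split value(s) {sorted(bad)}")
    if (df["age_days"] < 0).any():
        raise ValidationError(f"{path}: negative age_days")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def attach_metadata(s: SpectrumSet, meta: pd.DataFrame) -> SpectrumSet:
    """Join a full metadata table onto a SpectrumSet by sample_id."""
    meta = meta.set_index("sample_id")
    try:
        joined = meta.loc[s.sample_ids].reset_index()
    except KeyError as exc:
        raise ValidationError(f"metadata missing for sample(s): {exc}") from exc
    return SpectrumSet(s.wavelengths, s.values, joined, units=s.units)
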