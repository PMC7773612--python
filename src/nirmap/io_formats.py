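"""Spectra and reference-table containers, CSV round-tripping, replicate averaging.

A measurement session produces a matrix of diffuse-reflectance intensities
(rows = individual probe acquisitions, columns = wavelength channels on a
strictly increasing nm axis) and a reference table of constituent contents
(water, uronic acid, hydroxyproline, each as % of specimen wet weight),
optionally with (row, col) grid coordinates for mapped specimens.  Replicate
acquisitions at one location are collapsed to a representative spectrum by
channel-wise averaging before any modelling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthAxis",
    "SpectraSet",
    "ReferenceTable",
    "read_spectra",
    "write_spectra",
    "read_references",
    "write_references",
    "average_replicates",
]

CONSTITUENTS = ("water", "uronic_acid", "hydroxyproline")


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing, finite wavelength axis in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength axis must be 1-D with at least 2 channels")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelength axis contains non-finite values")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @classmethod
    def default(cls) -> "WavelengthAxis":
        """Instrument axis: 1000-2500 nm at 6.55 nm spacing (230 channels)."""
        return cls(np.arange(1000.0, 2500.0 + 1e-9, 6.55))

    def segments(self, gap_factor: float = 1.5) -> list[tuple[int, int]]:
        """Contiguous channel runs as [start, stop) index pairs.

        A gap wider than ``gap_factor`` times the median spacing (e.g. left by
        range cropping) starts a new segment.  Filters must never mix channels
        across such gaps.
        """
        wl = self.wavelengths
        step = float(np.median(np.diff(wl)))
        breaks = np.where(np.diff(wl) > gap_factor * step)[0]
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [wl.size]))
        return [(int(a), int(b)) for a, b in zip(starts, stops)]


@dataclass
class SpectraSet:
    """Measurement x channel intensity matrix with ids and replicate groups."""

    values: np.ndarray
    axis: WavelengthAxis
    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.axis):
            raise ValueError(
                f"column count {self.values.shape[1]} != axis length {len(self.axis)}"
            )
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("one sample id per row required")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("one replicate-group label per row required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain missing or non-finite values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, axis: WavelengthAxis | None = None) -> "SpectraSet":
        return SpectraSet(values, axis or self.axis, list(self.sample_ids), list(self.groups))

    def select_channels(self, idx: np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return SpectraSet(
            self.values[:, idx],
            WavelengthAxis(self.axis.wavelengths[idx]),
            list(self.sample_ids),
            list(self.groups),
        )


@dataclass
class ReferenceTable:
    """Per-location constituent contents in % of wet weight, optional grid coords."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "location_id" not in df.columns:
            raise ValueError("reference table needs a 'location_id' column")
        missing = [c for c in CONSTITUENTS if c not in df.columns]
        if missing:
            raise ValueError(f"reference table missing constituent columns {missing}")
        if df["location_id"].duplicated().any():
            raise ValueError("location ids must be unique")
        for c in CONSTITUENTS:
            vals = df[c].to_numpy(dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"{c} contains negative contents")
        if np.any(df["water"].to_numpy(dtype=float) > 100):
            raise ValueError("water content exceeds 100% of wet weight")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def has_grid(self) -> bool:
        return {"row", "col"}.issubset(self.table.columns)

    def values_for(self, constituent: str) -> np.ndarray:
        if constituent not in CONSTITUENTS:
            raise KeyError(f"unknown constituent {constituent!r}")
        return self.table[constituent].to_numpy(dtype=float)

    def aligned_to(self, ids: list[str]) -> "ReferenceTable":
        """Reorder rows to match the given location-id sequence."""
        df = self.table.set_index("location_id").loc[ids].reset_index()
        return ReferenceTable(df)


# ---------------------------------------------------------------------------
# CSV round-tripping.  Layout: first column sample_id, second replicate group,
# remaining columns one per wavelength with the nm value as header.  A leading
# '# wavelength unit: nm' comment line records the axis unit.


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        spectra.values,
        columns=[repr(float(w)) for w in spectra.axis.wavelengths],
    )
    df.insert(0, "group", spectra.groups)
    df.insert(0, "sample_id", spectra.sample_ids)
    with open(path, "w") as fh:
        fh.write("# wavelength unit: nm\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _sniff_sep(first_line: str) -> str:
    return "\t" if first_line.count("\t") > first_line.count(",") else ","


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a spectra CSV/TSV; wavelength columns are sorted ascending on load."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty spectra file")
    sep = _sniff_sep(lines[0])
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    groups = (
        df["group"].astype(str).tolist()
        if "group" in df.columns
        else df["sample_id"].astype(str).tolist()
    )
    wl_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength header: {exc}") from exc
    order = np.argsort(wl)
    values = df[wl_cols].to_numpy(dtype=float)[:, order]
    if np.any(pd.isna(values)):
        bad = int(np.where(pd.isna(values))[0][0])
        raise ValueError(f"{path}: missing values in row {bad}")
    return SpectraSet(
        values,
        WavelengthAxis(wl[order]),
        df["sample_id"].astype(str).tolist(),
        groups,
    )


def write_references(refs: ReferenceTable, path: str | Path) -> None:
    refs.table.to_csv(path, index=False)


def read_references(path: str | Path) -> ReferenceTable:
    first = Path(path).read_text().splitlines()[0]
    return ReferenceTable(pd.read_csv(path, sep=_sniff_sep(first)))


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Collapse replicate groups to representative spectra (channel-wise mean).

    One output row per group, in first-appearance order; a singleton group
    passes through unchanged.  Group labels become the new sample ids.
    """
    seen: dict[str, list[int]] = {}
    for i, g in enumerate(spectra.groups):
        seen.setdefault(g, []).append(i)
    means = np.stack([spectra.values[rows].mean(axis=0) for rows in seen.values()])
    ids = list(seen.keys())
    return SpectraSet(means, spectra.axis, ids, list(ids))
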