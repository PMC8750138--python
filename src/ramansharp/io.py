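"""Readers and writers for delimited-text spectra, matrices and peak tables.

Two-column tables (axis, intensity) cover single spectra; hyperspectral
sets are stored as a matrix whose first column is the shared axis and
whose remaining columns are spectra, with an optional sidecar table of
raster coordinates.  Comma is the default delimiter; tab-delimited files
are auto-detected.  Lines starting with ``#`` are comments.  All writers
emit full double precision so read-after-write is the identity.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .spectrum import FittedPeak, PeakList, Spectrum, SpectrumSet

__all__ = [
    "read_spectrum_table",
    "write_spectrum_table",
    "read_hyperspectral_matrix",
    "write_hyperspectral_matrix",
    "read_peak_table",
    "write_peak_table",
]

_FMT = "%.17g"


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: no data lines found")


def _read_numeric_table(path, min_cols: int) -> np.ndarray:
    path = Path(path)
    delim = _sniff_delimiter(path)
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            cells = [c.strip() for c in text.split(delim)]
            try:
                values = [float(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell on line {lineno}") from exc
            if width is None:
                width = len(values)
                if width < min_cols:
                    raise ValueError(
                        f"{path}: expected at least {min_cols} columns, got {width}"
                    )
            elif len(values) != width:
                raise ValueError(f"{path}: ragged row on line {lineno}")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite values in table")
    return arr


def read_spectrum_table(path) -> Spectrum:
    """Read a two-column (axis, intensity) delimited text file.

    Rows are sorted by axis; duplicate axis values are an error.
    """
    arr = _read_numeric_table(path, min_cols=2)
    order = np.argsort(arr[:, 0], kind="stable")
    axis, inten = arr[order, 0], arr[order, 1]
    if np.any(np.diff(axis) == 0):
        raise ValueError(f"{path}: duplicate axis values")
    return Spectrum(axis, inten)


def write_spectrum_table(s: Spectrum, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for x, y in zip(s.axis, s.intensities):
            fh.write(f"{x:.17g},{y:.17g}\n")


def read_hyperspectral_matrix(path, coords_path=None) -> SpectrumSet:
    """Read an axis-first matrix file, optionally joining raster coordinates.

    The sidecar ``coords_path`` is a delimited table with columns
    (column index, row, col); the column index refers to the spectrum's
    0-based position in the matrix (excluding the axis column).
    """
    arr = _read_numeric_table(path, min_cols=2)
    axis = arr[:, 0]
    if np.any(np.diff(axis) <= 0):
        raise ValueError(f"{path}: axis column must be strictly increasing")
    inten = arr[:, 1:].T  # (n_spectra, n_channels)
    coords = None
    if coords_path is not None:
        table = _read_numeric_table(coords_path, min_cols=3)
        n = inten.shape[0]
        coords_map = {}
        for col_idx, row, col in table:
            idx = int(col_idx)
            if idx < 0 or idx >= n:
                raise ValueError(
                    f"{coords_path}: coordinate row references unknown column {idx}"
                )
            coords_map[idx] = (int(row), int(col))
        if len(coords_map) != n:
            raise ValueError(f"{coords_path}: must give coordinates for every spectrum")
        coords = tuple(coords_map[i] for i in range(n))
    return SpectrumSet(axis, inten, coords)


def write_hyperspectral_matrix(sset: SpectrumSet, path, coords_path=None) -> None:
    mat = np.column_stack([sset.axis, sset.intensities.T])
    np.savetxt(path, mat, fmt=_FMT, delimiter=",")
    if coords_path is not None:
        if sset.coords is None:
            raise ValueError("SpectrumSet carries no raster coordinates")
        with open(coords_path, "w") as fh:
            fh.write("# column,row,col\n")
            for i, (r, c) in enumerate(sset.coords):
                fh.write(f"{i},{r},{c}\n")


def write_peak_table(peaks: PeakList, path) -> None:
    """One row per peak: position, amplitude, hwhm, shape, family."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position", "amplitude", "hwhm", "shape", "family"])
        for p in peaks:
            writer.writerow(
                [f"{p.position:.17g}", f"{p.amplitude:.17g}", f"{p.hwhm:.17g}",
                 f"{p.shape:.17g}", p.family]
            )


def read_peak_table(path) -> PeakList:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"position", "amplitude", "hwhm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: peak table needs columns {sorted(required)}")
    peaks = []
    for _, row in df.iterrows():
        peaks.append(
            FittedPeak(
                position=float(row["position"]),
                amplitude=float(row["amplitude"]),
                hwhm=float(row["hwhm"]),
                shape=float(row.get("shape", 1.0)),
                family=str(row.get("family", "pseudo_voigt")),
            )
        )
    return PeakList(peaks)
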