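"""File formats: hit tables (CSV / HDF5 / t3pa-like ASCII), spectra, tables.

Hit dialects
------------
* ``csv`` — header ``x,y,toa_ns,energy_keV``; 0-based pixel coordinates.
* ``hdf5`` — one group ``hits`` with datasets of the same four names.
* ``t3pa`` — whitespace-separated ASCII superset of the Timepix3 pixel
  stream: header line then columns ``Index  Matrix  ToA  Energy`` where
  ``Matrix`` is the linearized pixel index ``y * 256 + x``, ``ToA`` is the
  arrival time in ns and ``Energy`` the calibrated deposition in keV.

All readers validate the hit invariants and report malformed rows with
their line numbers (ParseError).

Spectra serialize as CSV (``bin_lo,bin_hi,weight``) with a JSON sidecar-or-
inline metadata file (quantity, medium, extra metadata); alpha(LET) tables
as two-column CSV (``let_kev_um,alpha_per_gy``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import GRID_SIZE, HIT_COLUMNS, validate_hits
from .errors import ConfigurationError, ParseError
from .let import Spectrum
from .mmkm import AlphaTable

DIALECTS = ("csv", "hdf5", "t3pa")


def _validate_rows(df: pd.DataFrame, offset: int) -> pd.DataFrame:
    """Row-level invariant check collecting offending line numbers."""
    bad = []
    x, y, e = df["x"].to_numpy(), df["y"].to_numpy(), df["energy_keV"].to_numpy()
    out_xy = (x < 0) | (x >= GRID_SIZE) | (y < 0) | (y >= GRID_SIZE)
    out_e = ~(e > 0)
    for i in np.nonzero(out_xy)[0]:
        bad.append((int(i) + offset, f"pixel ({x[i]}, {y[i]}) outside the matrix"))
    for i in np.nonzero(out_e & ~out_xy)[0]:
        bad.append((int(i) + offset, f"non-positive energy {e[i]}"))
    if bad:
        raise ParseError("invalid hit rows", sorted(bad))
    return df


def read_hits(path, dialect: str = "csv") -> pd.DataFrame:
    """Read a hit table in one of the supported dialects."""
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in HIT_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        df = df[list(HIT_COLUMNS)]
        offset = 2  # header is line 1
    elif dialect == "hdf5":
        with h5py.File(path, "r") as f:
            grp = f["hits"]
            df = pd.DataFrame({c: grp[c][()] for c in HIT_COLUMNS})
        offset = 0
    elif dialect == "t3pa":
        df = _read_t3pa(path)
        offset = 2
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = df.astype({"x": np.int64, "y": np.int64,
                    "toa_ns": np.float64, "energy_keV": np.float64})
    _validate_rows(df, offset)
    return validate_hits(df.reset_index(drop=True))


def _read_t3pa(path) -> pd.DataFrame:
    rows, bad = [], []
    with open(path) as f:
        header = f.readline()
        if "Matrix" not in header:
            raise ParseError(f"{path}: not a t3pa-like file (missing header)")
        for lineno, line in enumerate(f, start=2):
            parts = line.split()
            if not parts:
                continue
            try:
                matrix = int(parts[1])
                toa = float(parts[2])
                energy = float(parts[3])
            except (IndexError, ValueError):
                bad.append((lineno, "unparseable row"))
                continue
            rows.append((matrix % GRID_SIZE, matrix // GRID_SIZE, toa, energy))
    if bad:
        raise ParseError(f"{path}: malformed t3pa rows", bad)
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


def write_hits(df: pd.DataFrame, path, dialect: str = "csv") -> None:
    validate_hits(df)
    path = Path(path)
    if dialect == "csv":
        df[list(HIT_COLUMNS)].to_csv(path, index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            grp = f.create_group("hits")
            for c in HIT_COLUMNS:
                grp.create_dataset(c, data=df[c].to_numpy())
    elif dialect == "t3pa":
        with open(path, "w") as f:
            f.write("Index\tMatrix\tToA\tEnergy\n")
            for i, r in enumerate(df.itertuples(index=False)):
                matrix = int(r.y) * GRID_SIZE + int(r.x)
                f.write(f"{i}\t{matrix}\t{r.toa_ns:.3f}\t{r.energy_keV:.6g}\n")
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")


def write_spectrum(spec: Spectrum, csv_path, meta_path=None) -> None:
    """Write bins as CSV plus a JSON metadata file (default: <csv>.json)."""
    csv_path = Path(csv_path)
    pd.DataFrame({
        "bin_lo": spec.edges[:-1],
        "bin_hi": spec.edges[1:],
        "weight": spec.weights,
    }).to_csv(csv_path, index=False)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(csv_path.suffix + ".json")
    meta_path.write_text(json.dumps(
        {"quantity": spec.quantity, "medium": spec.medium, "meta": spec.meta}, indent=2))


def read_spectrum(csv_path, meta_path=None) -> Spectrum:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("bin_lo", "bin_hi", "weight"):
        if col not in df.columns:
            raise ParseError(f"{csv_path}: missing column {col}")
    lo, hi = df["bin_lo"].to_numpy(), df["bin_hi"].to_numpy()
    if len(lo) > 1 and not np.allclose(lo[1:], hi[:-1]):
        raise ParseError(f"{csv_path}: bins are not contiguous")
    edges = np.append(lo, hi[-1])
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(csv_path.suffix + ".json")
    kw = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kw = {"quantity": meta.get("quantity", "energy"),
              "medium": meta.get("medium"), "meta": meta.get("meta", {})}
    return Spectrum(edges, df["weight"].to_numpy(), **kw)


def write_alpha_table(table: AlphaTable, path) -> None:
    pd.DataFrame({"let_kev_um": table.let, "alpha_per_gy": table.alpha}).to_csv(
        Path(path), index=False)


def read_alpha_table(path, species: str = "") -> AlphaTable:
    df = pd.read_csv(Path(path))
    for col in ("let_kev_um", "alpha_per_gy"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return AlphaTable(df["let_kev_um"].to_numpy(), df["alpha_per_gy"].to_numpy(),
                      species=species)
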